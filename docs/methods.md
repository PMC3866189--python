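# Methods

## Scope and model of the data

The package analyses region-of-interest (ROI) BOLD time series that have
already been parcellated (AAL-90 by default: 45 homologous region pairs,
cerebellum excluded). Everything upstream of the ROI series — slice
timing, realignment, spatial normalisation — is out of scope. The unit of
analysis is one subject's T × N matrix (typically 230 retained volumes at
TR = 2 s × 90 ROIs) plus a nine-column nuisance table (six rigid-body
motion parameters, white-matter, CSF and global-mean signals).

## Preprocessing

Nuisance removal is ordinary least squares per ROI with an intercept;
residuals are exactly orthogonal to every covariate and the operation is
idempotent. Global-signal regression is included as the ninth covariate by
default and can be disabled (`include_global_signal=False`) for
sensitivity analyses.

Band-pass filtering is an ideal rectangular filter in the discrete Fourier
domain: bins with low ≤ f ≤ high (inclusive on both edges, f from the
length-T transform) are kept, all others — including 0 Hz — are zeroed.
This matches the FFT-mask convention of the standard resting-state
toolchains rather than an IIR design; no padding or tapering is applied.
The default band is 0.01–0.08 Hz. Filtering ROI averages is equivalent to
averaging filtered voxels because both operations are linear, so the
ROI-level placement of the filter does not change the result.

The pipeline order is regression → filtering, fixed in the default
configuration.

## Network construction

Connectivity is the absolute Pearson correlation between residual series;
the sign is deliberately discarded and the diagonal zeroed. Binarization
keeps the E = round(s·N(N−1)/2) strongest edges at sparsity s (half-up
rounding; floor/ceil selectable), which equalises edge count across
subjects at each threshold. Ties at the cutoff are broken by (row, column)
lexicographic order so thresholding is deterministic and the edge sets are
nested along the grid.

The default grid is 0.05–0.36 in steps of 0.01 (32 thresholds). A
data-driven range can be requested instead (`auto_grid`): the maximal
contiguous run of sparsities where every subject's mean degree 2E/N
exceeds ln N and every subject's small-worldness exceeds 1.1. Note a
boundary subtlety: at s = 0.05 on 90 nodes the mean degree is 4.44, just
below ln 90 ≈ 4.50, so a strict natural-log criterion starts the grid at
0.06; the printed convention of 0.05 is kept as the default and the
criterion (and its log base) is configurable rather than silently
reinterpreted.

## Graph metrics

All metrics are standard binary, undirected forms:

* clustering: per node 2·triangles/(k(k−1)), zero for degree < 2; C_p is
  the node mean;
* characteristic path length L_p: mean shortest-path length over mutually
  reachable pairs — unreachable pairs are excluded rather than assigned a
  penalty constant, which keeps L_p defined at the sparse end of the grid;
* global/nodal/local efficiency: mean of 1/d with 1/∞ = 0, so
  disconnection is handled natively;
* betweenness: Brandes accumulation, unordered source–target pairs,
  endpoints excluded (star centre with 4 leaves scores C(4,2) = 6).

γ and λ divide C_p and L_p by their means over an ensemble of
degree-preserving Maslov–Sneppen rewirings (default 100 networks, 10
successful double-edge swaps per edge; both configurable and echoed into
run metadata). Connectivity is preserved when the input is connected:
swaps are applied in windows with rollback on disconnection. If no valid
swap is found in 100·E consecutive attempts (e.g. a complete graph) the
current state is returned with a warning. σ = γ/λ by construction.

Every metric is validated against naive brute-force oracles (triangle
enumeration, Floyd–Warshall, shortest-path counting) on hundreds of small
random graphs to 1e-10.

## Integration and hubs

A metric curve Y(s) over the grid is summarised by the rectangle-rule sum
∑_k Y(k·Δs)·Δs, the plain-summation definition of the integrated network
parameter; a trapezoid option exists but is not the default. Normalised
betweenness B_i divides each subject's integrated betweenness by that
subject's across-node mean and averages the ratios across subjects
(normalise-then-average; the other order is available for sensitivity
analysis). Hubs are nodes with B_i strictly above 1.5, the conventional
multiple of the network average; the threshold is a parameter.

## Group inference

* Permutation tests shuffle group labels (n_perm default 10,000) and use
  the finite-sample-corrected p = (#{|null| ≥ |obs|}+1)/(n_perm+1), which
  is valid under exchangeability and never exactly zero.
* Cohen's d uses the (n−1)-weighted pooled SD and accepts either raw
  values or (mean, sd, n) summaries; the two routes agree to 1e-12.
* The NBS thresholds edge-wise pooled-variance t statistics at a primary
  edge-level p (default 0.001, two-tailed), extracts connected components
  of the suprathreshold graph, and scores them by edge count against the
  permutation null of the maximal component size. Corrected p uses the
  same +1 correction. An empty suprathreshold graph is a valid
  (non-significant) outcome, not an error.
* Nodal group differences are reported uncorrected together with their
  effect sizes; FDR correction is available but off by default, matching
  the study convention for these exploratory maps.
* Duration-of-use association is OLS of the metric on duration plus age
  (residualise-then-test for the age confound: age enters the regression
  rather than the permutation scheme); the partial correlation is derived
  from the slope's t statistic.

## Synthetic cohorts

The generator emulates the *second-order* structure of preprocessed
resting-state data: each subject is drawn from a zero-mean multivariate
normal whose correlation matrix is block-modular (default 90 ROIs, 6
modules, within-module r = 0.45, between-module r = 0.1). Because every
downstream stage consumes only correlations, second-order structure is the
sufficient statistic; no hemodynamic convolution, temporal autocorrelation
or physiological noise is simulated. Consequences for interpretation:
passing recovery tests demonstrate that the statistics detect the effects
they target at the stated sample sizes and effect magnitudes under
Gaussian, temporally white signals — they do not certify behaviour under
autocorrelated noise, where effective degrees of freedom are lower.

Group effects are implanted directly in the case-group correlation matrix:

* a connected component of edges (default: a 10-edge path inside module 0)
  sharing one delta (default −0.3, i.e. reduced connectivity in cases) —
  the target the NBS stage must recover;
* arbitrary extra (edge, delta) pairs;
* a duration link: the within-module edges of one node (default node 36,
  the left hippocampus position in AAL ordering) are shifted by
  slope·(duration − 10 yr) per subject. The default slope, 0.025
  correlation-units/year, was calibrated at design time so that the
  age-controlled regression detects the association in ≈90% of seeded
  cohorts at T = 230 and n = 17 — the generator contract requires ≥80%
  detectability of its default effect.

Demographics mirror the emulated cohort: ages Normal(36.3, 6.9) truncated
to 26–50 for cases and Normal(31.3, 8.1) truncated to 20–46 for controls,
education similarly truncated, female fractions 2/17 and 3/15, duration
Uniform(1, 19) years, dosage Uniform(0.1, 2.0) g/day. The within-module
correlation default of 0.45 keeps the default implant positive definite;
when a perturbation does break positive definiteness (e.g. the same
implant on a 0.5 block) the matrix is projected to the nearest PD
correlation matrix, the event is flagged with the largest collateral
change to non-target entries, and a second warning fires if that change
exceeds 100× the 1e-6 reporting tolerance.

Nuisance series are independent of the signal by default; a
`nuisance_leakage` coefficient mixes them in to exercise the regression
stage. All randomness flows from one cohort seed through spawned
sequences, so identical seeds give bit-identical cohorts.

## Numerical and design choices

* Correlations are clipped to [0, 1] after the absolute value to absorb
  floating-point overshoot; constant series are an error naming the ROI.
* Rank-deficient nuisance designs fall back to minimum-norm least squares
  with a warning (redundant columns contribute nothing).
* `determine_sparsity_range` reports per-sparsity diagnostics when no
  range qualifies, rather than a bare failure.
* Problem sizes in the test-suite and acceptance script (ensemble sizes
  5–20, 1,000 permutations, 20–50 simulation seeds, coarse 0.05-step grids
  for full-pipeline runs) are scaled-down choices that keep the recovery
  and calibration analyses statistically meaningful — rates are judged
  against binomial envelopes at those run counts — while remaining
  routine desk-side computations; production analyses would use the
  defaults (ensemble 100, 10,000 permutations, 0.01-step grid).

## Known limitations

* Weighted, signed, directed and partial-correlation networks are out of
  scope, as are modularity/rich-club analyses and voxel-level processing.
* L_p on fragmented graphs (very low sparsity) averages only reachable
  pairs; comparisons across graphs with very different component
  structures should lean on the efficiency metrics instead.
* The multivariate-normal generator cannot probe sensitivity to
  autocorrelation, non-Gaussianity or motion artefacts; its nuisance
  series are stylised (smooth random walks + white noise).
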