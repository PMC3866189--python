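"""ROI-level time-series preprocessing.

Operates on region-averaged BOLD series *after* parcellation: dropping
initial volumes, ordinary-least-squares removal of nuisance covariates
(six rigid-body motion parameters plus white-matter, CSF and global-mean
signals — nine in total by convention), and temporal band-pass filtering
restricted to the low-frequency fluctuation band (0.01–0.08 Hz by default).

Voxel-level steps (slice timing, realignment, spatial normalisation) are
out of scope; they belong to the imaging pipeline upstream of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "BandSpec",
    "drop_initial_volumes",
    "regress_nuisance",
    "bandpass",
]

DEFAULT_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's region-of-interest time-series matrix.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        Rows are time points, columns are ROIs.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    roi_labels : list of str
        N unique region labels (column names).
    """

    values: np.ndarray
    tr_seconds: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (time x ROI) matrix")
        if values.shape[0] < 2:
            raise ValueError("need at least two time points")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        labels = list(self.roi_labels)
        if not labels:
            from .atlas import labels_for

            labels = labels_for(values.shape[1])
        if len(labels) != values.shape[1]:
            raise ValueError(
                f"{len(labels)} labels for {values.shape[1]} ROI columns"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        object.__setattr__(self, "roi_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


@dataclass(frozen=True)
class BandSpec:
    """Pass band [low_hz, high_hz] for temporal filtering."""

    low_hz: float = DEFAULT_BAND[0]
    high_hz: float = DEFAULT_BAND[1]

    def __post_init__(self):
        if self.low_hz < 0:
            raise ValueError("low_hz must be >= 0")
        if self.high_hz <= self.low_hz:
            raise ValueError("high_hz must exceed low_hz")

    def validate_for(self, tr_seconds: float) -> None:
        nyq = 1.0 / (2.0 * tr_seconds)
        if self.high_hz > nyq + 1e-12:
            raise ValueError(
                f"high_hz={self.high_hz} exceeds Nyquist {nyq:.4f} Hz "
                f"for TR={tr_seconds}s"
            )


def drop_initial_volumes(ts: RoiTimeSeries, k: int) -> RoiTimeSeries:
    """Remove the first ``k`` volumes (scanner stabilisation period)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_timepoints:
        raise ValueError(f"cannot drop {k} of {ts.n_timepoints} volumes")
    if k == 0:
        return ts
    return replace(ts, values=ts.values[k:].copy())


def regress_nuisance(ts: RoiTimeSeries, covariates: np.ndarray) -> RoiTimeSeries:
    """Replace each ROI series by its OLS residual on the covariates.

    An intercept column is always included, so the residuals are mean-free.
    Rank-deficient covariate matrices are handled by a minimum-norm least
    squares solve (redundant directions contribute nothing) with a warning.
    """
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    T = ts.n_timepoints
    if cov.shape[0] != T:
        raise ValueError(
            f"covariates have {cov.shape[0]} rows, time series has {T}"
        )
    if cov.shape[1] >= T:
        raise ValueError("more covariates than time points")
    design = np.column_stack([np.ones(T), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient (rank {rank} < "
            f"{design.shape[1]} columns); redundant columns are ignored",
            UserWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    residuals = ts.values - design @ beta
    return replace(ts, values=residuals)


def bandpass(ts: RoiTimeSeries, band: BandSpec | tuple[float, float] = DEFAULT_BAND) -> RoiTimeSeries:
    """Ideal (rectangular) frequency-domain band-pass filter.

    Discrete Fourier coefficients at frequencies f with
    ``low_hz <= f <= high_hz`` are retained and all others (including the
    0 Hz mean) are zeroed; the inverse transform is returned. This matches
    the convention of the standard resting-state toolchains, which filter
    by masking FFT bins rather than with an IIR design.
    """
    if not isinstance(band, BandSpec):
        band = BandSpec(*band)
    band.validate_for(ts.tr_seconds)
    T = ts.n_timepoints
    freqs = np.fft.rfftfreq(T, d=ts.tr_seconds)
    eps = 1e-12
    keep = (freqs >= band.low_hz - eps) & (freqs <= band.high_hz + eps)
    keep &= freqs > eps  # always remove the mean
    spectrum = np.fft.rfft(ts.values, axis=0)
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=T, axis=0)
    return replace(ts, values=filtered)
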