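"""From region-level BOLD-like signals to temporal brain networks.

Post-parcellation stages of the extraction pipeline: confound regression,
band-pass filtering of the slow BOLD fluctuations (0.01-0.08 Hz by
default), rectangular sliding windows (60 s length / 30 s overlap at a
repetition time of 0.72 s), windowed Pearson correlation, and thresholding
of the correlation tensor into one binary snapshot per window.  A
label-averaging helper turns voxel-level matrices into region series.

Only positive thresholds are applied (negative correlations have no agreed
interpretation and never become edges); the comparison is strict
(``r > tau``).  The default threshold grid is 0.20..0.90 in steps of 0.05
plus 0.92..0.98 in steps of 0.02 (19 values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .temporal_graph import TemporalGraph

__all__ = [
    "RegionSeries",
    "WindowSpec",
    "regress_confounds",
    "bandpass",
    "parcellate",
    "sliding_windows",
    "window_correlations",
    "threshold",
    "default_thresholds",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: HCP-style repetition time in seconds.
DEFAULT_TR = 0.72
#: BOLD fluctuation band in Hz.
DEFAULT_BAND = (0.01, 0.08)


@dataclass
class RegionSeries:
    """A region x sample real matrix with its sampling interval.

    ``hemispheres`` optionally labels each region (e.g. "L"/"R") so synthetic
    generators can mark the block structure they imposed.
    """

    values: np.ndarray
    tr: float = DEFAULT_TR
    hemispheres: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x sample matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("region series must be finite")
        if self.tr <= 0:
            raise ValueError("sampling interval tr must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window specification in seconds."""

    length: float = 60.0
    overlap: float = 30.0

    def __post_init__(self):
        if not (0 <= self.overlap < self.length):
            raise ValueError("need 0 <= overlap < length")


def regress_confounds(series: RegionSeries, regressors=None) -> RegionSeries:
    """Replace each region series by its OLS residual against [intercept, regressors].

    With no regressors this simply demeans every region.  A rank-deficient
    design raises ``ValueError`` naming the collinear regressor columns.
    """
    n = series.n_samples
    cols = [np.ones((n, 1))]
    k = 0
    if regressors is not None:
        reg = np.atleast_2d(np.asarray(regressors, dtype=np.float64))
        if reg.shape[0] != n:
            reg = reg.T
        if reg.shape[0] != n:
            raise ValueError("regressor rows must align with samples")
        k = reg.shape[1]
        cols.append(reg)
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, rdiag = np.linalg.qr(X, mode="reduced")
        diag = np.abs(np.diag(rdiag))
        bad = np.nonzero(diag < 1e-10 * max(diag.max(), 1.0))[0]
        bad_regressors = [int(i) - 1 for i in bad if i > 0]
        raise ValueError(
            f"design matrix is rank-deficient; collinear regressor columns: {bad_regressors}"
        )
    beta, *_ = np.linalg.lstsq(X, series.values.T, rcond=None)
    resid = series.values - (X @ beta).T
    return replace(series, values=resid)


def _butter_sos(tr: float, low: float, high: float, order: int):
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency {nyquist:.4f} Hz"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")


def bandpass_array(values, tr: float, low: float, high: float, order: int = 4):
    """Zero-phase Butterworth band-pass along the last axis of ``values``."""
    sos = _butter_sos(tr, low, high, order)
    return signal.sosfiltfilt(sos, np.asarray(values, dtype=np.float64), axis=-1)


def bandpass(
    series: RegionSeries,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> RegionSeries:
    """Isolate the BOLD fluctuation band with a zero-phase Butterworth filter.

    Forward-backward application removes phase distortion; an order-4 design
    attenuates the pass band by less than 3 dB and frequencies at half the
    low cutoff or twice the high cutoff by more than 20 dB.
    """
    return replace(series, values=bandpass_array(series.values, series.tr, low, high, order))


def parcellate(voxels, labels, tr: float = DEFAULT_TR) -> RegionSeries:
    """Average voxel series into region series by integer label.

    ``labels`` maps each voxel (row of ``voxels``) to a region id in
    ``0..n_regions-1``; every region must own at least one voxel, otherwise
    ``ValueError`` lists the empty ids.
    """
    voxels = np.asarray(voxels, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if voxels.ndim != 2 or labels.shape != (voxels.shape[0],):
        raise ValueError("voxels must be voxel x sample with one label per voxel")
    n_regions = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_regions)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"regions with no voxels: {empty.tolist()}")
    out = np.zeros((n_regions, voxels.shape[1]))
    np.add.at(out, labels, voxels)
    out /= counts[:, None]
    return RegionSeries(out, tr=tr)


def sliding_windows(n_samples: int, tr: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open sample-index ranges of the rectangular sliding windows.

    Seconds convert to samples by floor: width ``w = floor(length/tr)``,
    step ``floor((length - overlap)/tr)``; windows are ``[k*step, k*step + w)``
    for every ``k`` that fits entirely inside ``n_samples``.
    """
    w = int(np.floor(spec.length / tr))
    step = int(np.floor((spec.length - spec.overlap) / tr))
    if step < 1:
        raise ValueError("window step is below one sample; reduce the overlap")
    if n_samples < w:
        raise ValueError(f"need at least {w} samples for a {spec.length} s window")
    windows = []
    start = 0
    while start + w <= n_samples:
        windows.append((start, start + w))
        start += step
    return windows


def window_correlations(series: RegionSeries, windows) -> np.ndarray:
    """Pearson correlation per region pair per window: a (W, N, N) tensor.

    Slices are symmetric with unit diagonal.  A region with zero variance
    inside a window gets all its correlations set to 0 (with a logged
    warning) but keeps the unit self-correlation.
    """
    n = series.n_regions
    tensor = np.empty((len(windows), n, n))
    for wi, (a, b) in enumerate(windows):
        if b - a < 3:
            raise ValueError(f"window {wi} has fewer than 3 samples")
        seg = series.values[:, a:b]
        sd = seg.std(axis=1)
        flat = sd == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(seg)
        if flat.any():
            logger.warning(
                "window %d: zero-variance regions %s; correlations set to 0",
                wi,
                np.nonzero(flat)[0].tolist(),
            )
            corr[flat, :] = 0.0
            corr[:, flat] = 0.0
        corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        tensor[wi] = corr
    return tensor


def threshold(tensor, tau: float) -> TemporalGraph:
    """Binarize a correlation tensor: edge iff ``r_ij(t) > tau`` (strict), no diagonal."""
    tensor = np.asarray(tensor, dtype=np.float64)
    if not (-1.0 < tau < 1.0):
        raise ValueError("threshold tau must lie in (-1, 1)")
    adj = (tensor > tau).astype(np.uint8)
    for t in range(adj.shape[0]):
        np.fill_diagonal(adj[t], 0)
    return TemporalGraph(adj, validate=False)


def default_thresholds() -> list[float]:
    """The printed grid: 0.20..0.90 step 0.05 plus 0.92..0.98 step 0.02."""
    coarse = np.arange(0.20, 0.9001, 0.05)
    fine = np.arange(0.92, 0.9801, 0.02)
    return [round(float(t), 2) for t in np.concatenate([coarse, fine])]


@dataclass
class PipelineResult:
    """Outcome of :func:`run_pipeline`: one graph per threshold plus provenance."""

    graphs: list[TemporalGraph]
    thresholds: list[float]
    windows: list[tuple[int, int]]
    correlations: np.ndarray = field(repr=False)


def run_pipeline(
    series: RegionSeries | None = None,
    voxels=None,
    labels=None,
    regressors=None,
    tr: float = DEFAULT_TR,
    window: WindowSpec = WindowSpec(),
    band: tuple[float, float] = DEFAULT_BAND,
    thresholds: list[float] | None = None,
) -> PipelineResult:
    """Run confound regression → band-pass → (parcellation) → windows → Pearson → thresholds.

    Accepts either region-level ``series`` or a voxel matrix plus an integer
    label vector.  Deterministic: identical inputs and configuration give
    bit-identical graphs.
    """
    if (series is None) == (voxels is None):
        raise ValueError("provide exactly one of series= or voxels=")
    if voxels is not None:
        if labels is None:
            raise ValueError("voxel input needs a labels vector")
        data = RegionSeries(np.asarray(voxels, dtype=np.float64), tr=tr)
    else:
        data = series
    data = regress_confounds(data, regressors)
    data = bandpass(data, *band)
    if voxels is not None:
        data = parcellate(data.values, labels, tr=data.tr)
    wins = sliding_windows(data.n_samples, data.tr, window)
    tensor = window_correlations(data, wins)
    taus = default_thresholds() if thresholds is None else list(thresholds)
    graphs = [threshold(tensor, tau) for tau in taus]
    return PipelineResult(graphs=graphs, thresholds=taus, windows=wins, correlations=tensor)
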