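"""Calibrating null-model parameters to empirical small-worldness curves.

A small-worldness curve pairs average degrees with the statistic value
(S = C/L or S_SB = TC/L) observed there, compared by linear interpolation.
Two calibration routes are provided:

* per-degree matching — for each requested average degree, the connection
  radius (``r`` for square/torus, ``R`` for hyperbolic) is bisected until
  the generated graphs hit the degree, exploiting monotonicity (degree
  increases with ``r`` and decreases with ``R``);
* area minimization — a grid search over the free parameters (``v``, plus
  ``alpha`` for the hyperbolic model) picks the candidate whose sweep curve
  minimizes the area between curves over the evaluation range.

Curve discrepancies are summarized by four norms evaluated on an equispaced
grid (by default 16,861 points on [0, 170], matching how such comparisons
are reported): minimum and maximum absolute difference, mean absolute
difference, and the "mean Euclidean distance" ``||d||_2 / n`` — the
Euclidean norm of the differences divided by the number of points (an RMS
variant ``||d||_2 / sqrt(n)`` is available via ``euclidean="rms"``).  The
area is the exact integral of the absolute difference between the two
piecewise-linear curves.

Replicate statistic values are aggregated by the median; the first and
third quartiles are carried along as a spread band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import null_models
from .measures import small_worldness
from .null_models import GeometricParams, HyperbolicParams

__all__ = [
    "SWCurve",
    "CurveDistance",
    "FitResult",
    "interpolate",
    "curve_distance",
    "calibrate_degree",
    "sweep_curve",
    "fit_parameters",
    "SmallWorldnessFit",
]

#: Default evaluation grid for curve comparisons: (lo, hi, n_points).
DEFAULT_GRID = (0.0, 170.0, 16_861)


@dataclass
class SWCurve:
    """A small-worldness curve: (average degree, value) knots, linearly interpolated."""

    degrees: np.ndarray
    values: np.ndarray
    statistic: str = "S"
    q1: np.ndarray | None = field(default=None, repr=False)
    q3: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.degrees = np.asarray(self.degrees, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.degrees.ndim != 1 or self.degrees.shape != self.values.shape:
            raise ValueError("degrees and values must be matching 1-D arrays")
        if len(self.degrees) >= 2 and not (np.diff(self.degrees) > 0).all():
            raise ValueError("degrees must be strictly increasing")
        if not (np.isfinite(self.degrees).all() and np.isfinite(self.values).all()):
            raise ValueError("curve knots must be finite")

    def __call__(self, x):
        return interpolate(self, x)

    @classmethod
    def from_points(cls, points, statistic: str = "S") -> "SWCurve":
        pts = sorted((float(d), float(v)) for d, v in points)
        return cls(
            degrees=np.array([d for d, _ in pts]),
            values=np.array([v for _, v in pts]),
            statistic=statistic,
        )


def interpolate(curve: SWCurve, x):
    """Piecewise-linear value of the curve at ``x``; no extrapolation."""
    if len(curve.degrees) < 2:
        raise ValueError("interpolation needs at least 2 knots")
    x = np.asarray(x, dtype=np.float64)
    lo, hi = curve.degrees[0], curve.degrees[-1]
    if (x < lo).any() or (x > hi).any():
        raise ValueError(f"query outside the curve's degree range [{lo}, {hi}]")
    out = np.interp(x, curve.degrees, curve.values)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CurveDistance:
    """The four reporting norms plus the area between two curves."""

    minimum: float
    maximum: float
    mean_absolute: float
    mean_euclidean: float
    area: float

    def as_dict(self) -> dict:
        return {
            "minimum": self.minimum,
            "maximum": self.maximum,
            "mean_absolute": self.mean_absolute,
            "mean_euclidean": self.mean_euclidean,
            "area": self.area,
        }


def _area_between(a: SWCurve, b: SWCurve, lo: float, hi: float) -> float:
    """Exact integral of |a - b| on [lo, hi] (difference is piecewise linear)."""
    knots = np.unique(np.concatenate([a.degrees, b.degrees, [lo, hi]]))
    knots = knots[(knots >= lo) & (knots <= hi)]
    d = a(knots) - b(knots)
    total = 0.0
    for (x0, x1), (d0, d1) in zip(
        zip(knots[:-1], knots[1:]), zip(d[:-1], d[1:])
    ):
        if d0 * d1 < 0:  # sign change: split at the root
            xr = x0 + (x1 - x0) * d0 / (d0 - d1)
            total += abs(d0) * (xr - x0) / 2.0 + abs(d1) * (x1 - xr) / 2.0
        else:
            total += (abs(d0) + abs(d1)) * (x1 - x0) / 2.0
    return float(total)


def curve_distance(
    a: SWCurve,
    b: SWCurve,
    grid: tuple[float, float, int] = DEFAULT_GRID,
    euclidean: str = "scaled",
) -> CurveDistance:
    """Norms of the pointwise difference on an equispaced grid, plus the exact area.

    Both curves must cover the grid range.  ``euclidean="scaled"`` divides the
    Euclidean norm of the differences by the number of points; ``"rms"``
    divides by its square root.
    """
    lo, hi, n = grid
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    for c in (a, b):
        if c.degrees[0] > lo or c.degrees[-1] < hi:
            raise ValueError(
                f"curve covers [{c.degrees[0]}, {c.degrees[-1]}], "
                f"not the evaluation range [{lo}, {hi}]"
            )
    xs = np.linspace(lo, hi, n)
    d = a(xs) - b(xs)
    absd = np.abs(d)
    if euclidean == "scaled":
        eu = float(np.linalg.norm(d)) / n
    elif euclidean == "rms":
        eu = float(np.linalg.norm(d)) / np.sqrt(n)
    else:
        raise ValueError("euclidean must be 'scaled' or 'rms'")
    return CurveDistance(
        minimum=float(absd.min()),
        maximum=float(absd.max()),
        mean_absolute=float(absd.mean()),
        mean_euclidean=eu,
        area=_area_between(a, b, lo, hi),
    )


# ---------------------------------------------------------------------------
# Degree calibration


def _build_params(model: str, params: dict, radius: float, n_steps: int | None = None):
    p = dict(params)
    if n_steps is not None:
        p["n_steps"] = n_steps
    if model in ("rts", "rtt"):
        return GeometricParams(
            n_nodes=p["n_nodes"], n_steps=p["n_steps"], r=radius, v=p.get("v", 0.0)
        )
    if model == "rth":
        return HyperbolicParams(
            n_nodes=p["n_nodes"],
            n_steps=p["n_steps"],
            alpha=p["alpha"],
            R=radius,
            v=p.get("v", 0.0),
            zeta=p.get("zeta", 1.0),
        )
    raise ValueError(f"unknown geometric model {model!r}")


#: Snapshot count used while calibrating (the positional marginal is
#: stationary, so the expected per-snapshot degree does not depend on T).
_CALIBRATION_STEPS = 6


def _mean_degree(model: str, params: dict, radius: float, seeds) -> float:
    degs = [
        null_models.generate(
            model,
            _build_params(model, params, radius,
                          n_steps=min(params["n_steps"], _CALIBRATION_STEPS)),
            int(s),
        ).average_degree()
        for s in seeds
    ]
    return float(np.mean(degs))


def calibrate_degree(
    model: str,
    params: dict,
    target: float,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 40,
    replicates: int = 12,
) -> float:
    """Bisect the connection radius until the expected average degree hits ``target``.

    Uses common random numbers (the same replicate seeds at every radius) so
    the estimated degree is a stable monotone function of the radius:
    increasing in ``r`` for square/torus, decreasing in ``R`` for the
    hyperbolic disk.  Stops at relative tolerance ``tol`` or after
    ``max_iter`` bisections.  Raises if the target is outside the achievable
    range, reporting the achievable bounds.

    Because the positional marginal of every movement rule is stationary,
    the expected degree does not depend on the speed ``v``; the calibrated
    radius is therefore a function of the model, the node count, the radial
    spread and the target only, and a fixed ``seed`` makes it deterministic —
    curves swept with the same calibration seed share radii exactly, which
    removes calibration noise from curve comparisons.
    """
    n = params["n_nodes"]
    if not (0 <= target <= n - 1):
        raise ValueError(f"target degree must lie in [0, {n - 1}]")
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    if model in ("rts", "rtt"):
        lo, hi = 1e-9, (np.sqrt(2.0) if model == "rts" else np.sqrt(2.0) / 2.0) * 1.01
        increasing = True
    elif model == "rth":
        lo, hi = 0.05, 5.0
        # expand until the bracket straddles the target (degree decreases in R)
        while _mean_degree(model, params, hi, seeds) > target and hi < 400.0:
            hi *= 2.0
        increasing = False
    else:
        raise ValueError(f"unknown geometric model {model!r}")
    d_lo = _mean_degree(model, params, lo, seeds)
    d_hi = _mean_degree(model, params, hi, seeds)
    d_min, d_max = sorted((d_lo, d_hi))
    if not (d_min <= target <= d_max) and target > 0:
        raise ValueError(
            f"target degree {target} outside achievable range "
            f"[{d_min:.3f}, {d_max:.3f}] for model {model}"
        )
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        d_mid = _mean_degree(model, params, mid, seeds)
        if target > 0 and abs(d_mid - target) <= tol * target:
            return mid
        if (d_mid < target) == increasing:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


_calibration_cache: dict[tuple, float] = {}


def _calibrate_cached(model: str, params: dict, target: float) -> float:
    """Calibrated radius under the fixed calibration stream, memoized.

    The key deliberately excludes the speed ``v`` (stationarity makes the
    expected degree independent of it), so sweeps over speed candidates
    reuse one calibration per (model, n_nodes, spread, target).
    """
    key = (
        model,
        params["n_nodes"],
        params.get("alpha"),
        params.get("zeta", 1.0),
        round(float(target), 9),
    )
    if key not in _calibration_cache:
        _calibration_cache[key] = calibrate_degree(model, params, target, seed=0)
    return _calibration_cache[key]


def _statistic(report, statistic: str) -> float:
    if statistic == "S":
        return report.S
    if statistic in ("S_SB", "SSB"):
        return report.S_SB
    raise ValueError("statistic must be 'S' or 'S_SB'")


def sweep_curve(
    model: str,
    params: dict,
    degrees,
    replicates: int = 20,
    statistic: str = "S",
    seed: int = 0,
    unreachable: str = "cap",
) -> SWCurve:
    """Median small-worldness per calibrated average degree → an :class:`SWCurve`.

    For each target degree the radius is calibrated, ``replicates`` graphs
    are generated, and the median (with first/third quartiles) of the
    statistic is recorded.
    """
    degrees = sorted(float(d) for d in degrees)
    rep_seeds = np.random.SeedSequence(seed).generate_state(
        replicates * len(degrees)
    ) % (2**31)
    med, q1s, q3s = [], [], []
    for di, deg in enumerate(degrees):
        radius = _calibrate_cached(model, params, deg)
        full = _build_params(model, params, radius)
        vals = []
        for ri in range(replicates):
            g = null_models.generate(model, full, int(rep_seeds[di * replicates + ri]))
            vals.append(_statistic(small_worldness(g, unreachable=unreachable), statistic))
        med.append(float(np.median(vals)))
        q1s.append(float(np.percentile(vals, 25)))
        q3s.append(float(np.percentile(vals, 75)))
    return SWCurve(
        degrees=np.array(degrees),
        values=np.array(med),
        statistic=statistic,
        q1=np.array(q1s),
        q3=np.array(q3s),
    )


@dataclass
class FitResult:
    """Outcome of a parameter fit: winning parameters, norms, and diagnostics."""

    model: str
    params: dict
    area: float
    norms: CurveDistance
    grid: tuple[float, float, int]
    curve: SWCurve = field(repr=False)
    candidates: list[tuple[dict, CurveDistance]] = field(default_factory=list, repr=False)

    def summary(self) -> str:
        lines = [
            f"Small-worldness fit: model={self.model}  statistic={self.curve.statistic}",
            f"evaluation grid: {self.grid[2]} points on [{self.grid[0]}, {self.grid[1]}]",
            "-" * 62,
            "fitted parameters: "
            + ", ".join(f"{k}={v}" for k, v in self.params.items()),
            f"{'area between curves':28s} {self.area:.6g}",
            f"{'minimum |difference|':28s} {self.norms.minimum:.6g}",
            f"{'maximum |difference|':28s} {self.norms.maximum:.6g}",
            f"{'mean absolute difference':28s} {self.norms.mean_absolute:.6g}",
            f"{'mean Euclidean distance':28s} {self.norms.mean_euclidean:.6g}",
            f"candidates evaluated: {len(self.candidates)}",
        ]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "area": self.area,
            "norms": self.norms.as_dict(),
            "grid": list(self.grid),
            "curve": {
                "degrees": self.curve.degrees.tolist(),
                "values": self.curve.values.tolist(),
                "statistic": self.curve.statistic,
            },
        }


def _expand_grid(parameter_grid: dict) -> list[dict]:
    keys = sorted(parameter_grid)
    combos = itertools.product(*(parameter_grid[k] for k in keys))
    return [dict(zip(keys, c)) for c in combos]


def fit_parameters(
    model: str,
    empirical: SWCurve,
    parameter_grid: dict,
    statistic: str = "S",
    grid: tuple[float, float, int] | None = None,
    degrees=None,
    replicates: int = 20,
    seed: int = 0,
    base_params: dict | None = None,
) -> FitResult:
    """Grid-search the free parameters minimizing the area between curves.

    ``parameter_grid`` maps parameter names (``v``, and ``alpha`` for the
    hyperbolic model) to candidate values; every combination is swept over
    the target ``degrees`` (default: the empirical curve's knots) and scored
    against ``empirical`` on the evaluation ``grid`` (default: the empirical
    degree range at 200 points).  Ties break by smaller mean absolute
    difference, then lexicographic parameter order.
    """
    if not parameter_grid or any(len(v) == 0 for v in parameter_grid.values()):
        raise ValueError("parameter grid must be nonempty")
    if degrees is None:
        degrees = empirical.degrees
    if grid is None:
        grid = (float(min(degrees)), float(max(degrees)), 200)
    base = dict(base_params or {})
    candidates = _expand_grid(parameter_grid)
    results: list[tuple[dict, CurveDistance, SWCurve]] = []
    for cand in candidates:
        params = {**base, **cand}
        curve = sweep_curve(
            model, params, degrees, replicates=replicates, statistic=statistic, seed=seed
        )
        dist = curve_distance(empirical, curve, grid)
        results.append((cand, dist, curve))

    def sort_key(item):
        cand, dist, _ = item
        return (dist.area, dist.mean_absolute, tuple(cand[k] for k in sorted(cand)))

    best_cand, best_dist, best_curve = min(results, key=sort_key)
    return FitResult(
        model=model,
        params={**base, **best_cand},
        area=best_dist.area,
        norms=best_dist,
        grid=grid,
        curve=best_curve,
        candidates=[(c, d) for c, d, _ in results],
    )


class SmallWorldnessFit:
    """Model-style front end: bind an empirical curve, then ``fit`` a parameter grid.

    Mirrors the model/results idiom: the constructor holds the data (the
    empirical small-worldness curve) and the fit configuration; ``fit()``
    runs the grid search and returns a :class:`FitResult` whose ``summary()``
    prints the fitted parameters and all reporting norms.
    """

    def __init__(
        self,
        empirical: SWCurve,
        model: str = "rth",
        statistic: str = "S",
        degrees=None,
        replicates: int = 20,
        grid: tuple[float, float, int] | None = None,
        base_params: dict | None = None,
    ):
        self.empirical = empirical
        self.model = model
        self.statistic = statistic
        self.degrees = degrees
        self.replicates = replicates
        self.grid = grid
        self.base_params = base_params or {}

    def fit(self, parameter_grid: dict, seed: int = 0) -> FitResult:
        return fit_parameters(
            self.model,
            self.empirical,
            parameter_grid,
            statistic=self.statistic,
            grid=self.grid,
            degrees=self.degrees,
            replicates=self.replicates,
            seed=seed,
            base_params=self.base_params,
        )
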