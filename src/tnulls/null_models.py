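"""Temporal random-graph null models.

Two data-based randomizations and three synthetic geometric generators:

* **RTPT** — randomly permuted times: the timestamps of an empirical
  temporal graph are shuffled, destroying temporal structure while
  conserving which pairs interact and how often.
* **RTE** — randomized edges: within each time step one endpoint of every
  contact is reassigned through a uniform node permutation.
* **RTS / RTT** — random temporal square / torus: nodes are uniform points
  on the unit square (or its periodic closure, the flat torus), connected
  when closer than a radius ``r``, and moved each step by a random
  displacement of direction Uniform[0, 2π) and length Uniform(0, v).
* **RTH** — random temporal hyperbolic: nodes are quasi-uniform points in a
  radius-``R`` disk of the hyperbolic plane of curvature ``-ζ²`` (angular
  density 1/2π, radial density ``ρ(r) = α sinh(αr) / (cosh(αR) - 1)``),
  connected when their hyperbolic distance is below ``R``; between steps the
  angle drifts by Uniform(0, v) and the radius performs a reflected random
  walk in CDF space so that the positional marginal is stationary.

Every stochastic operation takes an explicit seed (or an already-spawned
``numpy.random.Generator``) so runs are reproducible; the position-sampling
and movement streams of a generator run come from one generator consumed in
a fixed documented order (initial positions first, then one move per step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .temporal_graph import TemporalGraph

__all__ = [
    "GeometricParams",
    "HyperbolicParams",
    "permuted_times",
    "randomized_edges",
    "sample_square_positions",
    "torus_distance",
    "geometric_snapshot",
    "move_square",
    "move_torus",
    "sample_hyperbolic_positions",
    "hyperbolic_distance",
    "move_hyperbolic",
    "generate",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class GeometricParams:
    """Parameters of the RTS/RTT generators (unit square or flat torus)."""

    n_nodes: int
    n_steps: int
    r: float  # connection radius
    v: float = 0.0  # per-step displacement scale

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_steps < 1:
            raise ValueError("n_nodes and n_steps must be positive")
        if self.r <= 0:
            raise ValueError("connection radius r must be > 0")
        if self.v < 0:
            raise ValueError("speed v must be >= 0")


@dataclass(frozen=True)
class HyperbolicParams:
    """Parameters of the RTH generator.

    ``zeta`` is the curvature scale (default 1: only the ratio ``alpha/zeta``
    matters for the graph distribution), ``alpha`` controls the radial
    spread (``alpha == zeta`` gives the quasi-uniform disk), ``R`` is both
    the disk radius and the connection threshold, and ``v`` the per-step
    movement scale.
    """

    n_nodes: int
    n_steps: int
    alpha: float
    R: float
    v: float = 0.0
    zeta: float = 1.0

    def __post_init__(self):
        if self.n_nodes < 1 or self.n_steps < 1:
            raise ValueError("n_nodes and n_steps must be positive")
        if self.alpha <= 0 or self.R <= 0 or self.zeta <= 0:
            raise ValueError("alpha, R and zeta must be > 0")
        if self.v < 0:
            raise ValueError("speed v must be >= 0")


# ---------------------------------------------------------------------------
# Data-based randomizations


def permuted_times(g: TemporalGraph, seed, mode: str = "contacts") -> TemporalGraph:
    """RTPT null model: shuffle *when* contacts happen.

    ``mode="contacts"`` (default) uniformly permutes the timestamp multiset
    across individual contacts; should the shuffle propose a duplicate
    contact, colliding timestamps are swapped with random partners until the
    contact set is duplicate-free, so the contact count, the per-pair
    multiplicities and the timestamp multiset are conserved exactly.
    ``mode="snapshots"`` applies a single permutation to the snapshot order
    instead (whole time slices are reordered).
    """
    rng = _rng(seed)
    if mode == "snapshots":
        perm = rng.permutation(g.n_steps)
        return TemporalGraph(g.tensor[perm], validate=False)
    if mode != "contacts":
        raise ValueError("mode must be 'contacts' or 'snapshots'")
    contacts = g.to_contacts()
    m = len(contacts)
    if m == 0:
        return g.copy()
    uv = np.array([(u, v) for u, v, _ in contacts], dtype=np.int64)
    times = np.array([t for _, _, t in contacts], dtype=np.int64)
    times = times[rng.permutation(m)]
    key_base = np.int64(g.n_steps)
    pair_key = (uv[:, 0] * g.n_nodes + uv[:, 1]) * key_base
    for _ in range(10_000):
        keys = pair_key + times
        order = np.argsort(keys, kind="stable")
        dup = np.zeros(m, dtype=bool)
        dup[order[1:]] = keys[order[1:]] == keys[order[:-1]]
        idx = np.nonzero(dup)[0]
        if idx.size == 0:
            break
        partners = rng.integers(0, m, size=idx.size)
        for i, j in zip(idx, partners):
            times[i], times[j] = times[j], times[i]
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not resolve timestamp collisions")
    triples = [(int(u), int(v), int(t)) for (u, v), t in zip(uv, times)]
    return TemporalGraph.from_contacts(triples, g.n_nodes, g.n_steps)


def randomized_edges(g: TemporalGraph, seed, permutations=None) -> TemporalGraph:
    """RTE null model: rewire one endpoint of every contact within each step.

    For each time step an independent uniform permutation ``σ_t`` of the
    node set is sampled and each contact ``(u, v, t)`` (stored with
    ``u < v``) becomes ``(u, σ_t(v), t)``.  Self-loops produced by the
    rewiring are dropped and duplicate edges collapse, so per-step edge
    counts never increase.  ``permutations`` injects explicit per-step
    permutations (testing hook / custom rewiring).
    """
    rng = _rng(seed)
    out = np.zeros_like(g.tensor)
    for t in range(g.n_steps):
        sigma = (
            np.asarray(permutations[t])
            if permutations is not None
            else rng.permutation(g.n_nodes)
        )
        us, vs = np.nonzero(np.triu(g.tensor[t], 1))
        if us.size == 0:
            continue
        nv = sigma[vs]
        keep = us != nv
        a = np.minimum(us[keep], nv[keep])
        b = np.maximum(us[keep], nv[keep])
        out[t, a, b] = 1
        out[t, b, a] = 1
    return TemporalGraph(out, validate=False)


# ---------------------------------------------------------------------------
# Square / torus geometry


def sample_square_positions(n: int, seed) -> np.ndarray:
    """``n`` i.i.d. uniform points on the unit square, as an ``(n, 2)`` array."""
    if n < 1:
        raise ValueError("need n >= 1")
    return _rng(seed).random((n, 2))


def torus_distance(p, q) -> np.ndarray:
    """Wrap-around distance on the flat torus ``[0, 1]^2`` (elementwise on stacks).

    ``d = sqrt((1/2 - |1/2 - |xA - xB||)^2 + (1/2 - |1/2 - |yA - yB||)^2)``,
    i.e. the per-axis difference is folded to ``min(|Δ|, 1 - |Δ|)``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    delta = np.abs(p - q)
    folded = 0.5 - np.abs(0.5 - delta)
    return np.sqrt((folded**2).sum(axis=-1))


def _pairwise_square(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _pairwise_torus(positions: np.ndarray) -> np.ndarray:
    delta = np.abs(positions[:, None, :] - positions[None, :, :])
    folded = 0.5 - np.abs(0.5 - delta)
    return np.sqrt((folded**2).sum(axis=-1))


def geometric_snapshot(positions, r: float, metric: str = "square") -> np.ndarray:
    """Adjacency of the geometric graph: edge iff distance strictly below ``r``."""
    positions = np.asarray(positions, dtype=np.float64)
    if metric == "square":
        d = _pairwise_square(positions)
    elif metric == "torus":
        d = _pairwise_torus(positions)
    else:
        raise ValueError("metric must be 'square' or 'torus'")
    a = (d < r).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return a


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Fold real values into [0, 1] by billiard reflection at 0 and 1."""
    y = np.mod(x, 2.0)
    return np.where(y > 1.0, 2.0 - y, y)


def _displacement(n: int, v: float, rng: np.random.Generator) -> np.ndarray:
    angle = rng.uniform(0.0, 2.0 * np.pi, size=n)
    length = rng.uniform(0.0, v, size=n) if v > 0 else np.zeros(n)
    return np.column_stack([length * np.cos(angle), length * np.sin(angle)])


def move_square(positions, v: float, seed) -> np.ndarray:
    """One movement step on the unit square; overshoots reflect off the walls."""
    positions = np.asarray(positions, dtype=np.float64)
    if v < 0:
        raise ValueError("speed v must be >= 0")
    return _reflect_unit(positions + _displacement(len(positions), v, _rng(seed)))


def move_torus(positions, v: float, seed) -> np.ndarray:
    """One movement step on the torus; coordinates wrap modulo 1."""
    positions = np.asarray(positions, dtype=np.float64)
    if v < 0:
        raise ValueError("speed v must be >= 0")
    return np.mod(positions + _displacement(len(positions), v, _rng(seed)), 1.0)


# ---------------------------------------------------------------------------
# Hyperbolic geometry


def radial_cdf(r, alpha: float, R: float):
    """CDF of the radial density ``ρ(r) = α sinh(αr) / (cosh(αR) - 1)`` on [0, R]."""
    return (np.cosh(alpha * np.asarray(r, dtype=np.float64)) - 1.0) / (
        np.cosh(alpha * R) - 1.0
    )


def radial_inverse_cdf(u, alpha: float, R: float):
    """Inverse radial CDF: ``r = acosh(1 + u (cosh(αR) - 1)) / α``."""
    u = np.asarray(u, dtype=np.float64)
    return np.arccosh(1.0 + u * (np.cosh(alpha * R) - 1.0)) / alpha


def sample_hyperbolic_positions(params: HyperbolicParams, seed) -> np.ndarray:
    """``(n, 2)`` polar positions ``(r, θ)``: θ uniform, r by inverse-CDF sampling."""
    rng = _rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=params.n_nodes)
    u = rng.random(params.n_nodes)
    r = radial_inverse_cdf(u, params.alpha, params.R)
    return np.column_stack([r, theta])


def _angular_difference(a, b):
    return np.pi - np.abs(np.pi - np.abs(a - b) % (2.0 * np.pi))


def hyperbolic_distance(p, q, zeta: float = 1.0):
    """Hyperbolic geodesic distance between polar points in curvature ``-ζ²``.

    ``d = (1/ζ) acosh(cosh(ζ r_u) cosh(ζ r_v) - sinh(ζ r_u) sinh(ζ r_v) cos Δθ)``
    with ``Δθ = π - |π - |θ_u - θ_v||``; the acosh argument is clamped to 1
    against rounding below it.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    ru, tu = p[..., 0], p[..., 1]
    rv, tv = q[..., 0], q[..., 1]
    dtheta = _angular_difference(tu, tv)
    arg = np.cosh(zeta * ru) * np.cosh(zeta * rv) - np.sinh(zeta * ru) * np.sinh(
        zeta * rv
    ) * np.cos(dtheta)
    # coincident points can give arg = 1 ± few ulp; clamp those to distance 0
    arg = np.where(arg < 1.0 + 1e-12, 1.0, arg)
    return np.arccosh(arg) / zeta


def _hyperbolic_snapshot(positions: np.ndarray, params: HyperbolicParams) -> np.ndarray:
    r, theta = positions[:, 0], positions[:, 1]
    z = params.zeta
    ch, sh = np.cosh(z * r), np.sinh(z * r)
    dtheta = _angular_difference(theta[:, None], theta[None, :])
    arg = ch[:, None] * ch[None, :] - sh[:, None] * sh[None, :] * np.cos(dtheta)
    d = np.arccosh(np.maximum(arg, 1.0)) / z
    a = (d < params.R).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return a


def move_hyperbolic(
    positions,
    v: float,
    params: HyperbolicParams,
    seed,
    symmetric_drift: bool = False,
) -> np.ndarray:
    """One movement step in the hyperbolic disk.

    The angle gains Uniform(0, v) (or Uniform(-v/2, v/2) with
    ``symmetric_drift``) modulo 2π.  The radius is updated in CDF space:
    ``u = F(r)`` is uniform on [0, 1], a Uniform(-v, v) increment is added
    and reflected back into [0, 1], and ``r = F⁻¹(u)`` — which guarantees
    the per-step radial marginal stays exactly ``ρ(r)``.
    """
    positions = np.asarray(positions, dtype=np.float64)
    if v < 0:
        raise ValueError("speed v must be >= 0")
    rng = _rng(seed)
    n = len(positions)
    if symmetric_drift:
        drift = rng.uniform(-v / 2.0, v / 2.0, size=n) if v > 0 else np.zeros(n)
    else:
        drift = rng.uniform(0.0, v, size=n) if v > 0 else np.zeros(n)
    theta = np.mod(positions[:, 1] + drift, 2.0 * np.pi)
    u = radial_cdf(positions[:, 0], params.alpha, params.R)
    step = rng.uniform(-v, v, size=n) if v > 0 else np.zeros(n)
    u = _reflect_unit(u + step)
    r = radial_inverse_cdf(u, params.alpha, params.R)
    return np.column_stack([r, theta])


# ---------------------------------------------------------------------------
# Generator driver


def generate(model: str, params, seed, symmetric_drift: bool = False) -> TemporalGraph:
    """Generate a synthetic temporal graph (``model`` in {"rts", "rtt", "rth"}).

    Snapshot ``t`` is the geometric graph of the positions at step ``t``;
    positions evolve by the model's movement rule between snapshots.  With
    ``v = 0`` all snapshots are identical.
    """
    rng = _rng(seed)
    model = model.lower()
    if model in ("rts", "rtt"):
        if not isinstance(params, GeometricParams):
            params = GeometricParams(**params)
        metric = "square" if model == "rts" else "torus"
        mover = move_square if model == "rts" else move_torus
        pos = sample_square_positions(params.n_nodes, rng)
        snaps = np.empty(
            (params.n_steps, params.n_nodes, params.n_nodes), dtype=np.uint8
        )
        for t in range(params.n_steps):
            snaps[t] = geometric_snapshot(pos, params.r, metric)
            if t < params.n_steps - 1:
                pos = mover(pos, params.v, rng)
        return TemporalGraph(snaps, validate=False)
    if model == "rth":
        if not isinstance(params, HyperbolicParams):
            params = HyperbolicParams(**params)
        pos = sample_hyperbolic_positions(params, rng)
        snaps = np.empty(
            (params.n_steps, params.n_nodes, params.n_nodes), dtype=np.uint8
        )
        for t in range(params.n_steps):
            snaps[t] = _hyperbolic_snapshot(pos, params)
            if t < params.n_steps - 1:
                pos = move_hyperbolic(
                    pos, params.v, params, rng, symmetric_drift=symmetric_drift
                )
        return TemporalGraph(snaps, validate=False)
    raise ValueError(f"unknown geometric model {model!r}")
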