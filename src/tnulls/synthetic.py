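"""Synthetic inputs: BOLD-like region signals and small worked-example graphs.

``simulate_bold`` emulates the statistical structure resting-state region
series exhibit once ordered hemisphere-by-hemisphere: strong
intra-hemispheric block correlation, an extra homotopic-pair correlation
between each region and its mirror in the opposite hemisphere, and
band-limited Gaussian fluctuations confined to the slow BOLD band.  It does
not model hemodynamics, spatial structure or scanner artifacts — it exists
so the full extraction pipeline is exercisable without any imaging data.

The fixture builders reproduce the printed worked examples used throughout
the measure definitions: a static five-node star (persistence 1, clustering
0), a six-node alternation of a closed and an open triplet on disjoint node
sets (persistence 0, clustering 0.5), and the static open/closed-triplet
and hub graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import DEFAULT_BAND, DEFAULT_TR, RegionSeries, bandpass_array
from .temporal_graph import TemporalGraph

__all__ = [
    "BoldSimConfig",
    "target_correlation",
    "simulate_bold",
    "star_fixture",
    "alternating_triplet_fixture",
    "triplet_fixtures",
    "TripletFixtures",
]


@dataclass(frozen=True)
class BoldSimConfig:
    """Configuration of the synthetic BOLD generator.

    ``n_regions`` must be even: the first half is the "left" hemisphere, the
    second half the "right", and region ``i`` is homotopic to
    ``i + n_regions/2``.  Correlation targets must leave the implied target
    matrix positive definite (roughly ``within + homotopic < 1``).
    """

    n_regions: int = 302
    n_samples: int = 1200
    tr: float = DEFAULT_TR
    within_hemisphere_rho: float = 0.5
    homotopic_rho: float = 0.35
    noise_sd: float = 1.0
    band: tuple[float, float] = DEFAULT_BAND
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be even and >= 2")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (0 <= self.within_hemisphere_rho < 1):
            raise ValueError("within_hemisphere_rho must be in [0, 1)")
        if not (0 <= self.homotopic_rho < 1):
            raise ValueError("homotopic_rho must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def target_correlation(config: BoldSimConfig) -> np.ndarray:
    """The block target correlation matrix the generator imposes."""
    n = config.n_regions
    half = n // 2
    sigma = np.zeros((n, n))
    for lo in (0, half):
        sigma[lo : lo + half, lo : lo + half] = config.within_hemisphere_rho
    idx = np.arange(half)
    sigma[idx, idx + half] = config.homotopic_rho
    sigma[idx + half, idx] = config.homotopic_rho
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_bold(config: BoldSimConfig) -> RegionSeries:
    """Draw band-limited Gaussian region series with the target block correlation.

    White noise is band-pass filtered with the same zero-phase contract the
    pipeline applies, standardized, and mixed through the Cholesky factor of
    the target matrix, so the empirical correlations converge to the targets
    as ``n_samples`` grows.  Deterministic per seed.
    """
    sigma = target_correlation(config)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            "target correlation matrix is not positive definite; "
            "reduce within_hemisphere_rho and/or homotopic_rho"
        ) from None
    rng = np.random.default_rng(config.seed)
    pad = 200  # filter warm-up samples trimmed from both ends
    z = rng.standard_normal((config.n_regions, config.n_samples + 2 * pad))
    z = bandpass_array(z, config.tr, *config.band)[:, pad : pad + config.n_samples]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    values = config.noise_sd * (chol @ z)
    half = config.n_regions // 2
    return RegionSeries(values, tr=config.tr, hemispheres=["L"] * half + ["R"] * half)


# ---------------------------------------------------------------------------
# Worked-example fixtures


def star_fixture(T: int = 4) -> TemporalGraph:
    """Five-node star (center 0, leaves 1-4) repeated unchanged for ``T`` steps."""
    if T < 2:
        raise ValueError("need T >= 2")
    contacts = [(0, leaf, t) for t in range(T) for leaf in range(1, 5)]
    return TemporalGraph.from_contacts(contacts, n_nodes=5, n_steps=T)


def alternating_triplet_fixture(T: int = 4) -> TemporalGraph:
    """Closed triplet on {0,1,2} at even steps, open triplet on {3,4,5} at odd steps.

    Consecutive snapshots share neither edges nor active nodes, so the
    temporal correlation coefficient is 0 while the clustering coefficient
    alternates between 1 and 0 (time average 0.5).  ``T`` must be even.
    """
    if T < 2 or T % 2:
        raise ValueError("need an even T >= 2")
    triangle = [(0, 1), (0, 2), (1, 2)]
    path = [(3, 4), (4, 5)]
    contacts = [
        (u, v, t)
        for t in range(T)
        for u, v in (triangle if t % 2 == 0 else path)
    ]
    return TemporalGraph.from_contacts(contacts, n_nodes=6, n_steps=T)


@dataclass(frozen=True)
class TripletFixtures:
    """Static worked-example graphs (adjacency matrices).

    ``hub_none/hub_one/hub_all``: node 0 has three neighbours with 0, 1 and
    all 3 links among them, giving local clustering 0, 1/3 and 1.
    """

    open_triplet: np.ndarray
    closed_triplet: np.ndarray
    hub_none: np.ndarray
    hub_one: np.ndarray
    hub_all: np.ndarray


def _adj(n: int, edges) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    return a


def triplet_fixtures() -> TripletFixtures:
    hub = [(0, 1), (0, 2), (0, 3)]
    return TripletFixtures(
        open_triplet=_adj(3, [(0, 1), (1, 2)]),
        closed_triplet=_adj(3, [(0, 1), (1, 2), (0, 2)]),
        hub_none=_adj(4, hub),
        hub_one=_adj(4, hub + [(1, 2)]),
        hub_all=_adj(4, hub + [(1, 2), (1, 3), (2, 3)]),
    )
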