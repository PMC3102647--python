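"""Lattice Monte Carlo of phantom semiflexible chains with flexible hinges.

The physical picture: a chromatin fiber is modeled as a stiff chain in which
remodeling events (nucleosome depletion, histone modifications) create
locally flexible "hinges". On the cubic lattice the chain is a sequence of
unit bonds with a per-vertex bending energy ``eps_v * (1 - cos theta_v)``
(k_B*T units); a stiff vertex carries ``eps = 2`` by default and a hinge
``eps = 0``. The module samples such chains with a Metropolis move set
(pivot / corner flip / end re-draw), estimates persistence length from the
tangent-correlation decay, and runs the hinge-collapse experiment comparing
radii of gyration across hinge counts and chain lengths.

This doubles as the synthetic conformation generator for the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._mc_kernels import COS_TAB, DIRS, GROUP, run_mc

#: default bending-energy gap between stiff background and a hinge (k_B*T)
DEFAULT_STIFF_ENERGY = 2.0
DEFAULT_FLEXIBLE_ENERGY = 0.0

#: default move mix: (pivot, corner flip, end re-draw)
DEFAULT_MOVE_MIX = (0.2, 0.7, 0.1)


def split_seed(master_seed: int, *keys: int) -> int:
    """Derive a child seed from a master seed and a counter path.

    Counter-based splitting via ``numpy.random.SeedSequence`` so adding
    replicates or conditions never reshuffles earlier ones. The result fits
    in 31 bits (the numba RNG takes a C int seed).
    """
    ss = np.random.SeedSequence([int(master_seed)] + [int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo schedule: sweeps, sampling cadence, move mix, seed.

    One sweep is ``n_bonds`` attempted moves. ``n_sweeps`` are run after
    ``equilibration_sweeps``; an observation is recorded every
    ``sample_interval`` sweeps. Temperature is fixed at 1 (energies in
    k_B*T).
    """

    n_sweeps: int
    equilibration_sweeps: int
    sample_interval: int = 1
    move_mix: Tuple[float, float, float] = DEFAULT_MOVE_MIX
    seed: int = 0
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.n_sweeps < 0 or self.equilibration_sweeps < 0:
            raise ValueError("sweep counts must be nonnegative")
        if abs(sum(self.move_mix) - 1.0) > 1e-9 or min(self.move_mix) < 0:
            raise ValueError("move_mix must be nonnegative and sum to 1")
        if self.temperature != 1.0:
            raise ValueError("temperature is fixed at 1 in k_B*T units")

    @property
    def n_samples(self) -> int:
        return self.n_sweeps // self.sample_interval


@dataclass
class LatticeChain:
    """Ordered bead coordinates on the cubic lattice plus vertex stiffnesses.

    ``coordinates`` has shape (n_beads, 3) with consecutive beads one unit
    step apart; ``stiffness_map`` has one bending energy (k_B*T) per interior
    vertex, length ``n_beads - 2``. The chain is phantom: self-overlaps are
    allowed.
    """

    coordinates: np.ndarray
    stiffness_map: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64)
        self.stiffness_map = np.asarray(self.stiffness_map, dtype=np.float64)
        steps = np.diff(self.coordinates, axis=0)
        if not np.all(np.abs(steps).sum(axis=1) == 1):
            raise ValueError("consecutive beads must differ by one unit step")
        if len(self.stiffness_map) != self.n_beads - 2:
            raise ValueError(
                f"stiffness_map must have length n_beads - 2 = "
                f"{self.n_beads - 2}, got {len(self.stiffness_map)}"
            )

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.n_beads - 1

    def directions(self) -> np.ndarray:
        """Bond direction indices 0..5 (see ``_mc_kernels.DIRS``)."""
        steps = np.diff(self.coordinates, axis=0)
        idx = np.argmax(steps @ DIRS.T, axis=1)
        return idx.astype(np.int64)


@dataclass
class ObservableSeries:
    """Per-sample observables from one MC run.

    ``tangent_correlation[s]`` is the run-averaged ``<t_i . t_{i+s}>``
    (index 0 is the trivial s = 0 value, 1). ``energy`` is the bending
    energy of each sampled configuration (k_B*T), used for detailed-balance
    checks against exact enumeration.
    """

    ree2: np.ndarray
    rg2: np.ndarray
    tangent_correlation: np.ndarray
    energy: np.ndarray = field(default_factory=lambda: np.empty(0))


def build_chain(
    n_bonds: int,
    stiffness_map: Sequence[float],
    init: str = "rod",
    seed: int = 0,
) -> LatticeChain:
    """Construct an initial chain of ``n_bonds`` unit bonds.

    ``init='rod'`` gives a collinear chain along +x; ``init='random'`` an
    unbiased lattice walk (deterministic for a fixed seed).
    """
    if n_bonds < 2:
        raise ValueError("n_bonds must be >= 2")
    stiffness_map = np.asarray(stiffness_map, dtype=np.float64)
    if len(stiffness_map) != n_bonds - 1:
        raise ValueError(
            f"stiffness_map must have length n_bonds - 1 = {n_bonds - 1}, "
            f"got {len(stiffness_map)}"
        )
    if init == "rod":
        d = np.zeros(n_bonds, dtype=np.int64)
    elif init == "random":
        rng = np.random.default_rng(seed)
        d = rng.integers(0, 6, size=n_bonds)
    else:
        raise ValueError("init must be 'rod' or 'random'")
    coords = np.vstack([np.zeros(3, dtype=np.int64), np.cumsum(DIRS[d], axis=0)])
    return LatticeChain(coordinates=coords, stiffness_map=stiffness_map)


def hinge_stiffness_map(
    n_bonds: int,
    n_flexible_regions: int,
    stiff_energy: float = DEFAULT_STIFF_ENERGY,
    flexible_energy: float = DEFAULT_FLEXIBLE_ENERGY,
    region_width: int = 1,
) -> np.ndarray:
    """Stiff background with equally spaced flexible hinge regions.

    With ``n_vertices = n_bonds - 1`` interior vertices (1-based labels
    1..n_vertices), hinge ``j`` of ``k`` is centred at vertex
    ``floor(j * (n_vertices + 1) / (k + 1))`` and spans ``region_width``
    vertices; all other vertices carry ``stiff_energy``. The default
    stiff/flexible gap is 2 k_B*T per segment.
    """
    if n_bonds < 2:
        raise ValueError("n_bonds must be >= 2")
    n_vertices = n_bonds - 1
    if n_flexible_regions < 0 or region_width < 1:
        raise ValueError("need n_flexible_regions >= 0 and region_width >= 1")
    if n_flexible_regions * region_width > n_vertices:
        raise ValueError(
            f"{n_flexible_regions} regions of width {region_width} do not "
            f"fit in {n_vertices} vertices"
        )
    eps = np.full(n_vertices, float(stiff_energy))
    k = n_flexible_regions
    for j in range(1, k + 1):
        center = (j * (n_vertices + 1)) // (k + 1)  # 1-based vertex label
        start = center - region_width // 2
        start = min(max(start, 1), n_vertices - region_width + 1)
        eps[start - 1 : start - 1 + region_width] = float(flexible_energy)
    return eps


def metropolis_sample(
    chain: LatticeChain,
    config: MCConfig,
    smax: Optional[int] = None,
) -> ObservableSeries:
    """Sample the Boltzmann distribution of the chain's bending energy.

    At ``eps == 0`` everywhere this reduces to uniform sampling of lattice
    walks (ideal phantom chain). The chain object is not modified; the
    sampler works on a copy of the bond directions.
    """
    if config.n_samples < 1:
        raise ValueError(
            "zero samples requested: increase n_sweeps or lower "
            "sample_interval"
        )
    n = chain.n_bonds
    if smax is None:
        smax = min(n - 1, 20)
    smax = min(smax, n - 1)
    d = chain.directions().copy()
    p_pivot, p_corner, _ = config.move_mix
    ree2, rg2, tcorr, energy = run_mc(
        d,
        chain.stiffness_map,
        COS_TAB,
        GROUP,
        DIRS.astype(np.float64),
        config.equilibration_sweeps,
        config.n_samples,
        config.sample_interval,
        p_pivot,
        p_corner,
        int(config.seed) % (2**31),
        smax,
    )
    return ObservableSeries(
        ree2=ree2, rg2=rg2, tangent_correlation=tcorr, energy=energy
    )


@dataclass(frozen=True)
class TangentFit:
    """Persistence length from the tangent-correlation decay (bond units)."""

    lp: float
    slope: float
    stderr: float
    n_points: int
    rod_like: bool = False


def tangent_correlation_lp(
    series: ObservableSeries,
    fit_range: Tuple[int, int] = (1, 8),
    n_bonds: Optional[int] = None,
) -> TangentFit:
    """Persistence length from ``ln <t_i . t_{i+s}> = -s / Lp``.

    Least-squares fit of the log tangent correlation against separation over
    ``fit_range`` (inclusive, in bonds). A memoryless chain (correlations at
    or below zero already at s = 1) is reported as Lp = 0. If some
    correlations in the range are nonpositive the fit cannot use them; a
    fit-range error asks for a shorter range. Fits with Lp exceeding the
    chain length are flagged rod-like.
    """
    from scipy import stats

    tc = series.tangent_correlation
    lo, hi = fit_range
    if lo < 1 or hi >= len(tc) or hi < lo:
        raise ValueError("fit_range must lie within 1..smax of the series")
    s = np.arange(lo, hi + 1)
    c = tc[lo : hi + 1]
    if c[0] <= 0:
        return TangentFit(lp=0.0, slope=-np.inf, stderr=np.nan, n_points=0)
    if np.any(c <= 0):
        raise ValueError(
            "nonpositive tangent correlations inside the fit range: "
            "shorten the range to separations with positive correlation"
        )
    if len(s) == 1:
        slope = math.log(c[0]) / s[0]
        se = float("nan")
    else:
        res = stats.linregress(s, np.log(c))
        slope, se = res.slope, res.stderr
    if slope >= 0:
        lp = math.inf
    else:
        lp = -1.0 / slope
    rod_like = n_bonds is not None and lp > n_bonds
    if rod_like:
        warnings.warn(
            "fitted persistence length exceeds the chain length: "
            "chain is rod-like at this stiffness",
            stacklevel=2,
        )
    return TangentFit(
        lp=lp, slope=slope, stderr=se, n_points=len(s), rod_like=rod_like
    )


def transfer_matrix_mean_cos(eps: float) -> float:
    """Exact per-vertex ``<cos theta>`` of the uniform-stiffness chain.

    The direction sequence is a 6-state Markov chain whose transfer matrix
    ``T[d, d'] = exp(-eps * (1 - cos theta))`` has constant row sums, so the
    Perron vector is uniform and the junction average is

    ``<cos> = (1 - exp(-2 eps)) / (1 + 4 exp(-eps) + exp(-2 eps))``.

    The tangent correlation then decays exactly as ``<cos>**s``.
    """
    e1 = math.exp(-eps)
    e2 = math.exp(-2.0 * eps)
    return (1.0 - e2) / (1.0 + 4.0 * e1 + e2)


def ideal_chain_rg2(n_bonds: int) -> float:
    """Exact ``<Rg^2>`` of a freely jointed lattice chain of N unit bonds.

    ``<Rg^2> = N (N + 2) / (6 (N + 1))`` — the textbook closed form, which
    the test suite re-derives by exhaustive enumeration at small N.
    """
    n = n_bonds
    return n * (n + 2) / (6.0 * (n + 1))


def rg_ratio_experiment(
    n_bonds_list: Sequence[int],
    hinge_counts: Sequence[int],
    config: MCConfig,
    replicates: int = 32,
    stiff_energy: float = DEFAULT_STIFF_ENERGY,
    flexible_energy: float = DEFAULT_FLEXIBLE_ENERGY,
    region_width: Optional[int] = None,
) -> pd.DataFrame:
    """Hinge-collapse experiment: Rg^2 ratios vs hinge count and length.

    For each chain length ``N_r`` and hinge count ``k`` the ratio
    ``R(k) = <Rg^2>(k hinges in stiff background) / <Rg^2>(fully flexible)``
    is estimated from ``replicates`` independent seeds (derived from
    ``config.seed`` by counter splitting). Adding hinges softens the chain,
    so R decreases with k and increases with N_r.

    Hinges are extended soft regions: remodeling (nucleosome depletion,
    histone modification) acts on a stretch of fiber, not a point, and a
    point defect in a long phantom chain would leave the extensive
    ``<Rg^2>`` essentially unchanged. By default each region spans a fixed
    fraction of the chain, ``region_width = max(1, n_bonds // 16)``
    vertices; pass an explicit width to override.

    Returns a tidy table with columns ``n_bonds, k, ratio, stderr,
    rg2_hinged, rg2_flexible``. The ratio definition is recorded here
    because the convention (normalizing by the fully flexible chain) is a
    package choice.
    """
    rows = []
    for ni, n_bonds in enumerate(n_bonds_list):
        if n_bonds < 4:
            raise ValueError("chains shorter than 4 bonds cannot host hinges")
        width = region_width if region_width is not None else max(
            1, n_bonds // 16
        )
        flex_map = np.full(n_bonds - 1, float(flexible_energy))
        flex_means = _replicate_rg2(
            n_bonds, flex_map, config, replicates, cond=(ni, 10_000)
        )
        f_mean = flex_means.mean()
        f_se = flex_means.std(ddof=1) / math.sqrt(replicates)
        for k in hinge_counts:
            eps = hinge_stiffness_map(
                n_bonds, k, stiff_energy, flexible_energy, width
            )
            means = _replicate_rg2(
                n_bonds, eps, config, replicates, cond=(ni, k)
            )
            h_mean = means.mean()
            h_se = means.std(ddof=1) / math.sqrt(replicates)
            ratio = h_mean / f_mean
            se = ratio * math.sqrt((h_se / h_mean) ** 2 + (f_se / f_mean) ** 2)
            rows.append(
                {
                    "n_bonds": n_bonds,
                    "k": k,
                    "ratio": ratio,
                    "stderr": se,
                    "rg2_hinged": h_mean,
                    "rg2_flexible": f_mean,
                }
            )
    return pd.DataFrame(rows)


def _replicate_rg2(
    n_bonds: int,
    eps: np.ndarray,
    config: MCConfig,
    replicates: int,
    cond: Tuple[int, int],
) -> np.ndarray:
    """Per-replicate mean Rg^2 for one condition (one seed per replicate)."""
    means = np.empty(replicates)
    for r in range(replicates):
        seed = split_seed(config.seed, cond[0], cond[1], r)
        rep_cfg = MCConfig(
            n_sweeps=config.n_sweeps,
            equilibration_sweeps=config.equilibration_sweeps,
            sample_interval=config.sample_interval,
            move_mix=config.move_mix,
            seed=seed,
        )
        chain = build_chain(n_bonds, eps, init="random", seed=seed)
        series = metropolis_sample(chain, rep_cfg, smax=0)
        means[r] = series.rg2.mean()
    return means
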