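"""Gaussian loop models and confined/unconfined chain ensembles.

Three model families for chromosomal (Mbp-scale) organization:

* **Random loop**: a Gaussian backbone of N beads with extra harmonic bonds
  added independently between every pair separated by more than a genomic
  cutoff (default 15 beads = 150 kbp at 10 kbp/bead). Mean-square distances
  of the resulting harmonic network are exact via the pseudo-inverse of the
  connectivity Laplacian; averaging over loop configurations produces the
  observed leveling-off of distance vs genomic separation (nu -> 0).
* **Random-walk giant-loop (RW-GL)**: Mbp-scale closed Gaussian loops
  (Brownian bridges) hung consecutively on a random-walk backbone.
* **Freely jointed lattice chains**, open or confined in a cubic box at
  fixed density: the unconfined chain scales as nu = 1/2 (equilibrium
  globule interior), the density-fixed confined chain as nu = 1/3 (the
  fractal-globule comparison).

Distance units are bond lengths (``b = 1``) unless a bond variance is given.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from scipy.linalg import cholesky, solve_triangular

from ._mc_kernels import confined_walks

DEFAULT_BP_PER_BEAD = 10_000
DEFAULT_MIN_LOOP_SEPARATION = 15  # beads = 150 kbp at 10 kbp/bead
DEFAULT_CAPTURE_RADIUS = 2.0  # bond lengths

#: study conditions for the confined-globule size-scaling experiment: a
#: space-filling melt (one bead per lattice site) in exact-cube boxes of
#: side 12, 16, 20, 24 — large enough that O(1/side) surface corrections to
#: the apparent exponent stay small
GLOBULE_DENSITY = 1.0
GLOBULE_SIZES = (1728, 4096, 8000, 13824)


@dataclass
class LoopTopology:
    """Backbone of ``n_beads`` plus a set of extra harmonic bonds (loops)."""

    n_beads: int
    extra_bonds: Set[Tuple[int, int]]
    loop_probability: float
    min_loop_separation: int
    bp_per_bead: int = DEFAULT_BP_PER_BEAD

    def __post_init__(self) -> None:
        for i, j in self.extra_bonds:
            if not (0 <= i < j < self.n_beads):
                raise ValueError(f"bond ({i}, {j}) out of range or unordered")
            if j - i < self.min_loop_separation:
                raise ValueError(
                    f"bond ({i}, {j}) violates the minimum loop separation "
                    f"of {self.min_loop_separation} beads"
                )


@dataclass
class DistanceProfile:
    """Mean-square spatial distance vs genomic separation (beads)."""

    separation: np.ndarray
    mean_square_distance: np.ndarray
    stderr: np.ndarray


@dataclass
class ContactProfile:
    """Contact probability vs genomic separation at a capture radius."""

    separation: np.ndarray
    contact_probability: np.ndarray
    capture_radius: float


@dataclass
class ScalingFit:
    """Log-log power-law fit: exponent nu-hat with uncertainty."""

    exponent: float
    stderr: float
    fit_range: Tuple[float, float]
    prefactor: float


@dataclass
class Ensemble:
    """Conformation ensemble: positions with shape (n_chains, n_beads, 3)."""

    positions: np.ndarray
    mode: str = "unconfined"
    box_side: Optional[int] = None

    @property
    def n_chains(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]


def random_loop_topology(
    n_beads: int,
    p: float,
    min_loop_separation: int = DEFAULT_MIN_LOOP_SEPARATION,
    seed: int = 0,
    bp_per_bead: int = DEFAULT_BP_PER_BEAD,
) -> LoopTopology:
    """Draw a random-loop topology: each eligible pair looped with prob p.

    Eligible pairs are those separated by at least ``min_loop_separation``
    beads (the genomic cutoff below which loops are not observed).
    """
    if not 0 <= p <= 1:
        raise ValueError("loop probability must lie in [0, 1]")
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    ii, jj = np.triu_indices(n_beads, k=max(min_loop_separation, 1))
    if len(ii) == 0:
        warnings.warn(
            "minimum loop separation leaves no eligible pairs: "
            "returning a loop-free topology",
            stacklevel=2,
        )
        bonds: Set[Tuple[int, int]] = set()
    else:
        rng = np.random.default_rng(seed)
        mask = rng.random(len(ii)) < p
        bonds = {(int(i), int(j)) for i, j in zip(ii[mask], jj[mask])}
    return LoopTopology(
        n_beads=n_beads,
        extra_bonds=bonds,
        loop_probability=p,
        min_loop_separation=min_loop_separation,
        bp_per_bead=bp_per_bead,
    )


def n_eligible_pairs(n_beads: int, min_loop_separation: int) -> int:
    """Number of bead pairs eligible for a loop bond."""
    ii, _ = np.triu_indices(n_beads, k=max(min_loop_separation, 1))
    return len(ii)


def _laplacian(topology: LoopTopology, loop_strength: float = 1.0) -> np.ndarray:
    n = topology.n_beads
    lap = np.zeros((n, n))
    idx = np.arange(n - 1)
    lap[idx, idx + 1] -= 1.0
    lap[idx + 1, idx] -= 1.0
    for i, j in topology.extra_bonds:
        lap[i, j] -= loop_strength
        lap[j, i] -= loop_strength
    np.fill_diagonal(lap, 0.0)
    np.fill_diagonal(lap, -lap.sum(axis=1))
    return lap


def gaussian_distance_matrix(
    topology: LoopTopology,
    bond_variance: float = 1.0,
    loop_strength: float = 1.0,
) -> np.ndarray:
    """Exact mean-square distances of the harmonic (Gaussian) network.

    With connectivity Laplacian ``Gamma`` (backbone springs of unit strength,
    loop springs of relative strength ``loop_strength``) the equilibrium
    mean-square distance between beads i and j is

    ``<r_ij^2> = b^2 * (G+_ii + G+_jj - 2 G+_ij)``

    where ``G+`` is the Moore-Penrose pseudo-inverse and ``b^2`` the
    mean-square backbone bond length. With no loops this reduces exactly to
    the ideal chain, ``<r_ij^2> = |i - j| b^2``.
    """
    if bond_variance <= 0:
        raise ValueError("bond variance must be positive")
    lap = _laplacian(topology, loop_strength)
    gp = np.linalg.pinv(lap, hermitian=True)
    # guard against rank deficiency beyond the single translation mode
    rank = np.linalg.matrix_rank(lap)
    if rank < topology.n_beads - 1:
        raise np.linalg.LinAlgError(
            "connectivity Laplacian is singular beyond the translation mode"
        )
    diag = np.diag(gp)
    return bond_variance * (diag[:, None] + diag[None, :] - 2.0 * gp)


def sample_gaussian_network(
    topology: LoopTopology,
    n_draws: int,
    seed: int = 0,
    bond_variance: float = 1.0,
    loop_strength: float = 1.0,
) -> np.ndarray:
    """Independent Gaussian draws from the harmonic network (bead 0 pinned).

    Returns positions with shape (n_draws, n_beads, 3). Sampling goes
    through the Cholesky factor of the pinned precision matrix, a route
    independent of the pseudo-inverse distance formula, so the two can be
    cross-checked statistically.
    """
    n = topology.n_beads
    lap = _laplacian(topology, loop_strength)
    prec = lap[1:, 1:] * (3.0 / bond_variance)  # per-dimension precision
    c_upper = cholesky(prec, lower=False)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n - 1, 3 * n_draws))
    x = solve_triangular(c_upper, z, lower=False)
    pos = np.zeros((n, 3 * n_draws))
    pos[1:] = x
    return pos.reshape(n, 3, n_draws).transpose(2, 0, 1)


def distance_profile_from_matrix(
    d2: np.ndarray, separations: Optional[Sequence[int]] = None
) -> DistanceProfile:
    """Average a mean-square distance matrix over pairs at each separation."""
    n = d2.shape[0]
    if separations is None:
        separations = range(1, n)
    seps = np.asarray(list(separations), dtype=int)
    means = np.array([np.mean(np.diagonal(d2, offset=s)) for s in seps])
    return DistanceProfile(
        separation=seps, mean_square_distance=means, stderr=np.zeros_like(means)
    )


def random_loop_profile(
    n_beads: int,
    p: float,
    n_topologies: int = 30,
    min_loop_separation: int = DEFAULT_MIN_LOOP_SEPARATION,
    seed: int = 0,
    bond_variance: float = 1.0,
    separations: Optional[Sequence[int]] = None,
) -> DistanceProfile:
    """Loop-configuration-averaged distance profile of the random loop model.

    Averages the exact per-topology profiles over independently drawn loop
    configurations (the model's account of cell-to-cell variation); the
    standard error is across topologies.
    """
    if separations is None:
        separations = range(1, n_beads)
    seps = np.asarray(list(separations), dtype=int)
    acc = np.empty((n_topologies, len(seps)))
    for t in range(n_topologies):
        topo = random_loop_topology(
            n_beads, p, min_loop_separation, seed=seed * 1_000_003 + t
        )
        d2 = gaussian_distance_matrix(topo, bond_variance)
        acc[t] = [np.mean(np.diagonal(d2, offset=s)) for s in seps]
    return DistanceProfile(
        separation=seps,
        mean_square_distance=acc.mean(axis=0),
        stderr=acc.std(axis=0, ddof=1) / math.sqrt(n_topologies)
        if n_topologies > 1
        else np.zeros(len(seps)),
    )


def rwgl_profile(
    n_beads: int,
    loop_size: int,
    replicates: int = 100,
    seed: int = 0,
    bond_variance: float = 1.0,
    backbone_step_variance: Optional[float] = None,
    separations: Optional[Sequence[int]] = None,
) -> DistanceProfile:
    """Random-walk giant-loop model: closed loops on a random backbone.

    The chain is partitioned into consecutive closed Gaussian loops of
    ``loop_size`` beads, each built as a Brownian bridge returning to its
    anchor; the anchors follow an independent Gaussian random walk with
    per-step variance ``backbone_step_variance`` (default: one bond
    variance, i.e. a backbone much shorter than the loops, which is what
    produces the leveling-off of distances at separations much larger than
    a loop). Remaining beads past the last full loop form an open tail.
    """
    if loop_size < 2:
        raise ValueError("loop_size must be >= 2")
    if loop_size > n_beads:
        raise ValueError("loop_size may not exceed n_beads")
    if backbone_step_variance is None:
        backbone_step_variance = bond_variance
    if separations is None:
        separations = _log_separations(n_beads)
    seps = np.asarray(list(separations), dtype=int)
    rng = np.random.default_rng(seed)
    acc = np.empty((replicates, len(seps)))
    for r in range(replicates):
        pos = _sample_rwgl(
            n_beads, loop_size, rng, bond_variance, backbone_step_variance
        )
        for k, s in enumerate(seps):
            diff = pos[s:] - pos[:-s]
            acc[r, k] = np.mean(np.einsum("ij,ij->i", diff, diff))
    return DistanceProfile(
        separation=seps,
        mean_square_distance=acc.mean(axis=0),
        stderr=acc.std(axis=0, ddof=1) / math.sqrt(replicates)
        if replicates > 1
        else np.zeros(len(seps)),
    )


def _sample_rwgl(
    n_beads: int,
    loop_size: int,
    rng: np.random.Generator,
    bond_variance: float,
    backbone_step_variance: float,
) -> np.ndarray:
    sigma = math.sqrt(bond_variance / 3.0)  # per-dimension bond sd
    pos = np.empty((n_beads, 3))
    n_loops = n_beads // loop_size
    anchors = np.vstack(
        [
            np.zeros(3),
            np.cumsum(
                rng.normal(
                    0.0,
                    math.sqrt(backbone_step_variance / 3.0),
                    size=(max(n_loops, 1), 3),
                ),
                axis=0,
            ),
        ]
    )
    for j in range(n_loops):
        m = loop_size
        walk = np.cumsum(rng.normal(0.0, sigma, size=(m, 3)), axis=0)
        t = np.arange(1, m + 1)[:, None] / m
        bridge = walk - t * walk[-1]  # closed: returns to 0 at offset m
        pos[j * m] = anchors[j]
        # beads j*m + 1 .. j*m + m - 1 ride the bridge; bead (j+1)*m is the
        # next anchor (bridge end coincides with loop start physically; the
        # anchor walk carries the backbone displacement)
        for u in range(1, m):
            if j * m + u < n_beads:
                pos[j * m + u] = anchors[j] + bridge[u - 1]
    tail_start = n_loops * loop_size
    if tail_start < n_beads:
        start = anchors[n_loops] if n_loops > 0 else np.zeros(3)
        pos[tail_start] = start
        if n_beads - tail_start > 1:
            pos[tail_start + 1 :] = start + np.cumsum(
                rng.normal(0.0, sigma, size=(n_beads - tail_start - 1, 3)),
                axis=0,
            )
    return pos


def fjc_ensemble(
    n_beads: int,
    mode: str = "unconfined",
    box_side: Optional[int] = None,
    density: Optional[float] = None,
    n_chains: int = 64,
    seed: int = 0,
) -> Ensemble:
    """Phantom lattice-walk ensembles, open or box-confined.

    ``mode='unconfined'``: plain lattice random walks.
    ``mode='confined'``: walks reflected inside a cubic box; give either the
    integer ``box_side`` (lattice sites) or a ``density`` (beads per site),
    from which the side is ``round((n_beads/density)**(1/3))``.
    """
    if n_beads < 2 or n_chains < 1:
        raise ValueError("need n_beads >= 2 and n_chains >= 1")
    if mode == "unconfined":
        rng = np.random.default_rng(seed)
        from ._mc_kernels import DIRS

        steps = DIRS[rng.integers(0, 6, size=(n_chains, n_beads - 1))]
        pos = np.concatenate(
            [
                np.zeros((n_chains, 1, 3), dtype=np.int64),
                np.cumsum(steps, axis=1),
            ],
            axis=1,
        )
        return Ensemble(positions=pos, mode=mode)
    if mode == "confined":
        if box_side is None:
            if density is None:
                raise ValueError("confined mode needs box_side or density")
            box_side = int(round((n_beads / density) ** (1.0 / 3.0)))
        if box_side < 2:
            raise ValueError("box side must be at least 2 lattice sites")
        if n_beads / box_side**3 > 1.0 + 1e-9:
            raise ValueError("density above 1 bead per lattice site")
        pos = confined_walks(n_chains, n_beads, box_side, seed % (2**31))
        return Ensemble(positions=pos, mode=mode, box_side=box_side)
    raise ValueError("mode must be 'unconfined' or 'confined'")


def _log_separations(n_beads: int, per_decade: int = 8) -> np.ndarray:
    smax = n_beads - 1
    s = np.unique(
        np.round(
            np.logspace(0, math.log10(smax), int(per_decade * math.log10(smax)) + 2)
        ).astype(int)
    )
    return s[(s >= 1) & (s <= smax)]


def internal_distance_profile(
    ensemble: Ensemble, separations: Optional[Sequence[int]] = None
) -> DistanceProfile:
    """Mean-square internal distance vs separation, pooled over start beads.

    The standard error is computed across chains (each chain contributes one
    pooled mean per separation), so it is conservative with respect to the
    strong correlations among overlapping pairs within a chain.
    """
    pos = ensemble.positions.astype(np.float64)
    if separations is None:
        separations = _log_separations(ensemble.n_beads)
    seps = np.asarray(list(separations), dtype=int)
    means = np.empty(len(seps))
    errs = np.empty(len(seps))
    nc = ensemble.n_chains
    for k, s in enumerate(seps):
        diff = pos[:, s:, :] - pos[:, :-s, :]
        r2 = np.einsum("cij,cij->ci", diff, diff)
        per_chain = r2.mean(axis=1)
        means[k] = per_chain.mean()
        errs[k] = (
            per_chain.std(ddof=1) / math.sqrt(nc) if nc > 1 else 0.0
        )
    return DistanceProfile(
        separation=seps, mean_square_distance=means, stderr=errs
    )


def ensemble_rg2(ensemble: Ensemble) -> Tuple[float, float]:
    """Mean and standard error (over chains) of the squared gyration radius."""
    pos = ensemble.positions.astype(np.float64)
    com = pos.mean(axis=1, keepdims=True)
    rg2 = ((pos - com) ** 2).sum(axis=2).mean(axis=1)
    n = len(rg2)
    return float(rg2.mean()), float(
        rg2.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    )


def fit_scaling_exponent(
    x: Sequence[float],
    y: Sequence[float],
    fit_range: Optional[Tuple[float, float]] = None,
    squared: bool = True,
) -> ScalingFit:
    """Least-squares power-law fit on log-log axes.

    ``squared=True`` treats ``y`` as a mean-SQUARE size (r^2 or Rg^2), so
    the size exponent is half the log-log slope; ``squared=False`` returns
    the raw slope (use for contact probabilities or RMS sizes).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if fit_range is not None:
        lo, hi = fit_range
        mask = (x >= lo) & (x <= hi)
        x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 points in the fit range")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    res = stats.linregress(np.log(x), np.log(y))
    factor = 0.5 if squared else 1.0
    return ScalingFit(
        exponent=factor * res.slope,
        stderr=factor * res.stderr,
        fit_range=(float(x.min()), float(x.max())),
        prefactor=math.exp(res.intercept),
    )


def contact_probability(
    ensemble: Ensemble,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    separations: Optional[Sequence[int]] = None,
) -> ContactProfile:
    """Fraction of bead pairs at separation s within the capture radius."""
    if capture_radius <= 0:
        raise ValueError("capture radius must be positive")
    pos = ensemble.positions.astype(np.float64)
    if separations is None:
        separations = _log_separations(ensemble.n_beads)
    seps = np.asarray(list(separations), dtype=int)
    r2cut = capture_radius**2
    probs = np.empty(len(seps))
    for k, s in enumerate(seps):
        diff = pos[:, s:, :] - pos[:, :-s, :]
        r2 = np.einsum("cij,cij->ci", diff, diff)
        probs[k] = float((r2 < r2cut).mean())
    return ContactProfile(
        separation=seps, contact_probability=probs, capture_radius=capture_radius
    )


def moment_ratio_from_r2(r2_samples: np.ndarray) -> float:
    """``<r^4> / <r^2>^2`` of a pooled set of squared distances.

    Degenerate (rod-like) distributions give 1, the 3D Gaussian chain 5/3;
    Cauchy-Schwarz bounds the ratio below by 1.
    """
    r2 = np.asarray(r2_samples, dtype=float)
    if r2.size < 1_000:
        warnings.warn(
            "fewer than 1000 samples: moment ratio will be noisy",
            stacklevel=2,
        )
    m2 = r2.mean()
    if m2 <= 0:
        raise ValueError("need nonzero distances")
    return float((r2**2).mean() / m2**2)


def moment_ratio(ensemble: Ensemble, separation: int) -> float:
    """Moment ratio of the intrachain distance distribution at separation s."""
    s = int(separation)
    if not 1 <= s <= ensemble.n_beads - 1:
        raise ValueError("separation out of range")
    pos = ensemble.positions.astype(np.float64)
    diff = pos[:, s:, :] - pos[:, :-s, :]
    r2 = np.einsum("cij,cij->ci", diff, diff).ravel()
    return moment_ratio_from_r2(r2)
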