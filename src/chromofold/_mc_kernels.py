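"""Numba kernels for cubic-lattice Monte Carlo of phantom semiflexible chains.

A chain of ``n`` unit bonds is stored as a sequence of direction indices
0..5 mapping to (+x, -x, +y, -y, +z, -z). The bending energy is
``E = sum_v eps[v] * (1 - cos(theta_v))`` over the ``n - 1`` interior
vertices, with ``cos(theta)`` in {1, 0, -1} on the cubic lattice. Chains are
phantom (self-overlap allowed), so moves never need an overlap check.
"""

from itertools import permutations, product

import numpy as np
from numba import njit

#: unit step vectors for the 6 lattice directions
DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)

#: cos(theta) between every pair of directions
COS_TAB = (DIRS @ DIRS.T).astype(np.float64)


def _octahedral_group() -> np.ndarray:
    """All 48 signed-permutation maps of the lattice directions.

    Returned as a (48, 6) table: ``GROUP[g, d]`` is the image of direction
    ``d`` under group element ``g``. Phantom chains admit the full group
    (proper and improper rotations) as pivot symmetries.
    """
    index_of = {tuple(v): i for i, v in enumerate(DIRS.tolist())}
    tables = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            table = np.empty(6, dtype=np.int64)
            for d in range(6):
                v = DIRS[d]
                w = [0, 0, 0]
                for i in range(3):
                    w[perm[i]] = int(signs[i] * v[i])
                table[d] = index_of[tuple(w)]
            tables.append(table)
    return np.array(tables, dtype=np.int64)


GROUP = _octahedral_group()


@njit(cache=True)
def run_mc(
    d,
    eps,
    cos_tab,
    group,
    dirs,
    equil_sweeps,
    n_samples,
    interval_sweeps,
    p_pivot,
    p_corner,
    seed,
    smax,
):
    """Metropolis sampling of the bending-energy Boltzmann distribution.

    Moves (chosen with probabilities p_pivot / p_corner / rest):
      * pivot: a random octahedral element applied to all bonds after a
        random junction; only the junction angle changes energy,
      * corner flip: swap of two adjacent bond directions (the classic
        single-vertex corner move in direction space),
      * end re-draw: resample the first or last bond uniformly.

    One sweep = ``n`` attempted moves. After ``equil_sweeps`` sweeps,
    ``n_samples`` observations are recorded every ``interval_sweeps`` sweeps:
    squared end-to-end distance, squared radius of gyration, and (if
    ``smax > 0``) the tangent autocorrelation over separations 1..smax.

    Mutates ``d`` in place; returns (ree2, rg2, tcorr, energies).
    """
    np.random.seed(seed)
    n = d.shape[0]
    nb = n + 1
    ree2 = np.empty(n_samples, dtype=np.float64)
    rg2 = np.empty(n_samples, dtype=np.float64)
    energies = np.empty(n_samples, dtype=np.float64)
    tcorr = np.zeros(smax + 1, dtype=np.float64)
    pos = np.empty((nb, 3), dtype=np.float64)

    moves_per_sample = interval_sweeps * n
    n_equil_moves = equil_sweeps * n
    total_moves = n_equil_moves + n_samples * moves_per_sample

    for step in range(total_moves):
        u = np.random.random()
        if u < p_pivot:
            # pivot: rotate bonds j..n-1; only junction j-1 changes angle
            j = 1 + np.random.randint(0, n - 1)
            g = np.random.randint(0, 48)
            de = eps[j - 1] * (
                cos_tab[d[j - 1], d[j]] - cos_tab[d[j - 1], group[g, d[j]]]
            )
            if de <= 0.0 or np.random.random() < np.exp(-de):
                for i in range(j, n):
                    d[i] = group[g, d[i]]
        elif u < p_pivot + p_corner:
            # corner flip at vertex v: swap bonds v and v+1
            v = np.random.randint(0, n - 1)
            a = d[v]
            b = d[v + 1]
            if a != b:
                de = 0.0
                if v > 0:
                    de += eps[v - 1] * (
                        cos_tab[d[v - 1], a] - cos_tab[d[v - 1], b]
                    )
                if v < n - 2:
                    de += eps[v + 1] * (
                        cos_tab[b, d[v + 2]] - cos_tab[a, d[v + 2]]
                    )
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    d[v] = b
                    d[v + 1] = a
        else:
            # end re-draw
            nd = np.random.randint(0, 6)
            if np.random.random() < 0.5:
                de = eps[0] * (cos_tab[d[0], d[1]] - cos_tab[nd, d[1]])
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    d[0] = nd
            else:
                de = eps[n - 2] * (
                    cos_tab[d[n - 2], d[n - 1]] - cos_tab[d[n - 2], nd]
                )
                if de <= 0.0 or np.random.random() < np.exp(-de):
                    d[n - 1] = nd

        k = step - n_equil_moves + 1
        if k > 0 and k % moves_per_sample == 0:
            idx = k // moves_per_sample - 1
            pos[0, 0] = 0.0
            pos[0, 1] = 0.0
            pos[0, 2] = 0.0
            for i in range(n):
                pos[i + 1, 0] = pos[i, 0] + dirs[d[i], 0]
                pos[i + 1, 1] = pos[i, 1] + dirs[d[i], 1]
                pos[i + 1, 2] = pos[i, 2] + dirs[d[i], 2]
            dx = pos[n, 0] - pos[0, 0]
            dy = pos[n, 1] - pos[0, 1]
            dz = pos[n, 2] - pos[0, 2]
            ree2[idx] = dx * dx + dy * dy + dz * dz
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for i in range(nb):
                cx += pos[i, 0]
                cy += pos[i, 1]
                cz += pos[i, 2]
            cx /= nb
            cy /= nb
            cz /= nb
            s2 = 0.0
            for i in range(nb):
                s2 += (
                    (pos[i, 0] - cx) ** 2
                    + (pos[i, 1] - cy) ** 2
                    + (pos[i, 2] - cz) ** 2
                )
            rg2[idx] = s2 / nb
            e = 0.0
            for v in range(n - 1):
                e += eps[v] * (1.0 - cos_tab[d[v], d[v + 1]])
            energies[idx] = e
            for s in range(1, smax + 1):
                acc = 0.0
                cnt = n - s
                for i in range(cnt):
                    acc += cos_tab[d[i], d[i + s]]
                tcorr[s] += acc / cnt

    if n_samples > 0:
        for s in range(1, smax + 1):
            tcorr[s] /= n_samples
    tcorr[0] = 1.0
    return ree2, rg2, tcorr, energies


@njit(cache=True)
def confined_walks(n_chains, n_beads, side, seed):
    """Phantom lattice random walks reflected inside a cubic box.

    Each step is drawn uniformly from the directions that keep the bead
    inside ``[0, side)^3`` (rejection resampling), so every bond has unit
    length. Start sites are uniform in the box.
    """
    np.random.seed(seed)
    pos = np.empty((n_chains, n_beads, 3), dtype=np.int64)
    for c in range(n_chains):
        x = np.random.randint(0, side)
        y = np.random.randint(0, side)
        z = np.random.randint(0, side)
        pos[c, 0, 0] = x
        pos[c, 0, 1] = y
        pos[c, 0, 2] = z
        for b in range(1, n_beads):
            while True:
                m = np.random.randint(0, 6)
                nx = x + DIRS_X[m]
                ny = y + DIRS_Y[m]
                nz = z + DIRS_Z[m]
                if 0 <= nx < side and 0 <= ny < side and 0 <= nz < side:
                    break
            x = nx
            y = ny
            z = nz
            pos[c, b, 0] = x
            pos[c, b, 1] = y
            pos[c, b, 2] = z
    return pos


# module-level constants usable inside njit
DIRS_X = DIRS[:, 0].copy()
DIRS_Y = DIRS[:, 1].copy()
DIRS_Z = DIRS[:, 2].copy()
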