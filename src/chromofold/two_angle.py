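"""Two-angle geometry of nucleosome arrays.

The fiber is built deterministically from two angles: the linker entry-exit
angle ``alpha`` at each nucleosome and the rotation ``beta`` of successive
kink planes about the linker axis, the latter set by the linker length
through the DNA helical repeat. Nucleosomes are spheres (default diameter
11 nm) at the kink vertices, joined by straight linkers of length
``linker_bp * dna_rise``.

Conventions (declared, since the two-angle literature does not fix them):
``alpha`` is measured so that ``alpha = 180 deg`` means no kink (straight
beads-on-a-string); ``beta`` is a right-handed rotation about the incoming
linker direction applied before the kink. Large ``alpha`` gives open zigzags,
small ``alpha`` tight solenoid-like forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_NUCLEOSOME_DIAMETER = 11.0  # nm
DEFAULT_DNA_RISE = 0.34  # nm/bp
DEFAULT_HELICAL_REPEAT = 10.5  # bp/turn
AXIS_WINDOW = 5  # nucleosomes per sliding-window centroid


@dataclass(frozen=True)
class TwoAngleSpec:
    """Parameters of the two-angle construction.

    ``beta`` may be given explicitly (degrees) or left None to be derived
    from ``linker_bp`` via the helical repeat. ``linker_bp`` always sets the
    linker length (``linker_bp * dna_rise`` nm).
    """

    alpha: float  # degrees, 0 < alpha <= 180; 180 = straight
    linker_bp: float
    n_nucleosomes: int
    beta: Optional[float] = None  # degrees; None -> from linker length
    nucleosome_diameter: float = DEFAULT_NUCLEOSOME_DIAMETER
    dna_rise: float = DEFAULT_DNA_RISE
    helical_repeat: float = DEFAULT_HELICAL_REPEAT

    def __post_init__(self) -> None:
        # alpha = 0 (linker folded fully back) is degenerate but allowed:
        # build_fiber warns about the immediate steric clash it causes
        if not 0 <= self.alpha <= 180:
            raise ValueError("alpha must lie in [0, 180] degrees")
        if self.linker_bp < 0:
            raise ValueError("linker_bp must be nonnegative")
        if self.n_nucleosomes < 2:
            raise ValueError("need at least 2 nucleosomes")
        if self.nucleosome_diameter <= 0 or self.dna_rise <= 0:
            raise ValueError("diameter and dna_rise must be positive")

    @property
    def resolved_beta(self) -> float:
        if self.beta is None:
            return beta_from_linker(self.linker_bp, self.helical_repeat)
        return self.beta % 360.0

    @property
    def linker_length(self) -> float:
        """Linker length in nm."""
        return self.linker_bp * self.dna_rise


@dataclass
class FiberGeometry:
    """Nucleosome centers (nm) and the straight linkers joining them."""

    nucleosome_centers: np.ndarray  # (n, 3)
    linker_length: float
    nucleosome_diameter: float
    spec: Optional[TwoAngleSpec] = None

    @property
    def n_nucleosomes(self) -> int:
        return self.nucleosome_centers.shape[0]

    @property
    def linker_segments(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        c = self.nucleosome_centers
        return [(c[i], c[i + 1]) for i in range(len(c) - 1)]


@dataclass
class FiberMetrics:
    """Axis-based summary: packing ratio, fiber diameter, clash list."""

    packing_ratio: float  # nucleosomes per 11 nm of fiber axis
    fiber_diameter: float  # nm
    axis_curve: np.ndarray  # (n - window + 1, 3) sliding-window centroids
    clashes: List[Tuple[int, int]] = field(default_factory=list)


def beta_from_linker(
    linker_bp: float, helical_repeat: float = DEFAULT_HELICAL_REPEAT
) -> float:
    """Inter-nucleosome rotation (degrees in [0, 360)) set by linker length.

    One helical repeat of linker DNA rotates the next nucleosome by a full
    turn, so ``beta = 360 * (linker_bp mod repeat) / repeat``.
    """
    if linker_bp < 0:
        raise ValueError("linker_bp must be nonnegative")
    if helical_repeat <= 0:
        raise ValueError("helical_repeat must be positive")
    return (360.0 * (linker_bp % helical_repeat) / helical_repeat) % 360.0


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis by angle (radians)."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def build_fiber(spec: TwoAngleSpec) -> FiberGeometry:
    """Deterministic two-angle construction of the nucleosome array.

    A local frame (linker direction ``u``, kink-plane normal offset ``n``)
    is propagated: at each nucleosome the frame is rolled by ``beta`` about
    ``u``, then the direction is kinked by the deflection
    ``delta = 180 - alpha`` degrees inside the plane spanned by ``u`` and
    ``n``. The first linker lies along +x with the kink plane in xz.
    """
    delta = math.radians(180.0 - spec.alpha)
    beta = math.radians(spec.resolved_beta)
    L = spec.linker_length
    if spec.alpha <= 0.0 + 1e-12 and spec.nucleosome_diameter > 0:
        warnings.warn(
            "alpha = 0 folds each linker back on itself: immediate clashes",
            stacklevel=2,
        )
    centers = np.zeros((spec.n_nucleosomes, 3))
    u = np.array([1.0, 0.0, 0.0])
    n = np.array([0.0, 0.0, 1.0])
    centers[1] = centers[0] + L * u
    cd, sd = math.cos(delta), math.sin(delta)
    for i in range(2, spec.n_nucleosomes):
        n = _rotate(n, u, beta)
        u, n = cd * u + sd * n, -sd * u + cd * n
        centers[i] = centers[i - 1] + L * u
    return FiberGeometry(
        nucleosome_centers=centers,
        linker_length=L,
        nucleosome_diameter=spec.nucleosome_diameter,
        spec=spec,
    )


def detect_clashes(
    fiber: FiberGeometry, diameter: Optional[float] = None
) -> List[Tuple[int, int]]:
    """Sterically clashing nucleosome pairs (center distance < diameter).

    Bonded neighbours (|i - j| < 2) are excluded since consecutive
    nucleosomes are joined by the linker by construction. Pairs are returned
    canonically ordered (i < j), without duplicates.
    """
    if diameter is None:
        diameter = fiber.nucleosome_diameter
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    tree = cKDTree(fiber.nucleosome_centers)
    pairs = tree.query_pairs(r=diameter, output_type="ndarray")
    out = []
    c = fiber.nucleosome_centers
    for i, j in pairs:
        i, j = int(min(i, j)), int(max(i, j))
        if j - i >= 2 and np.linalg.norm(c[i] - c[j]) < diameter:
            out.append((i, j))
    return sorted(out)


def fiber_metrics(
    fiber: FiberGeometry, window: int = AXIS_WINDOW
) -> FiberMetrics:
    """Packing ratio and diameter relative to a smoothed fiber axis.

    The axis is the sliding-window centroid curve (window ``w`` nucleosomes);
    each of its ``n - w`` steps advances the window by one nucleosome, so the
    packing ratio is ``11 nm / (mean axis step length)`` nucleosomes per
    11 nm of axis. The fiber diameter is twice the largest radial distance
    of any center from the axis polyline plus the nucleosome diameter. For a
    straight fiber these reduce exactly to ``11 / spacing`` and the bare
    nucleosome diameter.
    """
    c = fiber.nucleosome_centers
    n = len(c)
    if n < window + 1:
        raise ValueError(
            f"axis undefined: need more than window = {window} nucleosomes"
        )
    kernel = np.ones(window) / window
    axis = np.column_stack(
        [np.convolve(c[:, k], kernel, mode="valid") for k in range(3)]
    )
    steps = np.diff(axis, axis=0)
    arc = float(np.linalg.norm(steps, axis=1).sum())
    if arc <= 0:
        raise ValueError("degenerate axis: zero arc length")
    packing = 11.0 * (n - window) / arc
    max_radial = max(
        float(_point_polyline_distance(p, axis)) for p in c
    )
    return FiberMetrics(
        packing_ratio=packing,
        fiber_diameter=2.0 * max_radial + fiber.nucleosome_diameter,
        axis_curve=axis,
        clashes=detect_clashes(fiber),
    )


def _point_polyline_distance(p: np.ndarray, poly: np.ndarray) -> float:
    """Distance from point p to the smoothed-axis polyline.

    The first and last segments extrapolate beyond the polyline span so that
    end nucleosomes (which always lie beyond the windowed centroids) measure
    their perpendicular, radial distance rather than the distance to the
    axis endpoint.
    """
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    ap = p - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.zeros(len(a))
    nz = denom > 0
    t[nz] = np.einsum("ij,ij->i", ap[nz], ab[nz]) / denom[nz]
    lo = np.zeros(len(a))
    hi = np.ones(len(a))
    lo[0] = -np.inf
    hi[-1] = np.inf
    t = np.clip(t, lo, hi)
    closest = a + t[:, None] * ab
    d = np.linalg.norm(p - closest, axis=1)
    return float(d.min())
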