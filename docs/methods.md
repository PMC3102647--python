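# Methods

`chromofold` implements four polymer-physics model families for hierarchical
genome organization, from the gene locus (10–2000 kbp) up to whole
chromosomes (1–200 Mbp). This note records the models, their assumptions,
the parameters that matter, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Worm-like-chain locus compaction (`chromofold.wlc`)

A gene locus is a worm-like chain (WLC) of fixed contour length `Lc` whose
effective persistence length `Lp` absorbs all consequences of chromatin
remodeling (nucleosome depletion, histone modification). The Kratky–Porod
mean-square end-to-end distance

    <R²> = 2·Lp·Lc − 2·Lp²·(1 − exp(−Lc/Lp))

is evaluated with `expm1` so the rigid-rod limit (`Lc ≪ Lp`, `<R²> → Lc²`)
is accurate to machine precision; the ideal-chain limit (`Lc ≫ Lp`) gives
`<R²> → 2·Lp·Lc`, where the final/initial size ratio under an `Lp` change at
fixed `Lc` reduces exactly to `Lp_f/Lp_i`. `compaction_ratio` uses that
exact limit when no contour length is supplied and warns when a supplied
`Lc/Lp < 100`, the regime where the full formula visibly departs from the
limit. For the canonical remodeling scenario (`Lp` 280 → 140 nm) the ratio
is 1/2, a 29.3 % RMS compaction.

The Flory argument converts the size change into a contact change: binary
intrachain interactions scale as the squared segment concentration,
`n_b ~ c²`, `c ~ 1/V`, and with spherical symmetry `V ~ <R²>^{3/2}`, so the
interaction ratio is `(r²-ratio)^(−3)` — an 8-fold gain for a halved `<R²>`.
The spherical-symmetry assumption and the neglect of excluded volume, stable
loops and fiber–fiber interactions make this a scaling estimate, not a
quantitative contact count.

**Cross-validation.** The closed form is tested against an independent
Monte Carlo oracle: a discretized WLC whose bend angles are drawn from the
Boltzmann density `∝ exp(κ·cosθ)`, `κ = Lp/ds`, by inverse-transform
sampling. At 800 segments the discretization bias of the oracle is ≈0.02 %,
far below its sampling error at 2×10⁴ chains.

## Folding-index framework (`chromofold.wlc`)

At the genome-wide level the chain is freely jointed with Kuhn length
`l = 2·Lp`: `N_r = Lc/(2Lp)` repeat units, folded size `C_s = 2Lp·N_r^ν`,
and folding index `Φ = Lc/C_s = N_r^{1−ν}` — the compaction of the fully
extended contour, usable as a variable-resolution lens across organization
levels. Genomic spans convert to contour length through the linear mass
density, default 2.94 bp/nm for dsDNA (6 Gbp ≈ 2.04 m); the B-DNA rise
0.34 nm/bp is used where a per-bp rise is natural (linker geometry).

Holding the folded size fixed at the nuclear size `C_s,0` (default 25 μm —
the empirical invariant: the 2 m genome at `Lp = 50 nm`, `ν = 1/3` folds to
27.1 μm, the nuclear scale) makes Φ a function of `Lp` alone:
`Φ = (C_s,0/2Lp)^{(1−ν)/ν}`, quadratic at `ν = 1/3`, with the exact inverse
`Lp = (C_s,0/2)·Φ^{−ν/(1−ν)}`. The general-ν form is an extension of the
`ν = 1/3` case, obtained by the same substitution `N_r = (C_s,0/2Lp)^{1/ν}`.

Two routes to the human-genome folding index deliberately disagree:
`Lc/C_s` with the rounded nuclear size 25 μm gives 8×10⁴, while the exact
repeat-unit route gives `(2×10⁷)^{2/3} = 7.37×10⁴` (and `(250)² = 6.25×10⁴`
if `Lp = 50 nm` is inserted in the quadratic relation). The package computes
each route separately and never forces agreement; the spread is pure
rounding of `C_s`.

## Lattice Monte Carlo of hinged stiff chains (`chromofold.lattice`)

**Model.** Phantom (self-intersecting) chains of `N` unit bonds on the
cubic lattice, energy `E = Σ_v ε_v·(1 − cosθ_v)` over interior vertices with
`cosθ ∈ {1, 0, −1}`, temperature fixed at 1 `k_B T`. The stiff background is
`ε = 2 k_B T`; a hinge is `ε = 0`, so the stiff/flexible gap is the nominal
2 `k_B T` per segment. Excluded volume is deliberately absent: the
qualitative hinge-collapse mechanism, not a quantitative fiber model, is the
target.

**Sampling.** The chain state is its bond-direction sequence. Moves: pivot
(random element of the full 48-element octahedral group applied to all bonds
after a random junction — only that junction's angle changes energy), corner
flip (swap of adjacent bond directions), and end re-draw; mix 0.2/0.7/0.1.
Acceptance is standard Metropolis on the bending-energy difference, verified
against exhaustive 6³-state enumeration of a 3-bond chain. One sweep = `N`
attempted moves; defaults are 10·N equilibration sweeps and sampling every
`max(1, N/8)` sweeps (pivots decorrelate phantom chains within a few
sweeps). Error bars are replicate-level standard errors over independent
seeds (32 by default) derived from a master seed by counter-based
`SeedSequence` splitting — no autocorrelation correction inside runs is
needed, and adding replicates never reshuffles earlier ones.

**Exact references.** At `ε ≡ 0` the sampler must reproduce
`<Ree²> = N` and `<Rg²> = N(N+2)/(6(N+1))` (the closed form is itself
re-derived in the tests by enumerating all walks at small N). At uniform ε
the direction sequence is a 6-state Markov chain whose transfer matrix
`T = exp(−ε(1−cosθ))` has constant row sums, so its Perron vector is uniform
and both the per-vertex mean `⟨cosθ⟩ = (1−e^{−2ε})/(1+4e^{−ε}+e^{−2ε})` and
the exact tangent correlation `⟨t_i·t_{i+s}⟩ = ⟨cosθ⟩^s` follow. The
persistence-length estimator fits `ln⟨t_i·t_{i+s}⟩` against `s`
(slope `−1/Lp`), reports `Lp = 0` for memoryless chains, raises a fit-range
error on nonpositive correlations inside the range, and flags fits with
`Lp > N` as rod-like.

**Hinge-collapse experiment.** For each chain length the radius-of-gyration
ratio `R(k) = <Rg²>(k hinges, stiff background) / <Rg²>(fully flexible)` is
reported. This normalization is a package convention (recorded in the output
metadata): it makes the fully flexible chain the fixed point `R = 1` and the
uniformly stiff chain the upper envelope. Hinges are *extended* soft
regions, by default `max(1, N/16)` vertices each, centred at the equally
spaced interior positions `⌊j·(n_vertices+1)/(k+1)⌋`: remodeling acts on a
stretch of fiber, and a single-vertex defect in a long phantom chain leaves
the extensive `<Rg²>` unchanged to below sampling resolution, which would
make the collapse unobservable at N = 256. Width and placement are fully
configurable. Expected behaviour — `R` decreasing in hinge count, increasing
in chain length, stiff/flexible asymptote `(1+⟨cosθ⟩)/(1−⟨cosθ⟩) ≈ 4.4` at
`ε = 2` — is checked as a direction/ordering property only; no published
table of ratio values is matched cell-by-cell, since ratio normalizations
differ across conventions.

## Two-angle fiber geometry (`chromofold.two_angle`)

Nucleosomes are spheres (diameter 11 nm) at the vertices of a deterministic
construction driven by the entry–exit angle α and the rotation β of
successive kink planes about the linker axis; β derives from the linker
length through the DNA helical repeat (10.5 bp/turn), with linker length
`linker_bp · 0.34 nm`. Conventions, declared because the two-angle
literature does not fix them: α = 180° means no kink (straight
beads-on-a-string); β is a right-handed roll about the incoming linker
applied before the kink; the first linker lies along +x with the kink plane
in xz. α = 0 is degenerate (each linker folds back on itself) and is
returned with an immediate-clash warning.

The fiber axis is the sliding-window centroid curve (window 5 nucleosomes).
The packing ratio is `11 nm / (mean axis step length)` nucleosomes per 11 nm
— each axis step advances the window by one nucleosome, so a straight fiber
with spacing `d` gives exactly `11/d`. The fiber diameter is twice the
maximal radial distance of any center from the axis polyline (terminal
segments extrapolated so end nucleosomes measure perpendicular distance)
plus the nucleosome diameter; a straight fiber returns exactly the bare
diameter. Clashes are unordered non-bonded pairs (|i−j| ≥ 2) with center
distance strictly below the nucleosome diameter. No linker elasticity,
electrostatics, histone tails or Monte Carlo relaxation: this is the plain
geometric model.

## Loop models and globule ensembles (`chromofold.loops`)

Granularity: 1 bead = 10 kbp by default, so the 150 kbp random-loop cutoff
is 15 beads; both are configurable.

**Random loop model.** Gaussian backbone plus extra harmonic bonds added
independently with probability `p` between all pairs at least the cutoff
apart; loop springs default to backbone strength (configurable multiplier).
Mean-square distances are exact through the Moore–Penrose pseudo-inverse of
the connectivity Laplacian, `<r_ij²> = b²(Γ⁺_ii + Γ⁺_jj − 2Γ⁺_ij)`, reducing
to `|i−j|·b²` at `p = 0`. Profiles are averaged over independently drawn
loop configurations (the model's account of cell-to-cell variation). The
plateau at large genomic separation (effective exponent → 0) sets in for
`p ≳ 3×10⁻⁴` at 512 beads; the analysis sweeps `p` rather than asserting one
curve. The independent check samples the same network through the Cholesky
factor of the pinned precision matrix — a sampling route that never touches
the pseudo-inverse identity.

**RW-GL.** Consecutive closed Gaussian loops (Brownian bridges returning to
their anchor) of `loop_size` beads (default 200 beads = 2 Mbp, mid-range of
the Mbp-scale giant loops), anchored on an independent Gaussian random-walk
backbone with per-step variance defaulting to one bond variance — a backbone
much shorter than its loops, which is what levels distances off beyond the
loop scale (`<r²(s)> ≈ m·b²/3 + (s/m)·σ_b²` for `s ≫ m`). Within one loop
the bridge gives exactly `s(m−s)/m·b²`. Pairs with `s` close to the chain
length are dominated by the few anchor-adjacent beads; scaling fits should
stay within `s ≲ 0.8·N`.

**Chain ensembles.** Unconfined mode: plain phantom lattice walks (ideal
chain, `ν = 1/2`, moment ratio `5/3 − 2/(3s)` exactly). Confined mode:
lattice walks whose steps are drawn uniformly among the directions keeping
the bead inside a cubic box — unit bonds always, beads never outside. The
fractal-globule comparison measures `Rg²` against chain length at fixed
density. Study conditions: melt density 1 bead/site in exact-cube boxes,
sizes N ∈ {1728, 4096, 8000, 13824} (sides 12–24), 64 chains each. The melt
is the space-filling reading of a chromosome packing its territory, and
exact cubes avoid box-rounding distortion of the density. The apparent
exponent carries an `O(1/side)` surface/equilibration correction biasing it
slightly above 1/3 (measured ≈ 0.35 at these sizes, vs ≈ 0.37 at density 0.5
in smaller boxes); it decays with box size and is reported, not subtracted.

**Diagnostics.** `fit_scaling_exponent` is a log–log least-squares slope
(via `scipy.stats.linregress`), halved when the input is a mean-square size.
Contact probability is the fraction of conformations with pair distance
below a capture radius (default 2 bond lengths; sensitivity to the radius is
an output, not hidden) — for open chains the large-s exponent approaches the
Gaussian return value −3/2. The moment ratio `<r⁴>/<r²>²` discriminates
chain statistics: 1 for rods, 5/3 for Gaussian chains, ≥ 1 always.

## What the generators emulate — and what they do not

The built-in generators produce phantom semiflexible lattice chains with
region-wise bending energies, Gaussian networks with random long-range
bonds, closed-loop backbones, and density-fixed confined walks. They emulate
the statistical signatures these models predict for chromatin — size ratios,
distance plateaus, scaling exponents, contact-probability decays — under
idealized conditions: no excluded volume (except the geometric clash test in
the fiber builder), no fiber heterogeneity beyond the stiffness map, no
dynamics, no sequence specificity, and no measurement noise of imaging or
crosslinking assays. Passing tests therefore validate the implementations
and the internal consistency of the theory at these scales; they do not by
themselves establish that real chromatin follows any of these models.

## Numerical choices and problem sizes

- Internal length unit: nm in the continuous models; lattice/bond units in
  the discrete models. PDB output converts nm → Å (×10).
- Seeds: every stochastic routine takes an explicit seed; replicate and
  condition seeds derive from a master seed via `SeedSequence([master,
  *counters])`, truncated to 31 bits for the compiled sampler.
- The MC kernel is numba-compiled; the first call in a session pays a
  few-second JIT cost.
- Default experiment sizes (hinge collapse N ≤ 256 with 32 replicates and 48
  samples per run; globules to N = 13824 with 64 chains; 20-40 loop
  topologies of ≤ 512 beads) were chosen so each analysis completes in
  seconds to a few minutes on one CPU while keeping replicate-level standard
  errors a few percent — small enough that every monotonicity gap tested is
  several standard errors wide.
- Degenerate inputs are contracts, not crashes: zero-length chains return 0,
  `ν = 1` is rejected where folding must be inverted, empty loop-eligible
  sets warn and return empty topologies, nonpositive tangent correlations
  raise a fit-range error naming the remedy.

## Known limitations

- Table-style quantitative matching of hinge-collapse ratios across
  publications is out of scope: normalization conventions for such ratios
  are not standardized, so only direction and ordering are asserted.
- The confined-globule exponent retains the finite-size surface bias
  described above (≈ +0.02 at the default sizes).
- The two-angle builder has no excluded-volume relaxation: clashing
  geometries are reported, not repaired.
- The WLC/FJC analytics are scaling arguments; prefactors (e.g. the Flory
  contact gain) should be read as orders of magnitude for real loci.
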