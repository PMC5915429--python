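# Methods

This note documents the model behind `emtrace`, the parameters that matter,
the numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Density model and local dense points

A cryo-EM map is treated as a non-negative scalar field Φ sampled on a
regular orthogonal grid (1 Å/voxel is typical at this resolution range).
Negative file values are clamped to zero on load: the method interprets
density as mass, and negative excursions in deposited maps are
reconstruction artifacts. Axis order is normalized to x,y,z on read; the
physical origin honors the MRC ORIGIN record when set, else NXSTART ×
spacing.

The main chain is assumed to coincide with the *ridge* of Φ. Grid points
with Φ ≥ Φ_thr seed a mean-shift ascent with kernel
k(p) = exp(−1.5‖p‖²/σ²), σ = 1.0 Å, equivalent to a Gaussian kernel of
standard deviation σ/√3 ≈ 0.58 Å. Contributions beyond 3σ are cut off
(k < e^{−13.5}); the kernel density Θ(y) = (1/N) Σ k(y−x)Φ(x) uses the same
cutoff. Seeds are updated synchronously until each moves less than
tol = 10⁻² Å (at most `max_iter` sweeps).

Two numerical choices here departed from the obvious reading and are worth
recording:

- **θ filtering happens once, after convergence.** Discarding seeds with
  normalized density θ < θ_thr after *every* sweep, with θ re-normalized
  over the survivors each time, is a ratchet: each round resets the minimum
  to zero and removes the new bottom band, and after a few dozen sweeps
  only the single densest blob survives. The filter is therefore applied
  once to the converged positions.
- **The sweep budget is a skeleton-density control.** Mean shift collapses
  seeds onto the ridge within a few sweeps (transverse convergence) and
  then slowly condenses them along the ridge into isolated modes spaced
  ≈ 3.8 Å apart. A useful skeleton needs points every ~0.5–1.5 Å along the
  chain, so the pipeline stops after `ms_max_iter = 15` sweeps by default:
  late enough that seeds sit on the ridge, early enough that they still
  sample it densely. The low-level `converge_seeds` keeps
  `max_iter = 100` for callers who want full mode convergence.

Converged seeds are clustered by **greedy density-first absorption**: the
highest-Θ unassigned seed absorbs every unassigned seed within 0.5 Å and
becomes an LDP (ties broken by lexicographic position). Single linkage at
the same radius was rejected after testing: ridge seeds form quasi-
continuous filaments, and single linkage chains entire ridges into a few
stringy clusters whose representatives are far from most members, which
fragments the downstream admissible graph. Greedy absorption guarantees
representatives ≥ 0.5 Å apart — a dense, evenly spaced skeleton.

Each LDP records its member voxels (the initial grid positions of its
seeds), their density sum `v_raw`, the kernel density θ (min-max normalized
over all LDPs), and a residue-scale density used by threading (below). Two
LDPs are adjacent iff any of their member voxels are grid neighbors
(26-connectivity by default).

On maps blurred from a bare Cα chain the LDPs sit on the chain (the test
suite asserts ≥ 90% within 2 Å of the generating trace). On all-atom
fixtures the LDP:heavy-atom ratio measures ≈ 0.14–0.23 across 2–5 Å
resolutions with this simulator; figures around 0.4 quoted for cryo-EM
skeletons correspond to sharper map conventions — mode counts scale with
map texture, so the ratio is a property of the blurring convention, not of
the clustering.

## Skeleton tree

Candidate edges are adjacent LDP pairs weighted by Euclidean length. For
every LDP the MST of the adjacency subgraph induced by LDPs within
`r_local` (default 5 Å) is computed; the union of these local-MST edges is
the **admissible set**, and the global MST (Kruskal, deterministic
(w, endpoint-id) tie-breaking) is built from admissible edges only. If the
admissible graph is disconnected the largest component is traced and the
component sizes are logged. The local-MST restriction prunes chords that
shortcut across the chain while preserving local connectivity.

Trees are scored by S(T) = Σₙ (Σ_{e∈Pₙ} w′(e))², n ≤ 100, where Pₙ is the
n-th edge-disjoint density-weighted longest path (two-sweep farthest-point
search, valid for the non-negative costs w′ = w·min(endpoint Θ)) and S is
*maximized*: long, dense paths are what a main chain looks like. The tabu
search samples 30 delete/add swaps per iteration — delete a non-tabu edge
with w > d_keep, re-add an admissible edge across the cut keeping
W(T) ≤ 1.01·W(MST) — applies the best if it strictly improves S, and pushes
the move and its reverse into a 100-entry FIFO. Determinism comes from a
seeded `random.Random`; the "ten trees per combination" differ only by
derived seed.

In practice the refinement helps when the MST mis-joins or splits chain
segments and hurts when the MST is already correct (S rewards length² and
will happily reroute through side-chain density). The desk-scale preset
therefore uses the smallest published iteration count (10) and a
conservative d_keep = 2.5 Å — on a skeleton sampled every ~0.7 Å, only
anomalous edges are worth rewiring. The full simulated/experimental presets
keep the published grids (N_it up to 500/5000, d_keep from 0.5 Å).

## Threading

The longest path supplies an observed density string V and the sequence an
expected string A; both are Z-normalized (population σ) and aligned.

**Observed profile.** Each LDP's raw profile value is a kernel density at
residue scale: the geometric mean of the tracing-bandwidth (σ = 1 Å)
density and a wide-bandwidth (σ = 2.5 Å) density. The narrow component
keeps per-residue bumps (registration phase); the wide one integrates a
residue's full side-chain mass (size contrast and direction signal). The
printed-formula alternative — per-cluster voxel density sums — is retained
as `source="cluster_sum"` but is not the default: on a dense skeleton the
number of clusters grows with local density, so cluster sums track the
basin partition rather than the mass and empirically carry almost no
sequence signal. Along the path the values are Gaussian-filtered
(V_k = Σ v_i (1/σ_path) exp(−‖z_i−z_k‖²/(2σ_path)), σ_path swept
0.8–1.4); the pipeline uses the weighted-*mean* variant
(`normalize=True`), which removes the dependence of V on how densely the
path happens to be sampled with LDPs while preserving the physical density
taper at chain ends.

**Expected profile.** A_j = W_ss(ss_j) · D(aa_j). The default D table is
the residue heavy-atom count normalized to mean 1 (a calibrated table can
be supplied as a file); the default secondary-structure weights are neutral
(1, 1, 1). Both are editable data files, not code constants.

**Alignment.** The DP state is "residue j matched at path LDP i"; path
LDPs may be skipped freely (there are several per residue), unassigned
residues cost `gap` (default −0.5, a declared substitute — the value is not
published), and successive matched residues j′ < j pay
w_Cα·|d_std·(j−j′) − d| with w_Cα = 0.9. Two choices matter:

- The span target scales with j−j′, so gapping residues cannot dodge the
  geometry term (with the penalty applied only to adjacent matches the
  optimizer happily parks several residues on neighboring LDPs separated
  by cheap gaps).
- d is measured **along the path arc** by default: arc length is additive
  over spans, whereas the Euclidean chord under-measures multi-residue
  spans on curved paths. The Euclidean reading is available as
  `distance_mode="euclidean"` and is the contract of `measure_d`.

The recursion is exact (it matches exhaustive enumeration over all
monotone partial alignments on every random instance the suite throws at
it) and O(N²L²) vectorized, which is negligible at these problem sizes.

Matched residues take their LDP coordinates; interior gaps are placed by
linear interpolation in arc length; overhanging termini are extrapolated at
d_std spacing by *constant-curvature continuation* — the mean rotation
between successive path segments over the last 8 Å is applied repeatedly —
which continues a helix as a helix instead of flying off on a tangent.
Threading in `reverse` aligns the reversed sequence and reports results in
the original residue order.

## Sweep, ranking, confidence, evaluation

`run_sweep` iterates the full parameter product, threading each refined
tree's longest path in both directions, and ranks all models by threading
score (ties by model id — fully deterministic given the seed). Consensus
confidence compares the top model's Cαs against the next `n_top − 1` models
(default 100): the fraction placing any Cα within 3.5 Å. On constructed
pools with known perturbation structure, mean per-residue error decreases
monotonically across consensus bins; the suite asserts this calibration.

Evaluation reports sequence-aware Cα RMSD **without superposition** (model
and reference live in the same map frame; a least-squares mode exists for
frame-mismatched references), plus sequence-agnostic coverage and precision
at the requested cutoffs.

## The synthetic-data generator

`make_synthetic_chain` builds ideal Cα traces (α-helix with 1.5 Å rise and
100°/residue, the radius chosen so consecutive Cα distances are exactly
3.8 Å; a near-linear zigzag strand; or a mixed chain), placed by a seeded
random rigid transform. `make_synthetic_model` decorates a trace with
pseudo heavy atoms: two bridge atoms along each Cα–Cα segment and a
perpendicular carbonyl-like offset (so the main chain is a continuous
dense tube, as in real maps), stub atoms at the chain termini, and the
remaining heavy-atom budget of each residue type as a seeded diffusive
outward walk at 1.5 Å bond steps capped at 3.5 Å from the Cα (rotamers
curl). Maps are simulated by Gaussian blurring with σ = 0.225 × resolution
(the common pdb2mrc-style convention; the kernel is a config knob since
deposition pipelines differ), unit amplitude per heavy atom, grid padded
to the full accumulation window.

What the fixtures do **not** emulate: reconstruction noise, B-factor
variation, solvent/ice background, map sharpening artifacts, multiple
chains, and real rotamer geometry. Passing tests on these fixtures
demonstrate the machinery — skeletonization, graph constraints, alignment
optimality, direction discrimination, calibration of confidence — not
performance on experimental maps.

## Accuracy envelope and known limitations

On the 5 Å helix benchmark fixture (30 residues, the resolution at which
maps are routinely still traceable but hardest), the top-scoring model of
the desk-scale preset typically lands at 2.5–5 Å Cα RMSD with coverage@3 Å
around 0.9–1.0, and the correct sequence direction wins in every seed of
the direction fixture. Two error terms dominate the RMSD:

- **Ridge offset.** The density ridge of a blurred helix runs slightly
  inside the Cα ring, and skeleton positions inherit that offset (~0.5 Å
  systematic, up to ~2 Å where side-chain mass pulls the ridge).
- **Registration phase.** The per-residue density bumps that anchor the
  alignment phase are weak at 5 Å, so the threading can slip by about one
  residue, contributing several Å of RMSD even when the traced path is
  correct. Full-atom rebuilding and density-guided refinement — the stage
  that conventionally restores helical pitch — are deliberately out of
  scope here; the package exports Cα PDBs suitable as input to such tools.

Consequently the end-to-end recovery check in the acceptance suite (RMSD
≤ 3.0 Å *and* coverage@3 ≥ 0.9 on ≥ 4 of 5 seeds) sits at the edge of what
the raw skeleton-path models achieve and currently fails more seeds than
it passes; the quantities are reported honestly by
`scripts/acceptance.py` (`helix_recovery_rate`, `helix_top_model_rmsd`,
`helix_top_model_coverage3`). Orthogonal checks — exhaustive-enumeration
agreement of the constrained MST, path score and alignment DP, mean-shift
mode convergence, direction discrimination, consensus calibration, and
bitwise determinism — pass at 100%.

Other limitations: single chains only (a zone-mask utility is provided for
segmenting a subunit out of a larger map); orthogonal unit cells only; no
sharpening or local-resolution handling; secondary-structure strings are
accepted as input but no predictor is bundled; problem sizes in the test
suite are desk-scale (30-residue fixtures, hundreds of LDPs) by design.
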