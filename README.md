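# emtrace

De novo Cα main-chain tracing from near-atomic-resolution cryo-EM density
maps.

Given an EM density map (MRC/CCP4) at roughly 2.5–5 Å resolution and the
protein's sequence, `emtrace` builds ranked Cα models fully automatically —
no template or fragment structures — by treating the main chain as the
dense skeleton of the map:

1. **Local dense points (LDPs).** Grid points above a density threshold
   Φ_thr are used as seeds of the mean-shift algorithm with a Gaussian
   kernel `k(p) = exp(−1.5‖p‖²/σ²)` (bandwidth σ = 1 Å). Converged seeds
   are clustered at 0.5 Å; each cluster's density peak becomes an LDP, and
   LDPs whose member voxels touch on the grid are labelled adjacent.
2. **Constrained minimum spanning tree.** LDPs are connected into the MST
   minimizing total Euclidean edge length `W(T) = Σ w(e)`, restricted to
   adjacent pairs that appear in at least one *local* MST (the MST of the
   LDPs within a sphere of radius `r_local` around each LDP).
3. **Tabu-search refinement.** Trees are rescored with
   `S(T) = Σₙ (Σ_{e∈Pₙ} w′(e))²`, where `P₁, P₂, …` are edge-disjoint
   density-weighted longest paths and `w′(e) = w(e)·min(Θ)` over the edge's
   endpoints. A tabu search (bounded FIFO of forbidden edge swaps, 30
   candidate moves per iteration, total length within 1% of the MST's)
   maximizes S.
4. **Sequence threading.** The longest path's density profile `V_k`
   (smoothed per-LDP kernel densities) is aligned with the sequence's
   expected-density profile `A_j` (per-residue density table × secondary-
   structure weight) by dynamic programming: match reward
   `SCO = 1 − |Z(V) − Z(A)|`, a Cα-geometry penalty
   `−w_Cα·|d_std·Δj − d|` between successive matched residues, a gap
   penalty per unassigned residue, free gaps on the path side. Both
   sequence directions are threaded.
5. **Model pool.** A sweep over (Φ_thr, θ_thr, r_local, d_keep, N_it,
   σ_path, d_std, direction) yields thousands of models, ranked by
   threading score. Per-residue **consensus confidence** — the fraction of
   the other top models placing a Cα within 3.5 Å — flags which regions of
   the top model are reliable.

A built-in simulator (Gaussian blurring, σ = 0.225 × resolution, 1 atom =
unit amplitude) generates maps from atomic models, and synthetic
helix/strand fixtures support testing end to end.

## Worked example

Simulate a 5 Å map of a 30-residue helix with pseudo side chains, then
trace it:

```python
import emtrace
seq = "GGASGASTGASTSAVTLQELKFEQLKFREW"
model = emtrace.make_synthetic_model(seq, "helix", seed=7)
grid = emtrace.simulate_map(model, resolution=5.0, spacing=1.0)
emtrace.write_map(grid, "helix.mrc")
```

```text
$ emtrace trace helix.mrc helix.fasta --seed 1 --out-dir demo_out --top 5
16 models generated; top threading score 8.389 (forward); results in demo_out/

$ head -3 demo_out/manifest.tsv
rank  model_id  threading_score  direction  phi_thr  theta_thr  r_local  d_keep  n_iter  tree  sigma_path  d_std
1     2         8.389348         forward    0.83212  0.1        5.0      2.5     10      0     0.9         3.4
2     10        8.389348         forward    0.83212  0.1        5.0      2.5     10      1     0.9         3.4

$ emtrace evaluate demo_out/model_000002.pdb native.pdb
ca_rmsd        3.721
coverage@2.0   0.833
precision@2.0  0.967
coverage@3.0   0.967
precision@3.0  1.000
```

The top-ranked model threads the sequence in the correct direction; 96.7%
of the true Cα positions lie within 3 Å of the model and every model Cα is
within 3 Å of the true trace. The 3.7 Å sequence-aware RMSD is typical of a
raw skeleton-path model on a 5 Å helix map: the traced path sits on the
density ridge, slightly inside the Cα ring, and registration can slip by
about one residue (see `docs/methods.md`).

The `trace` command also writes `confidence.tsv` and stores consensus × 100
in the top model's B-factor column, so low-confidence regions can be
colored directly in a viewer. Presets: `--preset fast` (default,
desk-scale), `simulated` (24 tree combinations × 10 trees × 112 threadings
= 26,880 models per map), `experimental` (72 × 10 × 112 = 80,640; requires
`--contour`). Any knob can be overridden with a `key=value` config file.

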