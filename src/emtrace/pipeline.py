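"""Parameter sweep, model pool ranking, consensus confidence, evaluation.

One tracing run sweeps a grid of stage parameters: seed density threshold
phi_thr, normalized LDP threshold theta_thr, local-MST radius r_local,
tabu-search d_keep and iteration count, then per refined tree a grid of
threading parameters (sigma_path, d_std, both sequence directions). Every
combination yields one Calpha model; the pool is ranked by threading score.
Consensus confidence marks, per residue of the top model, the fraction of
other top models that place a Calpha nearby — regions of high consensus are
reliably modeled.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .map_io import (AtomicModel, DensityGrid, EmptyThresholdError, write_ca_pdb)
from .ldp import EmptyResultError, find_ldps
from .tree import admissible_edges, build_mst, k_longest_paths, tabu_refine
from .threading import (ThreadedModel, path_profile, residue_profile,
                        thread_sequence, DEFAULT_GAP, DEFAULT_W_CA)

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "ModelPool",
    "EvalReport",
    "fast_preset",
    "simulated_preset",
    "experimental_preset",
    "resolve_phi",
    "run_sweep",
    "rank_and_select",
    "consensus_confidence",
    "evaluate",
    "write_models",
    "load_config",
]


@dataclass
class ParameterGrid:
    """The sweep grid. phi_thr entries are absolute densities, or
    ``("rel_max", f)`` for f x map maximum, or ``("contour", f)`` for
    f x a user-supplied recommended contour level."""

    phi_thr: list
    theta_thr: list
    r_local: list
    d_keep: list
    n_iter: list
    n_trees: int = 10
    sigma_path: list = field(default_factory=lambda: [1.0])
    d_std: list = field(default_factory=lambda: [3.8])
    directions: tuple = ("forward", "reverse")
    w_ca: float = DEFAULT_W_CA
    gap: float = DEFAULT_GAP
    sigma: float = 1.0            # mean-shift bandwidth
    merge_dist: float = 0.5
    connectivity: int = 26
    n_paths: int = 100
    ms_max_iter: int = 15      # mean-shift sweeps: transverse collapse onto the
                               # chain ridge without condensing along it
    ms_tol: float = 1e-2

    def __post_init__(self):
        for name in ("phi_thr", "theta_thr", "r_local", "d_keep", "n_iter",
                     "sigma_path", "d_std"):
            if not getattr(self, name):
                raise ValueError(f"parameter list {name} must be nonempty")

    @property
    def n_combos(self) -> int:
        return (len(self.phi_thr) * len(self.theta_thr) * len(self.r_local)
                * len(self.d_keep) * len(self.n_iter))

    @property
    def n_models(self) -> int:
        return (self.n_combos * self.n_trees * len(self.sigma_path)
                * len(self.d_std) * len(self.directions))


def simulated_preset() -> ParameterGrid:
    """Grid used for 5 A simulated maps: 24 tree combinations x 10 trees x
    112 threadings = 26,880 models per map. Seed thresholds are expressed
    relative to the map maximum (this simulator normalizes atom amplitude
    to 1, so absolute thresholds do not transfer between conventions)."""
    return ParameterGrid(
        phi_thr=[("rel_max", 0.10), ("rel_max", 0.15), ("rel_max", 0.20)],
        theta_thr=[0.3],
        r_local=[5.0],
        d_keep=[0.5, 1.0],
        n_iter=[10, 50, 100, 500],
        n_trees=10,
        sigma_path=[0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4],
        d_std=[3.1, 3.2, 3.3, 3.4, 3.5, 3.6, 3.7, 3.8],
    )


def experimental_preset() -> ParameterGrid:
    """Grid used for experimental maps: 72 tree combinations x 10 trees x
    112 threadings = 80,640 models per map. phi_thr derives from the
    author-recommended contour level, supplied at run time."""
    return ParameterGrid(
        phi_thr=[("contour", 0.5), ("contour", 0.25)],
        theta_thr=[0.0, 0.1, 0.2, 0.3],
        r_local=[5.0, 7.5, 10.0],
        d_keep=[0.5, 1.0, 1.5],
        n_iter=[5000],
        n_trees=10,
        sigma_path=[0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4],
        d_std=[3.1, 3.2, 3.3, 3.4, 3.5, 3.6, 3.7, 3.8],
    )


def fast_preset() -> ParameterGrid:
    """Desk-scale default: one tree combination, few trees, two threading
    widths; minutes instead of hours on a single CPU."""
    return ParameterGrid(
        phi_thr=[("rel_max", 0.12)],
        theta_thr=[0.1],
        r_local=[5.0],
        d_keep=[2.5],
        n_iter=[10],
        n_trees=2,
        sigma_path=[0.9, 1.3],
        d_std=[3.2, 3.4],
    )


def resolve_phi(grid: DensityGrid, entry, contour: float | None = None) -> float:
    """Turn a phi_thr grid entry into an absolute density threshold."""
    if isinstance(entry, (int, float)):
        return float(entry)
    mode, frac = entry
    if mode == "rel_max":
        return float(frac) * float(grid.values.max())
    if mode == "contour":
        if contour is None:
            raise ValueError("phi_thr mode 'contour' needs a contour level")
        return float(frac) * float(contour)
    raise ValueError(f"unknown phi_thr entry {entry!r}")


@dataclass
class ModelPool:
    """Ranked collection of threaded models from one sweep."""

    models: list                     # ThreadedModel, threading_score desc
    sequence: str
    consensus: np.ndarray | None = None   # per-residue fraction, top model

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class EvalReport:
    ca_rmsd: float
    coverage: dict          # cutoff -> fraction of native CAs near the model
    precision: dict         # cutoff -> fraction of model CAs near the native
    per_residue_error: np.ndarray


def _sorted_models(models) -> list:
    return sorted(models, key=lambda m: (-m.threading_score, m.model_id))


def run_sweep(grid_map: DensityGrid, sequence: str, pg: ParameterGrid,
              seed: int, ss: str | None = None,
              contour: float | None = None) -> ModelPool:
    """Run the full tracing sweep; fully deterministic given the seed.

    Per (phi_thr, theta_thr, r_local, d_keep, n_iter) combination: LDPs ->
    admissible edges -> MST -> ``n_trees`` tabu-refined trees (distinct
    derived seeds) -> longest path each -> one model per (sigma_path,
    d_std, direction). Combinations that yield no LDPs or no edges are
    skipped with a log entry.
    """
    if not sequence:
        raise ValueError("empty sequence")
    rprof = residue_profile(sequence, ss)
    combos = list(itertools.product(pg.phi_thr, pg.theta_thr, pg.r_local,
                                    pg.d_keep, pg.n_iter))
    models: list = []
    model_id = 0
    for ci, (phi_e, theta_thr, r_local, d_keep, n_iter) in enumerate(combos):
        phi = resolve_phi(grid_map, phi_e, contour)
        try:
            ldps = find_ldps(grid_map, phi, sigma=pg.sigma, theta_thr=theta_thr,
                             merge_dist=pg.merge_dist,
                             connectivity=pg.connectivity,
                             tol=pg.ms_tol, max_iter=pg.ms_max_iter)
        except (EmptyThresholdError, EmptyResultError) as exc:
            logger.info("combo %d skipped: %s", ci, exc)
            continue
        if len(ldps) < 2:
            logger.info("combo %d skipped: fewer than 2 LDPs", ci)
            continue
        try:
            adm = admissible_edges(ldps, r_local)
        except ValueError as exc:
            logger.info("combo %d skipped: %s", ci, exc)
            continue
        mst = build_mst(ldps, adm)
        by_id = {l.id: l for l in ldps}
        for t in range(pg.n_trees):
            tree_seed = (seed * 1000003 + ci * 1009 + t) % (2**31 - 1)
            refined = tabu_refine(mst, adm, d_keep=d_keep, n_iter=n_iter,
                                  seed=tree_seed, n_paths=pg.n_paths)
            verts, _, _ = k_longest_paths(refined, 1)[0]
            path_ldps = [by_id[v] for v in verts]
            for sigma_path in pg.sigma_path:
                pp = path_profile(path_ldps, sigma_path, normalize=True)
                for d_std in pg.d_std:
                    for direction in pg.directions:
                        m = thread_sequence(rprof, pp, gap=pg.gap,
                                            w_ca=pg.w_ca, d_std=d_std,
                                            direction=direction)
                        m.model_id = model_id
                        m.params = {
                            "phi_thr": round(phi, 6), "theta_thr": theta_thr,
                            "r_local": r_local, "d_keep": d_keep,
                            "n_iter": n_iter, "tree": t,
                            "sigma_path": sigma_path, "d_std": d_std,
                        }
                        models.append(m)
                        model_id += 1
    if not models:
        raise EmptyResultError("no parameter combination produced a model")
    return ModelPool(models=_sorted_models(models), sequence=sequence)


def rank_and_select(pool: ModelPool, k: int) -> ModelPool:
    """Stable re-rank by (threading score desc, model id asc); keep top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pool.models):
        logger.warning("requested top %d of a %d-model pool; keeping all",
                       k, len(pool.models))
    models = _sorted_models(pool.models)[:k]
    return ModelPool(models=models, sequence=pool.sequence,
                     consensus=pool.consensus)


def consensus_confidence(pool: ModelPool, n_top: int = 100,
                         cutoff: float = 3.5) -> np.ndarray:
    """Per-residue consensus of the top model among the next-best models.

    For each Calpha of the top-ranked model: the fraction of the other
    ``n_top - 1`` models that place at least one Calpha within ``cutoff``.
    Stored on the pool and returned.
    """
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    if len(pool.models) < n_top:
        logger.warning("pool has %d models < n_top=%d; using all",
                       len(pool.models), n_top)
        n_top = len(pool.models)
    top = pool.models[0]
    others = pool.models[1:n_top]
    counts = np.zeros(top.n_residues)
    for m in others:
        d, _ = cKDTree(m.ca_coords).query(top.ca_coords, k=1)
        counts += d <= cutoff
    frac = counts / max(len(others), 1)
    pool.consensus = frac
    return frac


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Least-squares superposition of P onto Q; returns transformed P."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return (P - pc) @ R.T + qc


def evaluate(model: ThreadedModel, native: AtomicModel,
             cutoffs=(2.0, 3.0), superpose: bool = False) -> EvalReport:
    """Score a model against a reference trace in the same map frame.

    Calpha RMSD is sequence-aware (shared residue numbers, no superposition
    by default since both live in map coordinates; ``superpose=True``
    applies a least-squares fit first). Coverage and precision at each
    cutoff are sequence-agnostic nearest-neighbor fractions.
    """
    nat_res = native.ca_residue_indices()
    nat_pos = native.ca_positions()
    mod_res = model.residue_indices()
    mod_pos = np.asarray(model.ca_coords, dtype=float)
    shared = sorted(set(nat_res) & set(mod_res))
    if not shared:
        raise ValueError("model and native share no residue numbers")
    nat_map = {r: p for r, p in zip(nat_res, nat_pos)}
    mod_map = {r: p for r, p in zip(mod_res, mod_pos)}
    P = np.array([mod_map[r] for r in shared])
    Q = np.array([nat_map[r] for r in shared])
    if superpose:
        P = _kabsch(P, Q)
    per_res = np.linalg.norm(P - Q, axis=1)
    rmsd = float(np.sqrt(np.mean(per_res ** 2)))
    cov, prec = {}, {}
    d_nat, _ = cKDTree(mod_pos).query(nat_pos, k=1)
    d_mod, _ = cKDTree(nat_pos).query(mod_pos, k=1)
    for c in cutoffs:
        cov[c] = float(np.mean(d_nat <= c))
        prec[c] = float(np.mean(d_mod <= c))
    return EvalReport(ca_rmsd=rmsd, coverage=cov, precision=prec,
                      per_residue_error=per_res)


def write_models(pool: ModelPool, out_dir: str,
                 native: AtomicModel | None = None,
                 cutoffs=(2.0, 3.0)) -> None:
    """Write one Calpha PDB per model, a ranked TSV manifest, and (when
    consensus has been computed) a per-residue confidence file; the top
    model's B-factor column carries consensus x 100."""
    if not pool.models:
        raise ValueError("empty model pool")
    os.makedirs(out_dir, exist_ok=True)
    aa3 = {"G": "GLY", "A": "ALA", "S": "SER", "C": "CYS", "T": "THR",
           "V": "VAL", "P": "PRO", "L": "LEU", "I": "ILE", "N": "ASN",
           "D": "ASP", "M": "MET", "Q": "GLN", "E": "GLU", "K": "LYS",
           "H": "HIS", "F": "PHE", "R": "ARG", "Y": "TYR", "W": "TRP",
           "X": "UNK"}
    resnames = [aa3.get(a, "UNK") for a in pool.sequence]
    rows = []
    for rank, m in enumerate(pool.models, start=1):
        bf = None
        if rank == 1 and pool.consensus is not None:
            bf = np.clip(pool.consensus * 100.0, 0.0, 100.0)
        fname = f"model_{m.model_id:06d}.pdb"
        write_ca_pdb(os.path.join(out_dir, fname), m.ca_coords,
                     m.residue_indices(), resnames, bfactors=bf,
                     remarks=[f"THREADING SCORE {m.threading_score:.6f}",
                              f"DIRECTION {m.direction}"])
        row = {"rank": rank, "model_id": m.model_id,
               "threading_score": f"{m.threading_score:.6f}",
               "direction": m.direction}
        for key in ("phi_thr", "theta_thr", "r_local", "d_keep", "n_iter",
                    "tree", "sigma_path", "d_std"):
            row[key] = m.params.get(key, "")
        if native is not None:
            rep = evaluate(m, native, cutoffs=cutoffs)
            row["ca_rmsd"] = f"{rep.ca_rmsd:.4f}"
            for c in cutoffs:
                row[f"coverage@{c}"] = f"{rep.coverage[c]:.4f}"
                row[f"precision@{c}"] = f"{rep.precision[c]:.4f}"
        rows.append(row)
    import pandas as pd
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "manifest.tsv"),
                              sep="\t", index=False)
    if pool.consensus is not None:
        with open(os.path.join(out_dir, "confidence.tsv"), "w") as fh:
            fh.write("residue\tconsensus\n")
            for i, f in enumerate(pool.consensus, start=1):
                fh.write(f"{i}\t{f:.4f}\n")


def load_config(path: str) -> dict:
    """Parse a simple key=value config file mirroring the grid knobs.

    List-valued knobs take comma-separated values; ``rel_max:0.1`` and
    ``contour:0.5`` spell the relative phi_thr modes.
    """
    out: dict = {}
    list_keys = {"phi_thr", "theta_thr", "r_local", "d_keep", "n_iter",
                 "sigma_path", "d_std"}
    int_keys = {"n_trees", "connectivity", "n_paths"}

    def parse_scalar(tok: str):
        tok = tok.strip()
        if ":" in tok:
            mode, frac = tok.split(":")
            return (mode, float(frac))
        return float(tok)

    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        val = val.strip()
        if key in list_keys:
            parsed = [parse_scalar(t) for t in val.split(",")]
            if key == "n_iter":
                parsed = [int(v) for v in parsed]
            out[key] = parsed
        elif key in int_keys:
            out[key] = int(val)
        elif key == "directions":
            out[key] = tuple(t.strip() for t in val.split(","))
        else:
            out[key] = float(val)
    return out
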