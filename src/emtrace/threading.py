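"""Sequence-to-path threading by density-profile dynamic programming.

The longest path of a skeleton tree gives a string of observed densities
V_k (per-LDP cluster density sums, Gaussian-smoothed along the path); the
protein sequence gives a string of expected densities A_j (per-residue
density table times a secondary-structure weight). Both strings are
Z-normalized and aligned by dynamic programming with

  * a match reward  SCO(i,j) = 1 - |Z(V_i) - Z(A_j)|,
  * a chain-geometry penalty  -w_ca * |d_std * (j - j') - d|  between
    successive matched residues j' < j, where d is by default the distance
    along the path arc between their LDPs (Euclidean mode available),
  * a per-residue gap penalty for unassigned residues, and
  * free gaps on the path side (there are several LDPs per residue).

Matched residues take their LDP coordinates; gapped residues are placed by
arc-length interpolation along the path, and overhanging termini are
extrapolated at d_std spacing by constant-curvature continuation of the
path. Threading in the "reverse" direction aligns the reversed sequence to
the same path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueProfile",
    "PathProfile",
    "ThreadedModel",
    "load_density_table",
    "load_ss_weights",
    "residue_profile",
    "path_profile",
    "zscore",
    "zscore_similarity",
    "measure_d",
    "thread_sequence",
    "DEFAULT_W_CA",
    "DEFAULT_GAP",
    "DEFAULT_D_STD",
    "DEFAULT_SIGMA_PATH",
]

DEFAULT_W_CA = 0.9        # weight of the Calpha-distance penalty
DEFAULT_GAP = -0.5        # score per unassigned residue
DEFAULT_D_STD = 3.8       # standard consecutive Calpha-Calpha distance, A
DEFAULT_SIGMA_PATH = 1.0  # width of the along-path density smoothing, A

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _read_table(name: str) -> dict:
    text = resources.files("emtrace").joinpath("data", name).read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split()
        out[key] = float(val)
    return out


def load_density_table(path: str | None = None) -> dict:
    """Per-residue expected density, normalized to mean 1 over its entries."""
    table = _read_table("residue_density.tsv") if path is None else {
        k: v for k, v in
        (line.split() for line in open(path)
         if line.strip() and not line.startswith("#"))
    }
    table = {k: float(v) for k, v in table.items()}
    mean = sum(table.values()) / len(table)
    return {k: v / mean for k, v in table.items()}


def load_ss_weights(path: str | None = None) -> dict:
    """Weights for the three secondary-structure states H/E/C."""
    if path is None:
        return _read_table("ss_weights.tsv")
    out = {}
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split()
        out[k] = float(v)
    return out


@dataclass
class ResidueProfile:
    """Expected per-residue density string A_j for a sequence."""

    sequence: str
    ss: str
    A: np.ndarray

    def __post_init__(self):
        if not (len(self.sequence) == len(self.ss) == len(self.A)):
            raise ValueError("sequence, ss and A must have equal length")

    def reversed(self) -> "ResidueProfile":
        return ResidueProfile(self.sequence[::-1], self.ss[::-1], self.A[::-1])

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PathProfile:
    """Observed density string V_k along a tree path of LDPs."""

    ldp_ids: list
    positions: np.ndarray   # (L,3)
    v_raw: np.ndarray       # (L,) per-LDP cluster density sums
    V: np.ndarray           # (L,) smoothed densities

    def __post_init__(self):
        if not (len(self.ldp_ids) == len(self.positions) == len(self.v_raw)
                == len(self.V)):
            raise ValueError("inconsistent path profile lengths")

    def __len__(self) -> int:
        return len(self.ldp_ids)


@dataclass
class ThreadedModel:
    """One Calpha model: residue coordinates threaded onto a tree path."""

    assignments: list               # per residue: path LDP index or None
    ca_coords: np.ndarray           # (N,3) per-residue coordinates
    direction: str                  # "forward" | "reverse"
    threading_score: float
    params: dict = field(default_factory=dict)
    model_id: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.assignments)

    def residue_indices(self) -> np.ndarray:
        return np.arange(1, self.n_residues + 1)


def residue_profile(sequence: str, ss: str | None = None,
                    d_table: dict | None = None,
                    w_ss: dict | None = None,
                    allow_x: bool = False) -> ResidueProfile:
    """Expected density A_j = W_ss[ss_j] * D[aa_j] for each residue."""
    sequence = sequence.upper()
    if ss is None:
        ss = "C" * len(sequence)
    ss = ss.upper()
    if len(ss) != len(sequence):
        raise ValueError("secondary-structure string length mismatch")
    if d_table is None:
        d_table = load_density_table()
    if w_ss is None:
        w_ss = load_ss_weights()
    mean_density = sum(d_table.values()) / len(d_table)
    A = np.empty(len(sequence))
    for j, (aa, s) in enumerate(zip(sequence, ss)):
        if aa not in d_table:
            if aa == "X" and allow_x:
                A[j] = w_ss[s] * mean_density
                continue
            raise ValueError(f"unknown residue letter {aa!r}")
        if s not in w_ss:
            raise ValueError(f"unknown secondary-structure state {s!r}")
        A[j] = w_ss[s] * d_table[aa]
    return ResidueProfile(sequence=sequence, ss=ss, A=A)


def path_profile(path_ldps: list, sigma_path: float = DEFAULT_SIGMA_PATH,
                 source: str = "kernel", normalize: bool = False) -> PathProfile:
    """Smoothed density string along a path of LDPs.

    The raw value of an LDP is its residue-scale kernel density estimate
    (``source="kernel"``, default) or the sum of map density over its
    cluster's voxels (``source="cluster_sum"``). On dense ridge skeletons
    cluster sums track the basin partition (how many LDPs share a region)
    rather than the local mass, which washes out the per-residue density
    signal; the wide-bandwidth kernel density captures a residue's full
    mass and preserves it. The final value is the Gaussian-filtered
    combination
    V_k = sum_i v_i * (1/sigma_path) * exp(-||z_i - z_k||^2 / (2 sigma_path))
    over the LDPs of the path; with ``normalize=True`` the filter is a
    weighted mean instead (dividing by the weight sum), which removes the
    dependence of V on how densely the path is sampled with LDPs.
    """
    if sigma_path <= 0:
        raise ValueError("sigma_path must be positive")
    if not path_ldps:
        raise ValueError("path must be nonempty")
    if source not in ("kernel", "cluster_sum"):
        raise ValueError("source must be 'kernel' or 'cluster_sum'")
    pos = np.array([l.position for l in path_ldps])
    if source == "kernel":
        v = np.array([l.theta_profile if l.theta_profile > 0 else l.theta_raw
                      for l in path_ldps])
    else:
        v = np.array([l.v_raw for l in path_ldps])
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=2)
    weights = np.exp(-d2 / (2.0 * sigma_path)) / sigma_path
    V = weights @ v
    if normalize:
        V = V / weights.sum(axis=1)
    return PathProfile(ldp_ids=[l.id for l in path_ldps], positions=pos,
                       v_raw=v, V=V)


def zscore(x: np.ndarray) -> np.ndarray:
    """Population Z-score; all-zero when the string has no variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or len(x) < 2:
        if len(x) >= 2:
            logger.info("zero-variance density string; Z-scores set to 0")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def zscore_similarity(V: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Similarity matrix SCO[i, j] = 1 - |Z(V_i) - Z(A_j)| (may be negative)."""
    zv, za = zscore(V), zscore(A)
    return 1.0 - np.abs(zv[:, None] - za[None, :])


def measure_d(path: PathProfile, k_prev: int, k_curr: int) -> float:
    """Euclidean distance between two assigned LDP positions on the path."""
    if not k_prev < k_curr:
        raise ValueError("alignment must be monotone (k_prev < k_curr)")
    return float(np.linalg.norm(path.positions[k_curr] - path.positions[k_prev]))


def _dp_align(SCO: np.ndarray, dist: np.ndarray, gap: float, w_ca: float,
              d_std: float):
    """Core alignment recursion.

    ``D[i, j]`` is the best score of an alignment of residues 0..j in which
    residue j is matched at path LDP i and all earlier matches sit at
    strictly smaller path indices. Unassigned residues cost ``gap`` each
    (leading, internal and trailing alike); path LDPs may be skipped
    freely. The chain-geometry penalty between residue j and the previous
    matched residue j' at LDP i' is ``w_ca * |d_std*(j - j') - dist[i', i]|``
    -- the expected span grows with the number of gapped residues bridged,
    so gapping cannot dodge the geometry term. Returns (score, assignments)
    with assignments mapping residue -> LDP index or None.
    """
    L, N = SCO.shape
    NEG = -np.inf
    D = np.full((L, N), NEG)
    # traceback: predecessor (i', j') of each match, or (-1, -1) for a start
    bI = np.full((L, N), -1, dtype=int)
    bJ = np.full((L, N), -1, dtype=int)
    upper = ~np.tril(np.ones((L, L), dtype=bool))   # i' < i allowed
    lead = np.arange(N) * gap                       # cost of gapping 0..j-1

    for j in range(N):
        best = np.full(L, lead[j])                  # start fresh at residue j
        bi = np.full(L, -1, dtype=int)
        bj = np.full(L, -1, dtype=int)
        for jp in range(j):
            span = d_std * (j - jp)
            trans = (D[:, jp][:, None] + gap * (j - 1 - jp)
                     - w_ca * np.abs(span - dist))  # rows i', cols i
            trans = np.where(upper, trans, NEG)
            cand = trans.max(axis=0)
            better = cand > best
            best = np.where(better, cand, best)
            bi = np.where(better, trans.argmax(axis=0), bi)
            bj = np.where(better, jp, bj)
        D[:, j] = SCO[:, j] + best
        bI[:, j] = bi
        bJ[:, j] = bj

    trailing = (N - 1 - np.arange(N)) * gap
    closed = D + trailing[None, :]
    best_flat = int(np.argmax(closed))
    i_star, j_star = divmod(best_flat, N)
    score = float(closed[i_star, j_star])
    if N * gap >= score:                            # all-gap fallback
        return N * gap, [None] * N

    assignments: list = [None] * N
    i, j = i_star, j_star
    while i >= 0 and j >= 0:
        assignments[j] = i
        i, j = bI[i, j], bJ[i, j]
    return score, assignments


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-9:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def _interp_arc(pos: np.ndarray, arc: np.ndarray, t: float) -> np.ndarray:
    """Piecewise-linear point at arc coordinate t (t within [0, arc[-1]])."""
    k = int(np.clip(np.searchsorted(arc, t) - 1, 0, len(arc) - 2))
    span = arc[k + 1] - arc[k]
    f = (t - arc[k]) / max(span, 1e-12)
    return pos[k] + f * (pos[k + 1] - pos[k])


_TAIL_STEP = 0.5     # arc spacing of extrapolated tail samples, Angstrom
_TAIL_SPAN = 8.0     # length of path end used to estimate local curvature
_TAIL_LEN = 60.0     # how far a tail may extend, Angstrom


def _curved_tail(pos: np.ndarray, arc: np.ndarray) -> np.ndarray:
    """Constant-curvature continuation beyond the far end of a polyline.

    The mean rotation between successive unit segments over the last
    ``_TAIL_SPAN`` A is applied repeatedly: a chain keeps curling the way
    it was curling, which places overhanging termini far better than a
    straight line on helical paths. Returns points at ``_TAIL_STEP`` arc
    spacing marching outward from the end.
    """
    t_end = float(arc[-1])
    ts = np.arange(max(t_end - _TAIL_SPAN, 0.0), t_end + 1e-9, _TAIL_STEP)
    samples = np.array([_interp_arc(pos, arc, t) for t in ts])
    n_steps = int(_TAIL_LEN / _TAIL_STEP)
    if len(samples) < 3:
        u = pos[-1] - pos[0] if len(pos) > 1 else np.array([1.0, 0.0, 0.0])
        u /= max(np.linalg.norm(u), 1e-12)
        return pos[-1] + np.outer(np.arange(1, n_steps + 1) * _TAIL_STEP, u)
    segs = np.diff(samples, axis=0)
    units = segs / np.maximum(np.linalg.norm(segs, axis=1)[:, None], 1e-12)
    R_sum = np.zeros((3, 3))
    for a, b in zip(units, units[1:]):
        R_sum += _rotation_between(a, b)
    U, _, Vt = np.linalg.svd(R_sum / (len(units) - 1))
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    out = np.empty((n_steps, 3))
    p = samples[-1]
    u = units[-1] * _TAIL_STEP
    for k in range(n_steps):
        u = R @ u
        p = p + u
        out[k] = p
    return out


def _place_residues(assignments: list, path: PathProfile, d_std: float) -> np.ndarray:
    """Coordinates for every residue: matched LDPs, arc interpolation in
    gaps, and d_std-spaced constant-curvature extrapolation for
    overhanging termini."""
    pos = path.positions
    L = len(pos)
    if L == 1:
        arc = np.array([0.0])
    else:
        arc = np.concatenate(([0.0], np.cumsum(
            np.linalg.norm(np.diff(pos, axis=0), axis=1))))
    tails = {}

    def tail_point(which: str, dist: float) -> np.ndarray:
        if which not in tails:
            if L == 1:
                tails[which] = None
            elif which == "hi":
                tails[which] = _curved_tail(pos, arc)
            else:
                tails[which] = _curved_tail(pos[::-1].copy(),
                                            arc[-1] - arc[::-1])
        tail = tails[which]
        anchor = pos[-1] if which == "hi" else pos[0]
        if tail is None:
            return anchor.copy()
        k = dist / _TAIL_STEP - 1.0
        k0 = int(np.clip(np.floor(k), -1, len(tail) - 1))
        k1 = min(k0 + 1, len(tail) - 1)
        p0 = anchor if k0 < 0 else tail[k0]
        f = k - k0
        return p0 + np.clip(f, 0.0, 1.0) * (tail[k1] - p0)

    def at_arc(t: float) -> np.ndarray:
        if L == 1:
            return pos[0].copy()
        if t < 0.0:
            return tail_point("lo", -t)
        if t > arc[-1]:
            return tail_point("hi", t - arc[-1])
        return _interp_arc(pos, arc, t)

    N = len(assignments)
    matched = [(j, k) for j, k in enumerate(assignments) if k is not None]
    coords = np.zeros((N, 3))
    if not matched:
        for j in range(N):
            coords[j] = at_arc(j * d_std)
        return coords
    res_arc = np.empty(N)
    for j, k in matched:
        res_arc[j] = arc[k]
    first_j, first_k = matched[0]
    last_j, last_k = matched[-1]
    for j in range(first_j):
        res_arc[j] = arc[first_k] - (first_j - j) * d_std
    for j in range(last_j + 1, N):
        res_arc[j] = arc[last_k] + (j - last_j) * d_std
    for (j1, k1), (j2, k2) in zip(matched, matched[1:]):
        for j in range(j1 + 1, j2):
            f = (j - j1) / (j2 - j1)
            res_arc[j] = arc[k1] + f * (arc[k2] - arc[k1])
    for j in range(N):
        coords[j] = at_arc(res_arc[j])
    for j, k in matched:
        coords[j] = pos[k]
    return coords


def thread_sequence(profile: ResidueProfile, path: PathProfile,
                    gap: float = DEFAULT_GAP, w_ca: float = DEFAULT_W_CA,
                    d_std: float = DEFAULT_D_STD,
                    direction: str = "forward",
                    distance_mode: str = "arc") -> ThreadedModel:
    """Align a residue profile to a path profile and build a Calpha model.

    ``direction="reverse"`` threads the reversed sequence onto the same
    path (the chain read the other way); assignments and coordinates are
    reported in the original residue order either way. ``distance_mode``
    selects how the inter-residue distance d of the geometry penalty is
    measured: along the path arc (default; additive over spans, robust on
    curved paths) or as the Euclidean separation of the assigned LDPs.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    prof = profile.reversed() if direction == "reverse" else profile
    SCO = zscore_similarity(path.V, prof.A)
    if distance_mode == "arc":
        arc = np.concatenate(([0.0], np.cumsum(
            np.linalg.norm(np.diff(path.positions, axis=0), axis=1))))
        dist = np.abs(arc[None, :] - arc[:, None])
    elif distance_mode == "euclidean":
        dist = np.linalg.norm(
            path.positions[:, None, :] - path.positions[None, :, :], axis=2)
    else:
        raise ValueError("distance_mode must be 'arc' or 'euclidean'")
    score, assignments = _dp_align(SCO, dist, gap, w_ca, d_std)
    coords = _place_residues(assignments, path, d_std)
    if direction == "reverse":
        assignments = assignments[::-1]
        coords = coords[::-1]
    return ThreadedModel(assignments=assignments, ca_coords=coords,
                         direction=direction, threading_score=score)
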