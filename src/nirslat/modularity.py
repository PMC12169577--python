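"""Module detection on connectivity matrices via the Louvain algorithm.

Runs greedy two-phase Louvain modularity maximization on the positive part
of a weighted graph (negative correlations are zeroed by default; a signed
variant with asymmetric positive/negative contributions is available behind
``negative='signed'``).  Because the node visiting order is random, module
detection is repeated over many seeded runs and downstream statistics are
averaged over runs.  A brute-force exhaustive-search oracle over all set
partitions is provided for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix

DEFAULT_N_RUNS = 50
_GAIN_EPS = 1e-10


@dataclass
class ModulePartition:
    """One Louvain run: channel -> module assignment and its modularity."""

    assignment: dict[str, int]
    q: float
    seed: int
    trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        mods = sorted(set(self.assignment.values()))
        if mods != list(range(len(mods))):
            raise ValueError("module indices must be contiguous from 0")
        if not -1.0 - 1e-9 <= self.q <= 1.0 + 1e-9:
            raise ValueError(f"modularity {self.q} outside [-1, 1]")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_modules)]
        for cid, m in self.assignment.items():
            out[m].append(cid)
        return out


def _as_matrix(matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(matrix, ConnectivityMatrix):
        return np.asarray(matrix.values, dtype=float), list(matrix.channel_ids)
    a = np.asarray(matrix, dtype=float)
    return a, [str(i) for i in range(a.shape[0])]


def _split_signed(a: np.ndarray, negative: str) -> tuple[np.ndarray, np.ndarray]:
    if negative not in ("zero", "signed"):
        raise ValueError(f"unknown negative-weight policy {negative!r}")
    ap = np.clip(a, 0.0, None).copy()
    an = np.clip(-a, 0.0, None).copy() if negative == "signed" else np.zeros_like(a)
    np.fill_diagonal(ap, 0.0)
    np.fill_diagonal(an, 0.0)
    return ap, an


def _q_one(a: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity of a non-negative zero-diagonal matrix."""
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    strength = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        q += a[np.ix_(mask, mask)].sum() / two_m - (strength[mask].sum() / two_m) ** 2
    return float(q)


def modularity_q(matrix, assignment: dict[str, int], negative: str = "zero") -> float:
    """Modularity Q = sum_c [ W_c/W - (S_c/2W)^2 ] of a given partition.

    Computed on the positive-weight graph by default; with
    ``negative='signed'`` the positive and negative parts contribute
    asymmetrically, Q = (2W+ Q+ - 2W- Q-) / (2W+ + 2W-).
    """
    a, ids = _as_matrix(matrix)
    missing = [c for c in ids if c not in assignment]
    if missing:
        raise ValueError(f"assignment missing channels: {missing}")
    labels = np.array([assignment[c] for c in ids])
    ap, an = _split_signed(a, negative)
    wp, wn = ap.sum(), an.sum()
    if wp + wn == 0:
        return 0.0
    return float((wp * _q_one(ap, labels) - wn * _q_one(an, labels)) / (wp + wn))


def _one_level(ap, an, labels, rng, resolution):
    """One Louvain node-moving phase, in place on ``labels``. Returns whether
    any node changed community."""
    n = ap.shape[0]
    two_mp, two_mn = ap.sum(), an.sum()
    total = two_mp + two_mn
    kp, kn = ap.sum(axis=1), an.sum(axis=1)
    sp = np.bincount(labels, weights=kp, minlength=n)
    sn = np.bincount(labels, weights=kn, minlength=n)
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            sp[ci] -= kp[i]
            sn[ci] -= kn[i]
            # self-loops travel with the node: exclude them from community links
            row_p = ap[i].copy()
            row_n = an[i].copy()
            row_p[i] = 0.0
            row_n[i] = 0.0
            lp = np.bincount(labels, weights=row_p, minlength=n)
            ln = np.bincount(labels, weights=row_n, minlength=n)
            neigh = np.flatnonzero((lp > 0) | (ln > 0))
            best_c, best_gain = ci, 0.0
            cand = set(neigh.tolist())
            cand.add(ci)
            for c in sorted(cand):
                gain = 0.0
                if two_mp > 0:
                    gain += (2 * lp[c] - resolution * 2 * sp[c] * kp[i] / two_mp) / total
                if two_mn > 0:
                    gain -= (2 * ln[c] - resolution * 2 * sn[c] * kn[i] / two_mn) / total
                if gain > best_gain + _GAIN_EPS:
                    best_c, best_gain = c, gain
                elif abs(gain - best_gain) <= _GAIN_EPS and c < best_c and best_gain > 0:
                    best_c = c
            labels[i] = best_c
            sp[best_c] += kp[i]
            sn[best_c] += kn[i]
            if best_c != ci:
                improved = True
                moved_any = True
    return moved_any


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, new = np.unique(labels, return_inverse=True)
    return new


def louvain_partition(
    matrix,
    seed: int = 0,
    resolution: float = 1.0,
    negative: str = "zero",
) -> ModulePartition:
    """Greedy two-phase Louvain community detection.

    Phase 1 visits nodes in seeded-random order, moving each to the
    neighbouring community with the largest positive modularity gain (ties
    break to the lowest community index) until no move improves; phase 2
    aggregates communities into super-nodes and repeats until stable.
    """
    a, ids = _as_matrix(matrix)
    if a.size == 0:
        raise ValueError("empty graph")
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-9):
        raise ValueError("matrix must be square and symmetric")
    rng = np.random.default_rng(seed)
    ap, an = _split_signed(a, negative)

    part = np.arange(len(ids))  # original node -> community
    cur_ap, cur_an = ap, an
    trace: list[float] = []
    while True:
        labels = np.arange(cur_ap.shape[0])
        moved = _one_level(cur_ap, cur_an, labels, rng, resolution)
        labels = _relabel(labels)
        part = labels[part]
        trace.append(_q_from_parts(ap, an, part))
        if not moved or labels.max() == cur_ap.shape[0] - 1:
            break
        onehot = np.eye(labels.max() + 1)[labels]
        cur_ap = onehot.T @ cur_ap @ onehot
        cur_an = onehot.T @ cur_an @ onehot
    part = _relabel(part)
    assignment = {cid: int(m) for cid, m in zip(ids, part)}
    q = modularity_q(matrix, assignment, negative=negative)
    return ModulePartition(assignment, q, int(seed), trace)


def _q_from_parts(ap, an, labels) -> float:
    wp, wn = ap.sum(), an.sum()
    if wp + wn == 0:
        return 0.0
    return float((wp * _q_one(ap, labels) - wn * _q_one(an, labels)) / (wp + wn))


def repeated_louvain(
    matrix,
    n_runs: int = DEFAULT_N_RUNS,
    master_seed: int = 0,
    resolution: float = 1.0,
    negative: str = "zero",
) -> list[ModulePartition]:
    """``n_runs`` Louvain partitions with run seeds derived from one master
    seed.  Partitions are returned individually (laterality statistics are
    averaged over runs downstream; partitions themselves are never merged).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_runs, dtype=np.uint32)
    return [
        louvain_partition(matrix, seed=int(s), resolution=resolution, negative=negative)
        for s in seeds
    ]


def _set_partitions(n: int):
    """All partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1) if n else iter(())


def brute_force_partition(matrix, negative: str = "zero", max_nodes: int = 10) -> ModulePartition:
    """Global modularity maximum by exhaustive search (test oracle).

    Refuses graphs larger than ``max_nodes`` (Bell-number growth).
    """
    a, ids = _as_matrix(matrix)
    n = a.shape[0]
    if n > max_nodes:
        raise ValueError(f"brute force limited to {max_nodes} nodes, got {n}")
    if n == 0:
        raise ValueError("empty graph")
    ap, an = _split_signed(a, negative)
    best_labels, best_q = np.zeros(n, dtype=int), -np.inf
    for labels in _set_partitions(n):
        q = _q_from_parts(ap, an, labels)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    best_labels = _relabel(best_labels)
    assignment = {cid: int(m) for cid, m in zip(ids, best_labels)}
    return ModulePartition(assignment, float(best_q), seed=-1)
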