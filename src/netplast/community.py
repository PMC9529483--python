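"""Newman modularity: scoring, spectral module detection, partition comparison.

Modularity of a partition c on a binary network with m edges:

    Q = (1/2m) * sum_vw [A_vw - k_v k_w / 2m] delta(c_v, c_w),

i.e. the within-module edge fraction minus its expectation under the
degree-preserving chance model; Q ranges over [-0.5, 1].

Detection follows Newman's leading-eigenvector method: recursive bisection by
the sign of the leading eigenvector of the (generalized) modularity matrix,
each split fine-tuned by a Kernighan-Lin pass, recursing while a split still
increases Q, followed by a greedy merge pass that undoes unprofitable
over-splitting.  Components of a disconnected network are handled
independently (merging two components can only decrease Q under the global
null model).  All tie-breaks are by ascending node index, and the eigenvector
comes from a deterministic dense solver, so results are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .connectivity import BinaryNetwork
from .metrics import shortest_paths

__all__ = [
    "Partition",
    "PartitionComparison",
    "modularity_q",
    "newman_partition",
    "compare_partitions",
]


@dataclass
class Partition:
    """Node-to-module assignment with its modularity score."""

    assignment: np.ndarray  # int module label per node
    q: float
    n_modules: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a 1-D label array")
        if not -0.5 - 1e-9 <= self.q <= 1 + 1e-9:
            raise ValueError("modularity Q must lie in [-0.5, 1]")

    def module_sizes(self) -> dict[int, int]:
        labs, counts = np.unique(self.assignment, return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def n_nontrivial_modules(self) -> int:
        """Modules containing at least 2 nodes (isolated nodes excluded)."""
        return int(sum(c >= 2 for c in self.module_sizes().values()))


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..K-1 in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def modularity_q(net: BinaryNetwork | np.ndarray, assignment) -> float:
    """Exact evaluation of Newman's Q for a given assignment."""
    a = net.values if isinstance(net, BinaryNetwork) else np.asarray(net)
    labels = np.asarray(assignment)
    n = a.shape[0]
    if labels.shape != (n,):
        raise ValueError("assignment must cover every node exactly once")
    two_m = float(a.sum())
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1).astype(float)
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        q += a[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _kl_refine(s: np.ndarray, bhat: np.ndarray) -> np.ndarray:
    """Kernighan-Lin fine-tuning of a bisection vector s in {-1, +1}^n,
    maximizing s^T Bhat s.  Each pass tentatively moves every node once (best
    gain first, ties to the lowest index) and keeps the best prefix."""
    n = s.size
    diag = np.diag(bhat).copy()
    s = s.copy()
    while True:
        s_work = s.copy()
        moved = np.zeros(n, dtype=bool)
        gains = np.empty(n)
        order = np.empty(n, dtype=np.int64)
        for step in range(n):
            d = -4.0 * s_work * (bhat @ s_work) + 4.0 * diag
            d[moved] = -np.inf
            i = int(np.argmax(d))
            gains[step] = d[i]
            order[step] = i
            s_work[i] = -s_work[i]
            moved[i] = True
        cum = np.cumsum(gains)
        j = int(np.argmax(cum))
        if cum[j] > 1e-10:
            s[order[: j + 1]] *= -1
        else:
            return s


def _components(a: np.ndarray) -> list[np.ndarray]:
    dist = shortest_paths(a)
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for i in range(n):
        if not seen[i]:
            comp = np.flatnonzero(np.isfinite(dist[i]))
            seen[comp] = True
            comps.append(comp)
    return comps


def _merge_pass(a: np.ndarray, labels: np.ndarray, two_m: float) -> np.ndarray:
    """Greedily merge module pairs while that increases Q (ties: lowest labels)."""
    labels = _canonical_labels(labels)
    while True:
        labs = np.unique(labels)
        k_mod = np.array([a[labels == l].sum() for l in labs], dtype=float)
        e = np.zeros((labs.size, labs.size))
        for ia, la in enumerate(labs):
            rows = a[labels == la]
            for ib in range(ia + 1, labs.size):
                e[ia, ib] = rows[:, labels == labs[ib]].sum()
        best, pair = 1e-10, None
        for ia in range(labs.size):
            for ib in range(ia + 1, labs.size):
                dq = 2.0 * e[ia, ib] / two_m - 2.0 * (k_mod[ia] / two_m) * (k_mod[ib] / two_m)
                if dq > best:
                    best, pair = dq, (labs[ia], labs[ib])
        if pair is None:
            return _canonical_labels(labels)
        labels[labels == pair[1]] = pair[0]


def newman_partition(net: BinaryNetwork, min_gain: float = 1e-10) -> Partition:
    """Detect modules by recursive leading-eigenvector bisection with
    Kernighan-Lin refinement and a final greedy merge pass."""
    a = net.values.astype(float)
    n = a.shape[0]
    if n == 0:
        return Partition(np.empty(0, dtype=np.int64), q=0.0, n_modules=0)
    two_m = float(a.sum())
    if two_m == 0:
        return Partition(np.zeros(n, dtype=np.int64), q=0.0, n_modules=1)
    k = a.sum(axis=1)
    b_full = a - np.outer(k, k) / two_m
    labels = np.full(n, -1, dtype=np.int64)
    next_label = 0
    stack: list[np.ndarray] = sorted(_components(a), key=lambda g: int(g[0]))
    stack.reverse()  # process lowest-index component first
    while stack:
        g = stack.pop()
        if g.size == 1:
            labels[g] = next_label
            next_label += 1
            continue
        bg = b_full[np.ix_(g, g)]
        bhat = bg - np.diag(bg.sum(axis=1))
        w, vecs = np.linalg.eigh(bhat)
        lead = vecs[:, -1]
        s = np.where(lead < 0, -1.0, 1.0)  # entries exactly 0 go positive
        s = _kl_refine(s, bhat)
        gain = float(s @ bhat @ s) / (2.0 * two_m)
        left = g[s > 0]
        right = g[s < 0]
        if gain > min_gain and left.size and right.size:
            stack.append(right)
            stack.append(left)
        else:
            labels[g] = next_label
            next_label += 1
    labels = _merge_pass(a, labels, two_m)
    q = modularity_q(net, labels)
    return Partition(labels, q=q, n_modules=int(np.unique(labels).size))


@dataclass
class PartitionComparison:
    """Label-invariant similarity between two partitions of the same nodes."""

    nmi: float
    ari: float
    contingency: pd.DataFrame
    per_module_jaccard: list[tuple[int, int, float]] = field(default_factory=list)


def compare_partitions(p1: Partition, p2: Partition) -> PartitionComparison:
    """NMI, adjusted Rand index, module-overlap contingency table, and greedy
    best-match per-module Jaccard overlaps (p1 modules, largest first)."""
    l1 = np.asarray(p1.assignment)
    l2 = np.asarray(p2.assignment)
    if l1.shape != l2.shape:
        raise ValueError("partitions must cover the same node set")
    nmi = float(normalized_mutual_info_score(l1, l2))
    ari = float(adjusted_rand_score(l1, l2))
    cont = pd.crosstab(pd.Series(l1, name="p1"), pd.Series(l2, name="p2"))
    jacc: list[tuple[int, int, float]] = []
    used: set[int] = set()
    sizes1 = {lab: int((l1 == lab).sum()) for lab in np.unique(l1)}
    for lab1 in sorted(sizes1, key=lambda l: (-sizes1[l], l)):
        m1 = l1 == lab1
        best_j, best_lab = -1.0, None
        for lab2 in np.unique(l2):
            if int(lab2) in used:
                continue
            m2 = l2 == lab2
            j = float((m1 & m2).sum() / (m1 | m2).sum())
            if j > best_j:
                best_j, best_lab = j, int(lab2)
        if best_lab is not None:
            used.add(best_lab)
            jacc.append((int(lab1), best_lab, best_j))
    return PartitionComparison(nmi=nmi, ari=ari, contingency=cont,
                               per_module_jaccard=jacc)
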