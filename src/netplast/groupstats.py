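"""Group-level statistics on brain networks.

Four analyses:

* threshold-sweep comparisons — per-threshold two-sample t-tests on
  subject-level global metrics, Bonferroni-corrected over the grid;
* threshold gating — admissible thresholds are those where both groups keep
  mean degree >= ln(N) and a small-world coefficient sigma > 1;
* within-group statistical networks — an edge survives iff a one-sample
  t-test of the subjects' Fisher-Z values against 0 rejects at the
  Bonferroni-corrected level over all node pairs AND the group-mean
  correlation exceeds the analysis threshold;
* between-group differential networks — per-edge Welch t-tests on Fisher-Z
  values with Benjamini-Hochberg FDR across all node pairs; surviving edges
  are labelled enhanced/weakened for group B by the sign of the mean
  difference.

Welch (unequal-variance) t-tests are the default throughout because real
cohorts rarely have equal group sizes; the pooled form is selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import BinaryNetwork, FCMatrix

__all__ = [
    "SweepComparison",
    "GateResult",
    "StatisticalNetwork",
    "DifferentialEdgeSet",
    "NodalRanking",
    "sweep_group_compare",
    "gate_thresholds",
    "statistical_network",
    "rank_nodes",
    "differential_network",
]


@dataclass
class SweepComparison:
    """Per-threshold two-sample comparison of one global metric."""

    thresholds: np.ndarray
    metric_name: str
    group_means: tuple[np.ndarray, np.ndarray]  # (mean A, mean B) per threshold
    t_stat: np.ndarray
    p_value: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray
    correction: str
    alpha: float


def sweep_group_compare(values_a: np.ndarray, values_b: np.ndarray,
                        thresholds: Sequence[float], metric_name: str = "metric",
                        alpha: float = 0.05, correction: str = "bonferroni",
                        equal_var: bool = False) -> SweepComparison:
    """Compare a metric between groups at every threshold of the sweep.

    ``values_a``/``values_b`` are (n_subjects, n_thresholds) arrays of
    subject-level metric values; the Bonferroni family is the threshold grid.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != thresholds.size or b.shape[1] != thresholds.size:
        raise ValueError("metric arrays must be (n_subjects, n_thresholds) on the given grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give t = nan
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    factor = thresholds.size if correction == "bonferroni" else 1
    p_corr = np.minimum(p * factor, 1.0)
    return SweepComparison(
        thresholds=thresholds, metric_name=metric_name,
        group_means=(np.nanmean(a, axis=0), np.nanmean(b, axis=0)),
        t_stat=t, p_value=p, p_corrected=p_corr,
        significant=p_corr < alpha, correction=correction, alpha=alpha,
    )


@dataclass
class GateResult:
    """Admissible threshold set under the degree and small-world criteria."""

    thresholds: np.ndarray
    admissible: np.ndarray          # boolean mask on the grid
    max_admissible: float | None    # the analysis threshold; None if empty
    gate_value: float               # ln(n_nodes)


def gate_thresholds(thresholds: Sequence[float],
                    mean_degree_by_group: Sequence[np.ndarray],
                    sigma_by_group: Sequence[np.ndarray],
                    n_nodes: int) -> GateResult:
    """Thresholds where every group keeps <k> >= ln(N) and sigma > 1.

    Returns the full admissible mask plus its maximum (the single analysis
    threshold in the style of the source design); an empty admissible set
    yields ``max_admissible=None`` and downstream single-threshold stages
    should refuse to run.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    gate = float(np.log(n_nodes))
    ok = np.ones(thresholds.size, dtype=bool)
    for deg in mean_degree_by_group:
        ok &= np.asarray(deg, dtype=float) >= gate
    for sig in sigma_by_group:
        s = np.asarray(sig, dtype=float)
        ok &= np.isfinite(s) & (s > 1.0)
    max_adm = float(thresholds[ok].max()) if ok.any() else None
    return GateResult(thresholds=thresholds, admissible=ok,
                      max_admissible=max_adm, gate_value=gate)


@dataclass
class StatisticalNetwork:
    """Within-group statistical network at one analysis threshold."""

    network: BinaryNetwork
    group: str
    threshold: float
    alpha: float
    test: str = "one-sample t on Fisher-Z edges, Bonferroni over node pairs"


def _stack_z(fcs: Sequence[FCMatrix]) -> tuple[np.ndarray, list[str]]:
    if len(fcs) < 2:
        raise ValueError("need at least 2 subjects")
    for fc in fcs:
        if fc.space != "fisher_z":
            raise ValueError("expected fisher_z-space matrices")
    n = fcs[0].n_nodes
    if any(fc.n_nodes != n for fc in fcs):
        raise ValueError("subjects must share the node set")
    return np.stack([fc.values for fc in fcs]), list(fcs[0].node_labels)


def statistical_network(group_fcs: Sequence[FCMatrix], threshold: float = 0.4,
                        alpha: float = 0.05, group: str = "",
                        require_mean_r: bool = True,
                        require_significance: bool = True) -> StatisticalNetwork:
    """One-sample t-test statistical network of a group at one threshold.

    Edge rule (both components individually switchable): the subjects'
    Fisher-Z values differ from 0 after Bonferroni correction over all
    n(n-1)/2 node pairs, and the group-mean correlation (mean of tanh(z))
    strictly exceeds ``threshold``.
    """
    z, labels = _stack_z(group_fcs)
    n = z.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    zu = z[:, iu, ju]
    n_pairs = iu.size
    keep = np.ones(n_pairs, dtype=bool)
    if require_significance:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.ttest_1samp(zu, 0.0, axis=0)
        p = np.where(np.isfinite(p), p, 1.0)
        keep &= (p * n_pairs) < alpha
    if require_mean_r:
        mean_r = np.tanh(zu).mean(axis=0)
        keep &= mean_r > threshold
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    net = BinaryNetwork(a, threshold_used=float(threshold), node_labels=labels,
                        meta={"alpha": alpha, "bonferroni_family": int(n_pairs)})
    return StatisticalNetwork(network=net, group=group, threshold=float(threshold),
                              alpha=float(alpha))


@dataclass
class NodalRanking:
    """Top-k nodes of one nodal metric with [0.1, 0.9] display normalization."""

    metric_name: str
    table: pd.DataFrame  # node_index, node_label, raw, normalized (descending raw)
    k: int


def rank_nodes(values: np.ndarray, node_labels: Sequence[str],
               metric_name: str = "metric", k: int = 50) -> NodalRanking:
    """Top-k nodes by raw value (ties by ascending node index), normalized to
    [0.1, 0.9] over the displayed set; a constant display set maps to 0.5."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if k > n:
        warnings.warn(f"k={k} exceeds n={n}; clamped", stacklevel=2)
        k = n
    order = np.lexsort((np.arange(n), -v))[:k]
    raw = v[order]
    span = raw.max() - raw.min() if k else 0.0
    if span > 0:
        norm = 0.1 + 0.8 * (raw - raw.min()) / span
    else:
        norm = np.full(k, 0.5)
    table = pd.DataFrame({
        "node_index": order,
        "node_label": [node_labels[i] for i in order],
        "raw": raw,
        "normalized": norm,
    })
    return NodalRanking(metric_name=metric_name, table=table, k=k)


@dataclass
class DifferentialEdgeSet:
    """FDR-qualified edges whose Fisher-Z connectivity differs between groups."""

    edges: pd.DataFrame  # node_i, node_j, direction, t_stat, p, q
    alpha: float
    method: str = "benjamini-hochberg"
    n_pairs_tested: int = 0

    def count(self, direction: str) -> int:
        if self.edges.empty:
            return 0
        return int((self.edges["direction"] == direction).sum())


def differential_network(group_a_fcs: Sequence[FCMatrix],
                         group_b_fcs: Sequence[FCMatrix],
                         alpha: float = 0.05,
                         equal_var: bool = False) -> DifferentialEdgeSet:
    """Per-edge Welch t-test (A vs B) on Fisher-Z values with BH FDR.

    Edges passing q < alpha are labelled for group B: "enhanced" when B's mean
    Fisher-Z exceeds A's, "weakened" otherwise.  t statistics carry the A - B
    orientation, so weakened-in-B edges have positive t.
    """
    za, labels = _stack_z(group_a_fcs)
    zb, _ = _stack_z(group_b_fcs)
    if za.shape[1] != zb.shape[1]:
        raise ValueError("groups must share the node set")
    n = za.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    au = za[:, iu, ju]
    bu = zb[:, iu, ju]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(au, bu, axis=0, equal_var=equal_var)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    diff = bu.mean(axis=0) - au.mean(axis=0)
    sel = reject
    edges = pd.DataFrame({
        "node_i": iu[sel],
        "node_j": ju[sel],
        "node_i_label": [labels[i] for i in iu[sel]],
        "node_j_label": [labels[j] for j in ju[sel]],
        "direction": np.where(diff[sel] > 0, "enhanced", "weakened"),
        "t_stat": t[sel],
        "p": p[sel],
        "q": q[sel],
    })
    edges = edges.sort_values("q", kind="stable").reset_index(drop=True)
    return DifferentialEdgeSet(edges=edges, alpha=float(alpha),
                               n_pairs_tested=int(iu.size))
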