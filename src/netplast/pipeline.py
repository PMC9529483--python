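"""End-to-end study orchestration.

``run_study`` drives the whole analysis on a synthetic (or loaded) two-group
cohort: per-subject FC matrices, the binary-network threshold sweep with
group comparisons, threshold gating, within-group statistical networks with
nodal rankings and Newman modules, and the FDR differential edge network.
``StudyResult`` carries every intermediate product plus a printable summary
and a determinism fingerprint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import community, groupstats, metrics, nulls
from .connectivity import (FCMatrix, TimeSeriesMatrix, binarize, fisher_z,
                           pearson_fc, threshold_grid)
from .synthetic import CohortSpec, GroundTruth, generate_cohort

__all__ = ["StudyConfig", "StudyResult", "run_study", "subject_sweep_metrics"]

SWEEP_METRICS = ("mean_degree", "mean_clustering", "char_path_length")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings; defaults mirror the reference design (sweep
    [0.02, 0.58] step 0.02, analysis threshold 0.4, alpha 0.05)."""

    t_min: float = 0.02
    t_max: float = 0.58
    step: float = 0.02
    analysis_threshold: float | None = 0.4  # None -> maximal admissible threshold
    alpha: float = 0.05
    sweep_metrics: tuple[str, ...] = SWEEP_METRICS
    n_nulls_sweep: int = 5       # nulls per threshold for the sigma curves
    n_nulls_analysis: int = 20   # nulls for sigma at the analysis threshold
    fisher_clip: float = 0.999999
    top_k: int = 50
    use_absolute: bool = False
    ranking_metrics: tuple[str, ...] = ("degree", "betweenness", "nodal_efficiency")
    null_seed: int = 1234        # shared across groups so contrasts are not null noise


def subject_sweep_metrics(fc: FCMatrix, thresholds: np.ndarray,
                          which: Sequence[str] = SWEEP_METRICS,
                          use_absolute: bool = False) -> dict[str, np.ndarray]:
    """Global metrics of one subject's binarized networks along the sweep."""
    out = {m: np.empty(thresholds.size) for m in which}
    for ti, t in enumerate(thresholds):
        gm = metrics.global_metrics(binarize(fc, float(t), use_absolute=use_absolute))
        d = gm.as_dict()
        for m in which:
            out[m][ti] = d[m]
    return out


@dataclass
class StudyResult:
    spec: CohortSpec
    config: StudyConfig
    ground_truth: GroundTruth
    thresholds: np.ndarray
    sweep_table: pd.DataFrame                      # tidy: subject, group, threshold, metric, value
    sweep_comparisons: dict[str, groupstats.SweepComparison]
    sigma_curves: dict[str, np.ndarray]            # per group, along the grid
    gate: groupstats.GateResult
    analysis_threshold: float | None
    statnets: dict[str, groupstats.StatisticalNetwork] = field(default_factory=dict)
    rankings: dict[str, dict[str, groupstats.NodalRanking]] = field(default_factory=dict)
    partitions: dict[str, community.Partition] = field(default_factory=dict)
    partition_comparison: community.PartitionComparison | None = None
    sigma_analysis: dict[str, nulls.SmallWorldResult] = field(default_factory=dict)
    differential: groupstats.DifferentialEdgeSet | None = None

    @property
    def groups(self) -> tuple[str, str]:
        return self.spec.groups

    def sweep_values(self, group: str, metric: str) -> np.ndarray:
        """(n_subjects, n_thresholds) matrix of one metric for one group."""
        sub = self.sweep_table[(self.sweep_table["group"] == group)
                               & (self.sweep_table["metric"] == metric)]
        wide = sub.pivot(index="subject", columns="threshold", values="value")
        return wide.reindex(columns=np.sort(wide.columns.to_numpy())).to_numpy()

    def summary(self) -> str:
        ga, gb = self.groups
        lines = [
            f"Two-group brain-network study: {ga} vs {gb}",
            f"  subjects: {self.spec.n_subjects_per_group} per group, "
            f"nodes: {self.spec.n_nodes}, timepoints: {self.spec.n_timepoints}",
            f"  threshold grid: [{self.thresholds[0]:.2f}, {self.thresholds[-1]:.2f}] "
            f"({self.thresholds.size} thresholds)",
            f"  degree gate ln(N) = {self.gate.gate_value:.3f}; "
            f"admissible thresholds: {int(self.gate.admissible.sum())}, "
            f"max admissible T = {self.gate.max_admissible}",
        ]
        for name, comp in self.sweep_comparisons.items():
            sig = comp.thresholds[comp.significant]
            band = (f"{sig.min():.2f}-{sig.max():.2f}" if sig.size else "none")
            lines.append(f"  {name}: significant thresholds (Bonferroni) {band}")
        if self.analysis_threshold is not None:
            lines.append(f"  analysis threshold T = {self.analysis_threshold:.2f}")
            for g in self.groups:
                part = self.partitions[g]
                sw = self.sigma_analysis[g]
                lines.append(
                    f"    {g}: statnet edges = {self.statnets[g].network.n_edges}, "
                    f"modules (>=2 nodes) = {part.n_nontrivial_modules()}, "
                    f"Q = {part.q:.3f}, sigma = {sw.sigma:.2f}"
                )
        if self.differential is not None:
            lines.append(
                f"  differential edges (q < {self.differential.alpha:g}): "
                f"{self.differential.count('weakened')} weakened, "
                f"{self.differential.count('enhanced')} enhanced in {gb}"
            )
        return "\n".join(lines)

    def fingerprint(self) -> str:
        """SHA-256 over the study's principal numerical outputs."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.thresholds).tobytes())
        tab = self.sweep_table.sort_values(["group", "subject", "metric", "threshold"])
        h.update(np.ascontiguousarray(tab["value"].to_numpy()).tobytes())
        for g in self.groups:
            h.update(np.ascontiguousarray(self.sigma_curves[g]).tobytes())
            if g in self.statnets:
                h.update(self.statnets[g].network.values.tobytes())
                h.update(self.partitions[g].assignment.tobytes())
        if self.differential is not None:
            for col in ("node_i", "node_j", "t_stat", "q"):
                h.update(np.ascontiguousarray(
                    self.differential.edges[col].to_numpy()).tobytes())
        return h.hexdigest()


def _group_mean_fc(fcs: Sequence[FCMatrix]) -> FCMatrix:
    mean_r = np.mean([fc.values for fc in fcs], axis=0)
    return FCMatrix(mean_r, space="pearson", subject_id="group_mean",
                    node_labels=list(fcs[0].node_labels))


def run_study(spec: CohortSpec, config: StudyConfig = StudyConfig(),
              cohort: dict[str, list[TimeSeriesMatrix]] | None = None,
              ground_truth: GroundTruth | None = None) -> StudyResult:
    """Run the complete two-group analysis.

    A cohort is generated from ``spec`` unless one (e.g. loaded from disk via
    synthetic.read_cohort) is passed in together with its ground truth.
    """
    if cohort is None:
        cohort, ground_truth = generate_cohort(spec)
    thresholds = threshold_grid(config.t_min, config.t_max, config.step)
    ga, gb = spec.groups

    pearson: dict[str, list[FCMatrix]] = {}
    fisher: dict[str, list[FCMatrix]] = {}
    rows = []
    for g in spec.groups:
        pearson[g] = [pearson_fc(ts) for ts in cohort[g]]
        fisher[g] = [fisher_z(fc, clip=config.fisher_clip) for fc in pearson[g]]
        for ts, fc in zip(cohort[g], pearson[g]):
            vals = subject_sweep_metrics(fc, thresholds, config.sweep_metrics,
                                         config.use_absolute)
            for m, arr in vals.items():
                for t, v in zip(thresholds, arr):
                    rows.append((ts.subject_id, g, float(t), m, float(v)))
    sweep_table = pd.DataFrame(rows, columns=["subject", "group", "threshold",
                                              "metric", "value"])

    result = StudyResult(spec=spec, config=config, ground_truth=ground_truth,
                         thresholds=thresholds, sweep_table=sweep_table,
                         sweep_comparisons={}, sigma_curves={}, gate=None,  # type: ignore[arg-type]
                         analysis_threshold=None)

    for m in config.sweep_metrics:
        result.sweep_comparisons[m] = groupstats.sweep_group_compare(
            result.sweep_values(ga, m), result.sweep_values(gb, m),
            thresholds, metric_name=m, alpha=config.alpha)

    # sigma along the sweep, on each group's mean-correlation network, with
    # null seeds shared across groups (per-threshold) so the group contrast is
    # not null-sampling noise
    for g in spec.groups:
        gmean = _group_mean_fc(pearson[g])
        sig = np.empty(thresholds.size)
        for ti, t in enumerate(thresholds):
            net = binarize(gmean, float(t), use_absolute=config.use_absolute)
            if net.n_edges < 2:
                sig[ti] = np.nan
                continue
            sw = nulls.small_world(net, n_nulls=config.n_nulls_sweep,
                                   seed=(config.null_seed, ti))
            sig[ti] = sw.sigma
        result.sigma_curves[g] = sig

    mean_deg = [result.sweep_values(g, "mean_degree").mean(axis=0)
                for g in spec.groups]
    result.gate = groupstats.gate_thresholds(
        thresholds, mean_deg, [result.sigma_curves[g] for g in spec.groups],
        n_nodes=spec.n_nodes)

    t_star = (config.analysis_threshold if config.analysis_threshold is not None
              else result.gate.max_admissible)
    result.analysis_threshold = t_star
    if t_star is None:
        return result  # empty admissible set: single-threshold stages refuse to run

    for g in spec.groups:
        stat = groupstats.statistical_network(fisher[g], threshold=t_star,
                                              alpha=config.alpha, group=g)
        result.statnets[g] = stat
        nm = metrics.nodal_metrics(stat.network)
        result.rankings[g] = {
            m: groupstats.rank_nodes(nm.as_dict()[m], stat.network.node_labels,
                                     metric_name=m, k=min(config.top_k, spec.n_nodes))
            for m in config.ranking_metrics
        }
        result.partitions[g] = community.newman_partition(stat.network)
        if stat.network.n_edges >= 2:
            result.sigma_analysis[g] = nulls.small_world(
                stat.network, n_nulls=config.n_nulls_analysis,
                seed=(config.null_seed, thresholds.size))
        else:
            result.sigma_analysis[g] = nulls.SmallWorldResult(
                gamma=float("nan"), lambda_=float("nan"), sigma=float("nan"),
                n_nulls=0, defined=False)
    result.partition_comparison = community.compare_partitions(
        result.partitions[ga], result.partitions[gb])
    result.differential = groupstats.differential_network(
        fisher[ga], fisher[gb], alpha=config.alpha)
    return result
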