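"""Functional connectivity construction.

Per-subject ROI time series are turned into Pearson correlation matrices,
optionally Fisher-Z transformed (z = atanh r, variance-stabilizing, so edge
values are approximately normal and t-testable), and binarized by an absolute
threshold: an edge exists iff the correlation strictly exceeds T.  Sweeping T
over a grid yields the family of binary networks whose topology is compared
between groups downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "FCMatrix",
    "BinaryNetwork",
    "pearson_fc",
    "fisher_z",
    "binarize",
    "threshold_sweep",
]


def _default_labels(n: int) -> list[str]:
    return [f"roi{i:04d}" for i in range(n)]


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI signals: ``values`` is (n_nodes, n_timepoints).

    Degenerate inputs (non-finite values, < 3 timepoints, flat signals) are
    rejected at construction: every downstream correlation is undefined for
    them, so failing early names the offending node.
    """

    values: np.ndarray
    subject_id: str = "subject"
    group: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series matrix must be 2-D (nodes x timepoints)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series matrix contains non-finite values")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints to correlate signals")
        if not self.node_labels:
            self.node_labels = _default_labels(self.values.shape[0])
        if len(self.node_labels) != self.values.shape[0]:
            raise ValueError("node_labels length does not match number of nodes")
        sd = self.values.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                f"node(s) {[self.node_labels[i] for i in flat]} have zero variance"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class FCMatrix:
    """Symmetric connectivity matrix with a fixed zero diagonal.

    ``space`` is "pearson" (entries are correlations in [-1, 1]) or "fisher_z"
    (entries are atanh-transformed).  The self-correlation of 1 is discarded:
    it carries no information and would map to an infinite z.
    """

    values: np.ndarray
    space: str = "pearson"
    subject_id: str = "subject"
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=False):
            raise ValueError("connectivity matrix must be symmetric")
        if self.space not in ("pearson", "fisher_z"):
            raise ValueError("space must be 'pearson' or 'fisher_z'")
        np.fill_diagonal(self.values, 0.0)
        if self.space == "pearson":
            off = self.values[~np.eye(n, dtype=bool)]
            if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
                raise ValueError("pearson-space values must lie in [-1, 1]")
        if not self.node_labels:
            self.node_labels = _default_labels(n)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary adjacency matrix (0/1, symmetric, no self-loops)."""

    values: np.ndarray
    threshold_used: float = float("nan")
    node_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.values)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.trace(a) != 0:
            raise ValueError("adjacency must have a zero diagonal")
        self.values = a.astype(np.uint8)
        if not self.node_labels:
            self.node_labels = _default_labels(a.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of node index pairs i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.values[iu, ju] == 1
        return np.column_stack([iu[keep], ju[keep]])


def pearson_fc(ts: TimeSeriesMatrix) -> FCMatrix:
    """Pearson correlation between every pair of node signals.

    r_ij = (1/(n-1)) * sum_t [(x_t - x̄)/s_x] [(y_t - ȳ)/s_y] with the sample
    (ddof=1) standard deviation; the diagonal is forced to 0.
    """
    x = ts.values
    sd = x.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"cannot correlate zero-variance node(s) {[ts.node_labels[i] for i in zero]}"
        )
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return FCMatrix(r, space="pearson", subject_id=ts.subject_id,
                    node_labels=list(ts.node_labels))


def fisher_z(fc: FCMatrix, clip: float | None = None) -> FCMatrix:
    """Fisher-Z transform: z = atanh(r) entrywise off the diagonal.

    Parameters
    ----------
    clip : float, optional
        If given, |r| is clipped to this value (< 1) first.  Without it a
        perfect correlation raises, because atanh(±1) is infinite.
    """
    if fc.space != "pearson":
        raise ValueError("fisher_z expects a pearson-space matrix")
    r = fc.values.copy()
    if clip is not None:
        if not 0 < clip < 1:
            raise ValueError("clip must lie in (0, 1)")
        r = np.clip(r, -clip, clip)
    n = r.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1):
        raise ValueError(
            "off-diagonal |r| = 1 found: atanh is infinite there; pass e.g. "
            "clip=0.999999 to fisher_z (or fix the degenerate signals)"
        )
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z, space="fisher_z", subject_id=fc.subject_id,
                    node_labels=list(fc.node_labels))


def binarize(fc: FCMatrix, threshold: float, use_absolute: bool = False) -> BinaryNetwork:
    """Absolute-threshold binarization: edge iff value > threshold (strict).

    By default only positive correlations can form edges; ``use_absolute=True``
    thresholds |value| instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    v = np.abs(fc.values) if use_absolute else fc.values
    a = (v > threshold).astype(np.uint8)
    np.fill_diagonal(a, 0)
    a = np.maximum(a, a.T)  # numerically symmetric input stays symmetric
    return BinaryNetwork(a, threshold_used=float(threshold),
                         node_labels=list(fc.node_labels))


def threshold_grid(t_min: float, t_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid t_min, t_min+step, ..., t_max."""
    if step <= 0:
        raise ValueError("step must be positive")
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    n = int(np.floor((t_max - t_min) / step + 1e-9)) + 1
    return np.round(t_min + step * np.arange(n), 10)


def threshold_sweep(fc: FCMatrix, t_min: float = 0.02, t_max: float = 0.58,
                    step: float = 0.02, use_absolute: bool = False) -> list[BinaryNetwork]:
    """Binarize ``fc`` at every threshold of the inclusive grid."""
    return [binarize(fc, float(t), use_absolute=use_absolute)
            for t in threshold_grid(t_min, t_max, step)]
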