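"""Key-lncRNA selection and bipartite lncRNA-mRNA co-expression networks.

Candidate key lncRNAs are the reversal lncRNAs ranked by the magnitude of
their treatment-contrast fold change; the top k (9 by default) form the
lncRNA side of the network. Edges join a lncRNA to an mRNA when the Pearson
product-moment correlation of their log2 intensities across ALL samples of
the study (the three groups pooled) satisfies |r| >= 0.98 with two-sided
p < 0.05. The p-value attached to a correlation r over n samples is the
exact test under bivariate normality: t = r * sqrt((n-2) / (1-r^2)) against
Student's t with n-2 degrees of freedom. At n = 12 the p criterion is
implied by the r criterion (|r| = 0.98 gives p ~ 5e-8), so the r threshold
is the operative one; both are still checked. Spearman rank correlation is
available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from lncnet.exceptions import DataError, ParameterError
from lncnet.synthetic import ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkThresholds:
    """Edge-calling thresholds: minimum |r| and maximum p."""

    min_abs_r: float = 0.98
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_abs_r <= 1.0:
            raise ParameterError("min_abs_r must be in [0, 1]")
        if not 0.0 < self.max_p <= 1.0:
            raise ParameterError("max_p must be in (0, 1]")


@dataclass(frozen=True)
class CoexpressionEdge:
    lncrna_id: str
    mrna_id: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA edge set; every node touches at least one edge."""

    lncrna_nodes: frozenset[str]
    mrna_nodes: frozenset[str]
    edges: tuple[CoexpressionEdge, ...]
    thresholds: NetworkThresholds

    def __post_init__(self) -> None:
        touched_l = {e.lncrna_id for e in self.edges}
        touched_m = {e.mrna_id for e in self.edges}
        if touched_l != self.lncrna_nodes or touched_m != self.mrna_nodes:
            raise DataError("network nodes must be exactly the edge endpoints")
        if touched_l & touched_m:
            raise DataError("a node cannot be both lncRNA and mRNA")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((e.lncrna_id, e.mrna_id) for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.lncrna_nodes, bipartite="lncRNA")
        g.add_nodes_from(self.mrna_nodes, bipartite="mRNA")
        for e in self.edges:
            g.add_edge(e.lncrna_id, e.mrna_id, r=e.r, p_value=e.p_value)
        return g


def select_key_lncrnas(records, k: int) -> list[str]:
    """The k transcript ids with largest treatment-contrast fold change.

    ``records`` is a sequence of objects with ``transcript_id`` and
    ``fc_bzxd_vs_cia`` attributes (e.g. the packaged reversed-lncRNA table)
    or of ``(transcript_id, fc)`` pairs. Returned in descending fold-change
    order; ties broken by transcript_id ascending.
    """
    pairs = []
    for rec in records:
        if hasattr(rec, "transcript_id"):
            pairs.append((str(rec.transcript_id), float(rec.fc_bzxd_vs_cia)))
        else:
            tid, fc = rec
            pairs.append((str(tid), float(fc)))
    if k > len(pairs):
        raise ParameterError(f"k={k} exceeds the {len(pairs)} available records")
    if k < 0:
        raise ParameterError("k must be >= 0")
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return [tid for tid, _ in pairs[:k]]


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("vectors must be one-dimensional and equal length")
    if len(x) < 3:
        raise ParameterError("correlation requires at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise DataError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation r over n samples."""
    if n < 3:
        raise ParameterError("correlation test requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ParameterError(f"r must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_r(x, y) -> float:
    """Spearman rank correlation (Pearson on ranks, average ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson_r(stats.rankdata(x), stats.rankdata(y))


def build_network(study: ExpressionStudy, lncrna_ids, mrna_ids,
                  thresholds: NetworkThresholds | None = None,
                  method: str = "pearson",
                  use_log2: bool = True) -> CoexpressionNetwork:
    """Call co-expression edges between candidate lncRNAs and mRNAs.

    Correlations are computed across all samples of the study (groups
    pooled), on log2 intensities by default. An edge (l, m) is retained iff
    |r| >= min_abs_r and p < max_p. Constant-expression transcripts are
    skipped with a warning. Candidate nodes left without an edge do not
    appear in the network. Deterministic given its inputs.
    """
    if thresholds is None:
        thresholds = NetworkThresholds()
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    lncrna_ids = sorted(dict.fromkeys(lncrna_ids))
    mrna_ids = sorted(dict.fromkeys(mrna_ids))
    for tid in (*lncrna_ids, *mrna_ids):
        if tid not in study.matrix.index:
            raise DataError(f"transcript {tid!r} not present in the study")
    overlap = set(lncrna_ids) & set(mrna_ids)
    if overlap:
        raise DataError(f"{sorted(overlap)[0]!r} listed as both lncRNA and mRNA")

    if not lncrna_ids or not mrna_ids:
        return CoexpressionNetwork(frozenset(), frozenset(), (), thresholds)

    values = study.matrix.to_numpy(dtype=float)
    if use_log2:
        values = np.log2(values)
    row_of = {tid: i for i, tid in enumerate(study.matrix.index)}

    def block(ids):
        m = values[[row_of[t] for t in ids], :]
        if method == "spearman":
            m = stats.rankdata(m, axis=1)
        keep = m.std(axis=1) > 0.0
        for tid, ok in zip(ids, keep):
            if not ok:
                logger.warning("skipping constant-expression transcript %s", tid)
        ids = [t for t, ok in zip(ids, keep) if ok]
        m = m[keep]
        m = m - m.mean(axis=1, keepdims=True)
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        return ids, m

    l_ids, lz = block(lncrna_ids)
    m_ids, mz = block(mrna_ids)
    if not l_ids or not m_ids:
        return CoexpressionNetwork(frozenset(), frozenset(), (), thresholds)

    n = values.shape[1]
    r = np.clip(lz @ mz.T, -1.0, 1.0)
    hits = np.argwhere(np.abs(r) >= thresholds.min_abs_r)
    edges = []
    for i, j in hits:
        rv = float(r[i, j])
        p = correlation_pvalue(rv, n)
        if p < thresholds.max_p:
            edges.append(CoexpressionEdge(l_ids[i], m_ids[j], rv, p, n))
    edges.sort(key=lambda e: (e.lncrna_id, e.mrna_id))
    return CoexpressionNetwork(
        lncrna_nodes=frozenset(e.lncrna_id for e in edges),
        mrna_nodes=frozenset(e.mrna_id for e in edges),
        edges=tuple(edges),
        thresholds=thresholds,
    )
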