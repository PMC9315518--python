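"""Per-sample edge perturbation scores over pathway graphs.

The reference (normal) cohort fixes a Pearson correlation ``PCC_n`` for each
pathway edge.  For each tumor sample the correlation is recomputed with that
single sample appended to the reference cohort (``PCC_{n+1}``), and the
perturbation of the edge by the sample is quantified as a z-like statistic

    edge_score = (PCC_{n+1} - PCC_n) / ((1 - PCC_n^2) / (n - 1))

whose null distribution (adding a sample drawn from the reference
distribution) is approximately standard normal.  Scores are computed one
sample at a time against the fixed reference cohort; the result is an
edges x tumor-samples matrix ranked downstream by the enrichment step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, PathwayEdgeSets, edge_id

logger = logging.getLogger(__name__)

#: edges with |PCC_n| >= 1 - EPS sit on the singularity of the score and are
#: excluded (not clipped) so downstream edge universes stay reproducible
EPS = 1e-8


class InvalidEdgeError(ValueError):
    """Raised when a score is requested for an edge flagged invalid."""


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two equal-length vectors (n >= 3).

    Uses the n-1 sample-variance convention throughout (the convention
    cancels in the ratio but is fixed so oracle tests are exact).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx @ dx) / (x.size - 1))
    sy = np.sqrt((dy @ dy) / (y.size - 1))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float((dx @ dy) / ((x.size - 1) * sx * sy))


def edge_score(pcc_n: float, pcc_n1: float, n: int, eps: float = EPS) -> float:
    """Perturbation z-statistic for one edge and one added sample.

    Parameters
    ----------
    pcc_n
        Reference-cohort correlation of the edge.
    pcc_n1
        Correlation after appending the single sample.
    n
        Number of reference samples (>= 3).
    """
    if n < 3:
        raise ValueError("need n >= 3 reference samples")
    if abs(pcc_n) >= 1.0 - eps:
        raise InvalidEdgeError(f"|PCC_n| = {abs(pcc_n)} too close to 1")
    return (pcc_n1 - pcc_n) * (n - 1) / (1.0 - pcc_n * pcc_n)


@dataclass
class ReferenceEdgeStats:
    """Per-edge reference correlations with validity bookkeeping.

    ``table`` is indexed by edge id with columns ``gene_a``, ``gene_b``,
    ``pcc`` (NaN for invalid edges), ``valid`` and ``reason``.
    """

    table: pd.DataFrame
    n: int
    eps: float = EPS

    @property
    def valid_edges(self) -> list[tuple[str, str]]:
        sub = self.table[self.table["valid"]]
        return list(zip(sub["gene_a"], sub["gene_b"]))


@dataclass
class EdgeScoreMatrix:
    """Edges x tumor-samples matrix of perturbation scores."""

    scores: pd.DataFrame  # index: edge ids, columns: tumor sample ids
    edges: list[tuple[str, str]]  # aligned to the index
    n: int
    eps: float = EPS

    def sample_scores(self, sample_id: str) -> pd.Series:
        return self.scores[sample_id]


def compute_reference_stats(
    expr: ExpressionMatrix, pathways: PathwayEdgeSets, eps: float = EPS
) -> ReferenceEdgeStats:
    """Reference correlation for every unique edge in the pathway universe.

    The edge universe is the union over pathways (an edge shared by several
    pathways gets one entry).  Edges with a gene absent from the expression
    matrix, a zero-variance reference profile, or |PCC| within ``eps`` of 1
    are flagged invalid with a reason.
    """
    ref_cols = expr.reference_samples
    if len(ref_cols) < 3:
        raise ValueError("need at least 3 reference samples")
    n = len(ref_cols)

    universe = pathways.edge_universe()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    R = expr.values[ref_cols].to_numpy(dtype=float)

    rows = []
    for a, b in universe:
        if a not in gene_pos or b not in gene_pos:
            rows.append((a, b, np.nan, False, "missing gene"))
            continue
        x = R[gene_pos[a]]
        y = R[gene_pos[b]]
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append((a, b, np.nan, False, "zero variance"))
            continue
        r = pearson_cc(x, y)
        if abs(r) >= 1.0 - eps:
            rows.append((a, b, r, False, "near-singular correlation"))
        else:
            rows.append((a, b, r, True, ""))

    table = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "pcc", "valid", "reason"]
    )
    table.index = [edge_id(e) for e in zip(table["gene_a"], table["gene_b"])]
    n_invalid = int((~table["valid"]).sum())
    if n_invalid:
        logger.info("flagged %d invalid edges out of %d", n_invalid, len(table))
    if not table["valid"].any():
        raise ValueError("no usable edges: every edge flagged invalid")
    return ReferenceEdgeStats(table=table, n=n, eps=eps)


def compute_edge_score_matrix(
    expr: ExpressionMatrix, ref_stats: ReferenceEdgeStats
) -> EdgeScoreMatrix:
    """Score every valid edge against every tumor sample.

    For sample *s* and edge *e*, ``PCC_{n+1}`` is the correlation over the
    reference cohort plus *s* alone; the update is done incrementally from
    per-edge reference sums, which is algebraically exact.
    """
    ref_cols = expr.reference_samples
    tum_cols = expr.tumor_samples
    if not tum_cols:
        raise ValueError("no tumor samples in expression matrix")
    n = len(ref_cols)
    if n != ref_stats.n:
        raise ValueError("reference cohort size differs from the stats' n")

    valid = ref_stats.table[ref_stats.table["valid"]]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    ia = np.array([gene_pos[g] for g in valid["gene_a"]], dtype=int)
    ib = np.array([gene_pos[g] for g in valid["gene_b"]], dtype=int)

    X = expr.values.to_numpy(dtype=float)
    # center per gene for numerical conditioning (correlations are
    # shift-invariant and the running-sum update stays exact under a shift)
    X = X - X.mean(axis=1, keepdims=True)
    ref_idx = [expr.sample_ids.index(s) for s in ref_cols]
    tum_idx = [expr.sample_ids.index(s) for s in tum_cols]

    A = X[np.ix_(ia, ref_idx)]  # (E, n)
    B = X[np.ix_(ib, ref_idx)]
    s1a, s1b = A.sum(axis=1), B.sum(axis=1)
    s2a, s2b = (A * A).sum(axis=1), (B * B).sum(axis=1)
    sab = (A * B).sum(axis=1)

    Ta = X[np.ix_(ia, tum_idx)]  # (E, S)
    Tb = X[np.ix_(ib, tum_idx)]

    n1 = n + 1
    S1a = s1a[:, None] + Ta
    S1b = s1b[:, None] + Tb
    S2a = s2a[:, None] + Ta * Ta
    S2b = s2b[:, None] + Tb * Tb
    Sab = sab[:, None] + Ta * Tb

    num = n1 * Sab - S1a * S1b
    den = np.sqrt((n1 * S2a - S1a * S1a) * (n1 * S2b - S1b * S1b))
    pcc1 = np.clip(num / den, -1.0, 1.0)

    pcc_n = valid["pcc"].to_numpy()[:, None]
    scores = (pcc1 - pcc_n) * (n - 1) / (1.0 - pcc_n * pcc_n)

    frame = pd.DataFrame(scores, index=valid.index, columns=tum_cols)
    edges = list(zip(valid["gene_a"], valid["gene_b"]))
    return EdgeScoreMatrix(scores=frame, edges=edges, n=n, eps=ref_stats.eps)


def write_edge_scores(esm: EdgeScoreMatrix, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        esm.scores.to_csv(fh, sep="\t", index_label="edge_id", float_format="%.17g")


def write_invalid_edges(ref_stats: ReferenceEdgeStats, path) -> None:
    bad = ref_stats.table[~ref_stats.table["valid"]]
    bad[["gene_a", "gene_b", "reason"]].to_csv(path, sep="\t", index_label="edge_id")
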