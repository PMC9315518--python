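"""Per-sample GSEA over edge-score-ranked edge lists.

Each tumor sample's edges are ranked by score in descending order and every
pathway's edge set is tested with the weighted Kolmogorov-Smirnov running
sum of GSEA: walking down the list, an edge in the set increments the sum by
|score|^p normalized over the set, an edge outside it decrements by
1/(N - |set|).  The signed maximum deviation is the enrichment score (ES);
significance comes from a same-size random edge-set permutation null
(phenotype permutation is impossible with a single ranked sample), and FDR
is Benjamini-Hochberg across pathways within the sample.  The set members at
or before (positive ES) / at or after (negative ES) the running-sum peak are
the core-enrichment ("leading edge") edges; per pathway passing the FDR cut
they are assembled into that sample's subpathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import PathwayEdgeSets, edge_id
from .edge_scoring import EdgeScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_EXPONENT = 1.0
DEFAULT_N_PERM = 1000
DEFAULT_MIN_SET_SIZE = 5
DEFAULT_ALPHA = 0.05


@dataclass
class RankedEdgeList:
    """One sample's edges in descending score order (ties by edge id)."""

    sample_id: str
    edges: list[tuple[str, str]]
    scores: np.ndarray  # aligned, non-increasing
    tie_break: str = "edge_id_ascending"

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class SampleEnrichment:
    """Per-pathway enrichment results for one sample.

    ``table`` has one row per tested pathway: es, peak (1-based), p, q,
    n_core, direction; ``core_edges`` maps pathway id to its leading-edge
    edges.
    """

    sample_id: str
    table: pd.DataFrame
    core_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


@dataclass
class Subpathway:
    """A sample's core-enrichment edges within one significant pathway."""

    sample_id: str
    pathway_id: str
    edges: set[tuple[str, str]]
    direction: str  # "up" or "down"
    q: float

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e}


def rank_edges(scores: pd.Series, sample_id: str = "") -> RankedEdgeList:
    """Rank one sample's edge scores descending, ties by edge id ascending."""
    if len(scores) == 0:
        raise ValueError("empty score vector")
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite edge scores")
    ids = np.asarray(scores.index, dtype=object)
    order = np.lexsort((ids, -vals))
    from .data_io import parse_edge_id

    return RankedEdgeList(
        sample_id=sample_id,
        edges=[parse_edge_id(ids[i]) for i in order],
        scores=vals[order],
    )


def _hit_mask(ranked: RankedEdgeList, edge_set: Iterable[tuple[str, str]]) -> np.ndarray:
    eset = set(edge_set)
    return np.fromiter((e in eset for e in ranked.edges), dtype=bool, count=len(ranked))


def enrichment_score(
    ranked: RankedEdgeList,
    edge_set: Iterable[tuple[str, str]],
    exponent: float = DEFAULT_EXPONENT,
) -> tuple[float, int, np.ndarray]:
    """Weighted KS enrichment score of ``edge_set`` in the ranked list.

    Returns ``(ES, peak_index, running_sum)`` where ``peak_index`` is the
    1-based position of the signed maximum deviation.  ``exponent = 0``
    reduces to the classical unweighted KS statistic.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    hit = _hit_mask(ranked, edge_set)
    k = int(hit.sum())
    N = len(ranked)
    if k == 0 or k == N:
        raise ValueError("edge set must hit a strict, non-empty subset of the list")
    w = np.where(hit, np.abs(ranked.scores) ** exponent, 0.0)
    norm = w.sum()
    if norm == 0.0:  # all hit scores exactly zero: fall back to equal weights
        w = hit / k
    else:
        w = w / norm
    step = np.where(hit, w, -1.0 / (N - k))
    running = np.cumsum(step)
    peak0 = int(np.argmax(np.abs(running)))
    return float(running[peak0]), peak0 + 1, running


def _null_es_abs(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    exponent: float,
) -> np.ndarray:
    """|ES| for ``n_perm`` random same-size position sets, vectorized.

    The running sum only attains its extremes immediately after a hit
    (candidate maxima) or immediately before a hit (candidate minima), so
    only the k sorted hit positions per permutation are needed.
    """
    N = scores.size
    k = set_size
    # random k-subsets of positions: argpartition of uniform noise
    u = rng.random((n_perm, N))
    pos = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)  # 0-based
    w = np.abs(scores[pos]) ** exponent
    norm = w.sum(axis=1, keepdims=True)
    uniform = norm[:, 0] == 0.0
    if uniform.any():
        w[uniform] = 1.0
        norm = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w / norm, axis=1)
    miss = 1.0 / (N - k)
    i = np.arange(k)
    after = cw - (pos - i) * miss  # value right after hit i
    before = np.concatenate(
        [np.zeros((n_perm, 1)), cw[:, :-1]], axis=1
    ) - (pos - i) * miss  # value right before hit i (after the miss run)
    return np.maximum(after.max(axis=1), -before.min(axis=1))


def permutation_pvalue(
    ranked: RankedEdgeList,
    edge_set: Iterable[tuple[str, str]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    exponent: float = DEFAULT_EXPONENT,
) -> float:
    """Two-sided (|ES|-based) permutation p for one pathway in one sample.

    Null ES values come from ``n_perm`` random same-size edge sets drawn
    from the ranked universe; p uses the add-one estimator
    ``(1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es, _, _ = enrichment_score(ranked, edge_set, exponent)
    k = int(_hit_mask(ranked, edge_set).sum())
    null_abs = _null_es_abs(ranked.scores, k, n_perm, rng, exponent)
    return float((1 + int((null_abs >= abs(es)).sum())) / (n_perm + 1))


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q values (within one sample)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def leading_edge(
    ranked: RankedEdgeList,
    edge_set: Iterable[tuple[str, str]],
    es: float,
    peak_index: int,
) -> list[tuple[str, str]]:
    """Core-enrichment edges: set members at/before (ES>0) or at/after
    (ES<0) the running-sum peak, in rank order."""
    hit = _hit_mask(ranked, edge_set)
    positions = np.nonzero(hit)[0] + 1  # 1-based
    if es > 0:
        keep = positions <= peak_index
    elif es < 0:
        keep = positions >= peak_index
    else:
        return []
    return [ranked.edges[p - 1] for p in positions[keep]]


def analyze_sample(
    scores: pd.Series,
    pathways: PathwayEdgeSets,
    sample_id: str = "",
    exponent: float = DEFAULT_EXPONENT,
    n_perm: int = DEFAULT_N_PERM,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    seed: int | np.random.Generator = 0,
) -> SampleEnrichment:
    """Enrichment of every eligible pathway in one sample's ranked edges."""
    ranked = rank_edges(scores, sample_id=sample_id)
    universe = set(ranked.edges)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    cores: dict[str, list[tuple[str, str]]] = {}
    for pid in pathways.pathway_ids:
        eset = pathways.pathways[pid] & universe
        if len(eset) < min_set_size or len(eset) >= len(universe):
            logger.debug("skipping pathway %s (effective size %d)", pid, len(eset))
            continue
        es, peak, _ = enrichment_score(ranked, eset, exponent)
        p = permutation_pvalue(ranked, eset, n_perm=n_perm, seed=rng, exponent=exponent)
        core = leading_edge(ranked, eset, es, peak)
        cores[pid] = core
        rows.append((pid, es, peak, p, len(core), "up" if es >= 0 else "down"))

    table = pd.DataFrame(
        rows, columns=["pathway_id", "es", "peak", "p", "n_core", "direction"]
    )
    if len(table):
        table["q"] = fdr_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
    table = table[["pathway_id", "es", "peak", "p", "q", "n_core", "direction"]]
    return SampleEnrichment(sample_id=sample_id, table=table, core_edges=cores)


def extract_subpathways(
    enrichment: SampleEnrichment,
    alpha: float = DEFAULT_ALPHA,
    min_edges: int = 1,
) -> list[Subpathway]:
    """Subpathways of one sample: core edges of each pathway with q < alpha."""
    out = []
    for _, row in enrichment.table.iterrows():
        if row["q"] >= alpha:
            continue
        core = enrichment.core_edges.get(row["pathway_id"], [])
        if len(core) < min_edges:
            continue
        out.append(
            Subpathway(
                sample_id=enrichment.sample_id,
                pathway_id=row["pathway_id"],
                edges=set(core),
                direction=row["direction"],
                q=float(row["q"]),
            )
        )
    return out


def analyze_cohort(
    esm: EdgeScoreMatrix,
    pathways: PathwayEdgeSets,
    exponent: float = DEFAULT_EXPONENT,
    n_perm: int = DEFAULT_N_PERM,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    seed: int = 0,
) -> dict[str, SampleEnrichment]:
    """Run per-sample enrichment for every tumor sample in the score matrix.

    Each sample gets an independent child seed spawned from ``seed`` so that
    results do not depend on the number of pathways tested per sample.
    """
    samples = list(esm.scores.columns)
    children = np.random.SeedSequence(seed).spawn(len(samples))
    out = {}
    for sample, child in zip(samples, children):
        out[sample] = analyze_sample(
            esm.scores[sample],
            pathways,
            sample_id=sample,
            exponent=exponent,
            n_perm=n_perm,
            min_set_size=min_set_size,
            seed=np.random.default_rng(child),
        )
    return out


def cohort_subpathways(
    enrichments: Mapping[str, SampleEnrichment],
    alpha: float = DEFAULT_ALPHA,
    min_edges: int = 1,
) -> dict[str, list[Subpathway]]:
    return {
        s: extract_subpathways(enr, alpha=alpha, min_edges=min_edges)
        for s, enr in enrichments.items()
    }


def subpathways_long_table(subpathways: Mapping[str, list[Subpathway]]) -> pd.DataFrame:
    """Long-format table: sample_id, pathway_id, edge_id, gene_a, gene_b."""
    rows = []
    for sample in sorted(subpathways):
        for sp in subpathways[sample]:
            for a, b in sorted(sp.edges):
                rows.append((sample, sp.pathway_id, edge_id((a, b)), a, b))
    return pd.DataFrame(
        rows, columns=["sample_id", "pathway_id", "edge_id", "gene_a", "gene_b"]
    )
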