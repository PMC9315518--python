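"""Gene-level analytics on per-sample subpathways.

A sample's subpathway union is a small graph; its high-degree genes are the
genes whose interactions the sample perturbs most broadly, and they are the
candidate individual drivers.  This module computes per-sample degree
profiles, overlap of top-k high-degree genes with mutation / driver /
immune gene lists, recurrent "potential disease genes", and a permutation
test comparing their cohort mutation ratio against random mutated genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import GeneList, MutationTable
from .edge_gsea import Subpathway

logger = logging.getLogger(__name__)

DEFAULT_KS = (5, 10, 20, 30)


@dataclass
class DegreeProfile:
    """Gene degrees within the union of one sample's subpathway edges."""

    sample_id: str
    degrees: dict[str, int]

    def ranked_genes(self) -> list[str]:
        """All genes, highest degree first, ties by symbol ascending."""
        return sorted(self.degrees, key=lambda g: (-self.degrees[g], g))


@dataclass
class OverlapReport:
    """Top-k overlap rates: one row per (sample, k), plus cohort means."""

    per_sample: pd.DataFrame  # columns: sample_id, k, rate
    mean_rate: pd.Series  # index: k


@dataclass
class PermutationTestResult:
    observed: float
    null: np.ndarray
    p: float
    seed: int

    def __post_init__(self) -> None:
        assert 0.0 < self.p <= 1.0


def node_degrees(subpathways: Sequence[Subpathway], sample_id: str = "") -> DegreeProfile:
    """Degrees on the union of a sample's subpathway edges.

    Each distinct gene pair counts once even when it occurs in several
    pathways' subpathways.
    """
    if not subpathways:
        logger.warning("sample %s has no subpathways; empty degree profile", sample_id)
        return DegreeProfile(sample_id=sample_id, degrees={})
    union: set[tuple[str, str]] = set()
    for sp in subpathways:
        union |= sp.edges
    counts: Counter[str] = Counter()
    for a, b in union:
        counts[a] += 1
        counts[b] += 1
    sid = sample_id or subpathways[0].sample_id
    return DegreeProfile(sample_id=sid, degrees=dict(counts))


def top_k_genes(profile: DegreeProfile, k: int) -> list[str]:
    """The k highest-degree genes (ties by symbol; all genes if fewer)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return profile.ranked_genes()[:k]


def overlap_rate(
    profiles: Mapping[str, DegreeProfile],
    targets: GeneList | Mapping[str, set[str]] | MutationTable,
    conditioning: GeneList | None = None,
    ks: Sequence[int] = DEFAULT_KS,
) -> OverlapReport:
    """Mean rate at which top-k high-degree genes fall in a target set.

    ``targets`` may be a fixed gene list, a per-sample mapping (e.g. each
    sample's own mutated genes) or a MutationTable (uses its per-sample
    view).  ``conditioning`` further restricts the numerator (e.g. to
    driver genes).  The denominator is the number of top-k genes actually
    returned, so samples with fewer than k subpathway genes are handled.
    """
    if isinstance(targets, MutationTable):
        per_sample_targets: Mapping[str, set[str]] | None = targets.by_sample()
        fixed: set[str] | None = None
    elif isinstance(targets, GeneList):
        per_sample_targets = None
        fixed = targets.genes
    else:
        per_sample_targets = targets
        fixed = None

    cond = conditioning.genes if conditioning is not None else None

    rows = []
    for sample in sorted(profiles):
        profile = profiles[sample]
        target = fixed if fixed is not None else per_sample_targets.get(sample, set())
        for k in ks:
            top = top_k_genes(profile, k)
            if not top:
                rows.append((sample, k, 0.0))
                continue
            hits = set(top) & target
            if cond is not None:
                hits &= cond
            rows.append((sample, k, len(hits) / len(top)))

    per_sample = pd.DataFrame(rows, columns=["sample_id", "k", "rate"])
    mean_rate = per_sample.groupby("k")["rate"].mean()
    return OverlapReport(per_sample=per_sample, mean_rate=mean_rate)


def potential_disease_genes(
    per_sample_sets: Mapping[str, set[str]],
    min_samples: int = 10,
    name: str = "potential_disease_genes",
) -> GeneList:
    """Genes recurring in at least ``min_samples`` samples' sets.

    The intended input is, per sample, the intersection of the sample's
    top-5 high-degree genes with its own mutated genes.
    """
    counts: Counter[str] = Counter()
    for genes in per_sample_sets.values():
        counts.update(set(genes))
    selected = {g for g, c in counts.items() if c >= min_samples}
    if not selected:
        raise ValueError(f"no gene recurs in >= {min_samples} samples")
    return GeneList(name=name, genes=selected)


def mutation_ratio(
    gene_set: Iterable[str], mutations: MutationTable, n_samples: int
) -> float:
    """Mean per-gene fraction of samples carrying a mutation in the gene."""
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("empty gene set")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    counts = mutations.gene_sample_counts()
    return float(np.mean([counts.get(g, 0) / n_samples for g in genes]))


def random_gene_test(
    observed_set: Iterable[str],
    universe: GeneList,
    mutations: MutationTable,
    n_samples: int,
    R: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of the observed mutation ratio against random genes.

    Draws ``R`` same-size gene sets without replacement from ``universe``
    (by default the cohort's mutated genes), recomputes the mutation ratio
    for each, and reports the add-one empirical p-value
    ``(1 + #{null >= observed}) / (R + 1)``.
    """
    observed = sorted(set(observed_set))
    pool = sorted(universe.genes)
    if len(pool) <= len(observed):
        raise ValueError("universe must be larger than the observed set")

    counts = mutations.gene_sample_counts()
    ratios = np.array([counts.get(g, 0) / n_samples for g in pool])
    obs_stat = mutation_ratio(observed, mutations, n_samples)

    rng = np.random.default_rng(seed)
    m = len(observed)
    u = rng.random((R, len(pool)))
    draws = np.argpartition(u, m - 1, axis=1)[:, :m]
    null = ratios[draws].mean(axis=1)

    p = float((1 + int((null >= obs_stat).sum())) / (R + 1))
    return PermutationTestResult(observed=obs_stat, null=null, p=p, seed=seed)
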