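"""Readers, writers and in-memory containers for the tool's tabular inputs.

All inputs are plain tab-separated text: an expression matrix (genes x
samples), a three-column pathway edge table (pathway_id, geneA, geneB), a
MAF-like somatic mutation table, a clinical survival table and one-symbol-
per-line gene lists.  Gene symbols are upper-cased and whitespace-stripped
everywhere so that joins across tables never miss on case.  Edges are stored
canonically with the lexicographically smaller symbol first; every module in
the package compares edges by this form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE = "reference"
TUMOR = "tumor"

#: default mapping of textual vital-status values to the 0/1 event indicator
DEFAULT_STATUS_MAP: dict[str, int] = {
    "DEAD": 1,
    "DECEASED": 1,
    "1": 1,
    "ALIVE": 0,
    "LIVING": 0,
    "0": 0,
}


def normalize_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol."""
    return str(symbol).strip().upper()


def canonical_edge(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered gene pair in canonical (lexicographic) order."""
    a, b = normalize_symbol(gene_a), normalize_symbol(gene_b)
    return (a, b) if a <= b else (b, a)


def edge_id(edge: tuple[str, str]) -> str:
    """Stable string key ``GENEA|GENEB`` for a canonical edge."""
    return f"{edge[0]}|{edge[1]}"


def parse_edge_id(eid: str) -> tuple[str, str]:
    a, b = eid.split("|")
    return canonical_edge(a, b)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample role labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per sample.
    sample_role
        Mapping sample id -> ``"reference"`` or ``"tumor"``.
    log_transformed
        Whether the stored values are on the log2(x+1) scale.
    """

    values: pd.DataFrame
    sample_role: dict[str, str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.sample_role)
        if missing:
            raise ValueError(f"samples without a role label: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def reference_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == REFERENCE]

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.sample_role[s] == TUMOR]


@dataclass
class PathwayEdgeSets:
    """Background edge sets: pathway id -> set of canonical gene pairs."""

    pathways: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        for pid, edges in self.pathways.items():
            for a, b in edges:
                if a == b:
                    raise ValueError(f"self-loop {a} in pathway {pid}")
                if (a, b) != canonical_edge(a, b):
                    raise ValueError(f"non-canonical edge ({a}, {b}) in {pid}")

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.pathways)

    def edge_universe(self) -> list[tuple[str, str]]:
        """Sorted union of all pathways' edges (each unique pair once)."""
        universe: set[tuple[str, str]] = set()
        for edges in self.pathways.values():
            universe |= edges
        return sorted(universe)

    def genes(self) -> set[str]:
        return {g for edges in self.pathways.values() for e in edges for g in e}


@dataclass
class MutationTable:
    """Somatic mutation calls with a per-sample mutated-gene-set view."""

    records: pd.DataFrame  # columns: sample_id, gene_symbol, variant_class

    def by_sample(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sample, gene in zip(self.records["sample_id"], self.records["gene_symbol"]):
            out.setdefault(sample, set()).add(gene)
        return out

    def gene_sample_counts(self) -> pd.Series:
        """Number of distinct samples carrying a mutation in each gene."""
        dedup = self.records.drop_duplicates(["sample_id", "gene_symbol"])
        return dedup.groupby("gene_symbol")["sample_id"].nunique().sort_index()

    @property
    def samples(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())


@dataclass
class ClinicalTable:
    """Survival follow-up: one row per sample with time and event status."""

    table: pd.DataFrame  # columns: sample_id, time, status
    time_unit: str = "days"

    def __post_init__(self) -> None:
        if (self.table["time"] <= 0).any():
            bad = self.table.loc[self.table["time"] <= 0, "sample_id"].tolist()
            raise ValueError(f"non-positive survival time for samples {bad}")
        if not self.table["status"].isin([0, 1]).all():
            raise ValueError("status must be 0 (censored) or 1 (event)")

    def aligned(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Rows for ``sample_ids`` (in that order); missing samples dropped."""
        idx = self.table.set_index("sample_id")
        keep = [s for s in sample_ids if s in idx.index]
        return idx.loc[keep].reset_index()


@dataclass
class GeneList:
    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene list {self.name!r} is empty")
        self.genes = {normalize_symbol(g) for g in self.genes}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_expression(
    path,
    reference_samples: Iterable[str],
    tumor_samples: Iterable[str],
    log_transform: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV and label sample roles.

    Duplicate gene symbols are merged by averaging their rows; genes that are
    zero across all retained samples are removed; if ``log_transform`` is set
    the values become log2(x + 1).
    """
    reference_samples = list(reference_samples)
    tumor_samples = list(tumor_samples)
    if not reference_samples or not tumor_samples:
        raise ValueError("reference and tumor sample lists must be non-empty")
    overlap = set(reference_samples) & set(tumor_samples)
    if overlap:
        raise ValueError(f"samples listed as both reference and tumor: {sorted(overlap)}")

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = [normalize_symbol(g) for g in df.index]

    wanted = reference_samples + tumor_samples
    missing = [s for s in wanted if s not in df.columns]
    if missing:
        raise FormatError(f"sample ids absent from expression header: {missing}")
    df = df[wanted]

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().sum() > df[col].isna().sum():
            bad_rows = df.index[coerced.isna() & df[col].notna()].tolist()
            raise FormatError(f"non-numeric value in column {col!r}, rows {bad_rows[:5]}")
        df[col] = coerced

    if df.index.has_duplicates:
        n_dup = df.index.duplicated().sum()
        logger.info("merging %d duplicate gene symbol rows by averaging", n_dup)
        df = df.groupby(level=0, sort=False).mean()

    all_zero = (df == 0).all(axis=1)
    if all_zero.any():
        logger.info("dropping %d genes with all-zero expression", int(all_zero.sum()))
        df = df.loc[~all_zero]

    if log_transform:
        df = np.log2(df + 1.0)

    roles = {s: REFERENCE for s in reference_samples}
    roles.update({s: TUMOR for s in tumor_samples})
    return ExpressionMatrix(values=df, sample_role=roles, log_transformed=log_transform)


def read_pathway_edges(path) -> PathwayEdgeSets:
    """Read a three-column pathway edge TSV (pathway_id, geneA, geneB).

    Edges are canonicalized, duplicates within a pathway dropped, and
    self-loops dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise FormatError(
            f"pathway edge table needs >=3 columns, found {df.shape[1]}"
        )
    pathways: dict[str, set[tuple[str, str]]] = {}
    n_loops = 0
    for pid, a, b in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        pid = str(pid).strip()
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            n_loops += 1
            continue
        pathways.setdefault(pid, set()).add(canonical_edge(a, b))
    if n_loops:
        logger.warning("dropped %d self-loop rows from %s", n_loops, path)
    if not pathways:
        raise FormatError(f"no usable pathway edges in {path}")
    return PathwayEdgeSets(pathways=pathways)


def read_mutations(
    path,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
    exclude_classes: Iterable[str] | None = None,
) -> MutationTable:
    """Read a MAF-like mutation TSV.

    Only the sample and gene columns are required; the variant-class column
    is optional and no consequence filter is applied unless
    ``exclude_classes`` is given.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (sample_col, gene_col):
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    records = pd.DataFrame(
        {
            "sample_id": df[sample_col].astype(str).str.strip(),
            "gene_symbol": [normalize_symbol(g) for g in df[gene_col]],
            "variant_class": (
                df[class_col].astype(str).str.strip()
                if class_col in df.columns
                else "unknown"
            ),
        }
    )
    if exclude_classes:
        drop = records["variant_class"].isin(set(exclude_classes))
        logger.info("excluding %d rows by variant class", int(drop.sum()))
        records = records.loc[~drop]
    return MutationTable(records=records.reset_index(drop=True))


def read_clinical(
    path,
    sample_col: str = "sample",
    time_col: str = "time",
    status_col: str = "status",
    status_map: Mapping[str, int] | None = None,
    time_unit: str = "days",
) -> ClinicalTable:
    """Read a clinical TSV; rows with missing time or status are dropped."""
    status_map = dict(DEFAULT_STATUS_MAP if status_map is None else status_map)
    status_map = {str(k).upper(): v for k, v in status_map.items()}
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (sample_col, time_col, status_col):
        if col not in df.columns:
            raise FormatError(f"clinical table missing required column {col!r}")

    time = pd.to_numeric(df[time_col], errors="coerce")
    raw_status = df[status_col].astype(str).str.strip().str.upper()
    status = raw_status.map(status_map)

    known = raw_status.isin(status_map) | df[status_col].isna()
    unknown = sorted(raw_status[~known].unique())
    if unknown:
        raise FormatError(f"unrecognized status values: {unknown}")

    keep = time.notna() & status.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d clinical rows with missing time/status", n_dropped)

    if (time[keep] < 0).any():
        raise ValueError("negative survival time in clinical table")

    table = pd.DataFrame(
        {
            "sample_id": df.loc[keep, sample_col].astype(str).str.strip(),
            "time": time[keep].astype(float),
            "status": status[keep].astype(int),
        }
    ).reset_index(drop=True)
    return ClinicalTable(table=table, time_unit=time_unit)


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; '#' comments and blanks allowed."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(normalize_symbol(line))
    return GeneList(name=name or str(path), genes=genes)


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers; used by the simulator and CLI)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # full float round-trip through text


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format=_FLOAT_FMT)


def write_pathway_edges(edges: PathwayEdgeSets, path) -> None:
    with open(path, "w") as fh:
        for pid in edges.pathway_ids:
            for a, b in sorted(edges.pathways[pid]):
                fh.write(f"{pid}\t{a}\t{b}\n")


def write_mutations(mut: MutationTable, path) -> None:
    out = mut.records.rename(
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene_symbol": "Hugo_Symbol",
            "variant_class": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_clinical(clin: ClinicalTable, path) -> None:
    out = clin.table.rename(columns={"sample_id": "sample"})
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_gene_list(genes: GeneList, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes.genes):
            fh.write(g + "\n")


def write_sample_list(samples: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(str(s) + "\n")


def read_sample_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
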