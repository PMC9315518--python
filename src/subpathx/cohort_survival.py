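"""Cohort recurrence statistics and survival risk modeling.

Recurrence: an edge (or pathway) enriched in more than half of the cohort's
samples is tested with a one-sided exact binomial test against p0 = 0.5.
High-frequency mutation genes (mutated in more than a threshold fraction of
samples) restrict the recurrent edges to a mutation-linked candidate set.

Survival: each candidate feature (an edge's score column, or a gene's
expression) is screened with a univariate Cox proportional-hazards fit
(Efron tie handling); features with Wald p < alpha form the signature.  The
per-sample risk score is the coefficient-weighted sum of feature values,
patients are split at the median risk score, and the two groups are
compared with Kaplan-Meier curves and a log-rank test.  The screening/risk
coefficients can be estimated on one cohort and evaluated on an independent
one, which keeps the final log-rank test free of selection bias.

The univariate Cox solver is implemented here (Newton-Raphson on the
partial likelihood) so that screening hundreds of candidate features per
cohort is fast; lifelines provides the Kaplan-Meier and log-rank machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .data_io import ClinicalTable, GeneList, MutationTable
from .edge_gsea import Subpathway

logger = logging.getLogger(__name__)


class CoxConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration cannot converge."""


@dataclass
class RecurrenceTable:
    """Per-unit counts of samples whose subpathway output contains the unit."""

    unit: str  # "edge" or "pathway"
    counts: pd.Series  # index: unit id, value: sample count
    n_samples: int


@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    p: float  # two-sided Wald

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class RiskModel:
    """Univariate-Cox-weighted risk signature and its stratification."""

    features: list[str]
    betas: pd.Series  # index: features
    cox_table: pd.DataFrame  # all screened features: beta, se, hr, p, selected
    risk_scores: pd.Series  # evaluated samples
    groups: pd.Series  # "high"/"low", same index
    cutoff: float
    logrank_statistic: float
    logrank_p: float


@dataclass
class SurvivalCurves:
    """Product-limit curves per group plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> columns: time, at_risk, survival
    logrank_statistic: float
    logrank_p: float


# ---------------------------------------------------------------------------
# Recurrence
# ---------------------------------------------------------------------------


def recurrence_counts(
    subpathways_by_sample: Mapping[str, Sequence[Subpathway]],
    unit: str = "edge",
) -> RecurrenceTable:
    """Count, per edge or pathway, how many samples' output contains it."""
    if unit not in ("edge", "pathway"):
        raise ValueError("unit must be 'edge' or 'pathway'")
    counts: dict[str, int] = {}
    for sps in subpathways_by_sample.values():
        if unit == "edge":
            present = {f"{a}|{b}" for sp in sps for a, b in sp.edges}
        else:
            present = {sp.pathway_id for sp in sps}
        for key in present:
            counts[key] = counts.get(key, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    return RecurrenceTable(unit=unit, counts=series, n_samples=len(subpathways_by_sample))


def binomial_enrichment(k: int, N: int, p0: float = 0.5) -> float:
    """One-sided exact binomial upper tail P(X >= k | N, p0)."""
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    return float(stats.binom.sf(k - 1, N, p0))


def recurrent_significant(
    table: RecurrenceTable, alpha: float = 0.05, p0: float = 0.5
) -> pd.DataFrame:
    """Units enriched in more than ``p0`` of samples with binomial p < alpha."""
    p = np.array([binomial_enrichment(int(k), table.n_samples, p0) for k in table.counts])
    df = pd.DataFrame(
        {"count": table.counts, "fraction": table.counts / table.n_samples, "p": p}
    )
    df["significant"] = (df["fraction"] > p0) & (df["p"] < alpha)
    return df


def high_frequency_mutations(
    mutations: MutationTable,
    n_samples: int,
    threshold: float = 0.05,
    name: str = "high_frequency_mutations",
) -> GeneList:
    """Genes mutated in strictly more than ``threshold`` of the cohort."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    counts = mutations.gene_sample_counts()
    selected = set(counts.index[counts > threshold * n_samples])
    if not selected:
        raise ValueError("no gene exceeds the mutation-frequency threshold")
    return GeneList(name=name, genes=selected)


def mutated_edge_filter(
    edges: Iterable[tuple[str, str]], hf_genes: GeneList
) -> list[tuple[str, str]]:
    """Edges with at least one endpoint in the high-frequency gene list."""
    return [e for e in edges if e[0] in hf_genes.genes or e[1] in hf_genes.genes]


# ---------------------------------------------------------------------------
# Univariate Cox (Efron ties)
# ---------------------------------------------------------------------------


def _cox_quantities(beta: float, x, time, status):
    """(loglik, gradient, information) of the Efron partial likelihood.

    Inputs must be sorted by time.  Unique event times take a fully
    vectorized path (Efron reduces to Breslow there); tied event times fall
    back to a per-group loop.
    """
    eta = beta * x
    eta = eta - eta.max()  # overflow guard; shifts cancel in every ratio
    e = np.exp(eta)
    xe = x * e
    x2e = x * x * e

    # suffix sums over the risk set (subjects with time >= t)
    cs_e = np.cumsum(e[::-1])[::-1]
    cs_xe = np.cumsum(xe[::-1])[::-1]
    cs_x2e = np.cumsum(x2e[::-1])[::-1]

    events = np.nonzero(status)[0]
    ev_times = time[events]
    if np.unique(ev_times).size == ev_times.size:
        first = np.searchsorted(time, ev_times, side="left")
        phi, psi, chi = cs_e[first], cs_xe[first], cs_x2e[first]
        mean = psi / phi
        loglik = float(eta[events].sum() - np.log(phi).sum())
        grad = float(x[events].sum() - mean.sum())
        info = float((chi / phi - mean * mean).sum())
        return loglik, grad, info

    loglik = grad = info = 0.0
    i = 0
    n = time.size
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = np.nonzero(status[i:j])[0] + i
        d = deaths.size
        if d:
            phi_r, psi_r, chi_r = cs_e[i], cs_xe[i], cs_x2e[i]
            phi_d, psi_d, chi_d = e[deaths].sum(), xe[deaths].sum(), x2e[deaths].sum()
            frac = np.arange(d) / d
            phi = phi_r - frac * phi_d
            psi = psi_r - frac * psi_d
            chi = chi_r - frac * chi_d
            loglik += eta[deaths].sum() - np.log(phi).sum()
            mean = psi / phi
            grad += x[deaths].sum() - mean.sum()
            info += (chi / phi - mean * mean).sum()
        i = j
    return loglik, grad, info


def univariate_cox(
    values: Sequence[float],
    clinical_or_time,
    status=None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit with Efron ties.

    Accepts either ``(values, ClinicalTable-aligned DataFrame)`` arrays or
    explicit ``(values, time, status)`` vectors.  Raises
    :class:`CoxConvergenceError` for constant covariates, too few events, or
    monotone-separable data.
    """
    x = np.asarray(values, dtype=float)
    if status is None:
        clin = clinical_or_time
        time = np.asarray(clin["time"], dtype=float)
        status_arr = np.asarray(clin["status"], dtype=int)
    else:
        time = np.asarray(clinical_or_time, dtype=float)
        status_arr = np.asarray(status, dtype=int)
    if not (x.size == time.size == status_arr.size):
        raise ValueError("values, time and status must have equal length")
    if status_arr.sum() < 2:
        raise CoxConvergenceError("need at least 2 events")
    if np.ptp(x) == 0.0:
        raise CoxConvergenceError("constant feature")

    order = np.argsort(time, kind="stable")
    x, time, status_arr = x[order], time[order], status_arr[order]

    beta = 0.0
    loglik, grad, info = _cox_quantities(beta, x, time, status_arr)
    for _ in range(max_iter):
        if info <= 1e-12:
            raise CoxConvergenceError("vanishing information (separation?)")
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_quantities(new_beta, x, time, status_arr)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_quantities(new_beta, x, time, status_arr)
            halvings += 1
        converged = abs(step) < tol or abs(new_grad) < 1e-9
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(beta) > 50:
            raise CoxConvergenceError("coefficient diverging (separation?)")
        if converged:
            break
    else:
        raise CoxConvergenceError("Newton iteration did not converge")

    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(beta=float(beta), se=float(se), hr=float(np.exp(beta)), p=float(p))


def cox_screen(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox over every feature column; non-convergent fits skipped.

    ``features`` is samples x features.  Returns one row per feature with
    beta, se, hr, p and a ``selected`` flag (Wald p < alpha).  No multiple-
    testing correction is applied at this step.
    """
    clin = clinical.aligned(features.index)
    feats = features.loc[clin["sample_id"]]
    rows = []
    for name in feats.columns:
        try:
            res = univariate_cox(feats[name].to_numpy(), clin)
        except CoxConvergenceError as exc:
            logger.warning("feature %s skipped: %s", name, exc)
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        rows.append((name, res.beta, res.se, res.hr, res.p, res.p < alpha))
    return pd.DataFrame(
        rows, columns=["feature", "beta", "se", "hr", "p", "selected"]
    ).set_index("feature")


# ---------------------------------------------------------------------------
# Risk score, stratification, survival curves
# ---------------------------------------------------------------------------


def risk_score(betas: Sequence[float], values: Sequence[float]) -> float:
    """Coefficient-weighted sum of feature values for one sample."""
    b = np.asarray(betas, dtype=float)
    v = np.asarray(values, dtype=float)
    if b.shape != v.shape:
        raise ValueError("betas and values must align")
    return float(b @ v) if b.size else 0.0


def risk_scores(betas: pd.Series, features: pd.DataFrame) -> pd.Series:
    """Per-sample risk scores for a samples x features frame."""
    missing = [f for f in betas.index if f not in features.columns]
    if missing:
        raise ValueError(f"features absent from matrix: {missing}")
    return features[betas.index] @ betas


def median_split(scores: pd.Series) -> tuple[pd.Series, float]:
    """Split at the median: score > median -> high, else low."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0.0:
        raise ValueError("degenerate split: all risk scores identical")
    cutoff = float(np.median(vals))
    groups = pd.Series(
        np.where(vals > cutoff, "high", "low"), index=scores.index, name="group"
    )
    return groups, cutoff


def kaplan_meier(times: Sequence[float], status: Sequence[int]) -> pd.DataFrame:
    """Product-limit curve: columns time, at_risk, survival."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(status, dtype=int)
    if t.size == 0:
        raise ValueError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=s)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "survival": surv.to_numpy(dtype=float),
        }
    )


def logrank(
    times_a: Sequence[float],
    status_a: Sequence[int],
    times_b: Sequence[float],
    status_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square statistic, p)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    sa, sb = np.asarray(status_a, int), np.asarray(status_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if sa.sum() + sb.sum() == 0:
        raise ValueError("log-rank undefined without any event")
    res = logrank_test(ta, tb, event_observed_A=sa, event_observed_B=sb)
    return float(res.test_statistic), float(res.p_value)


def survival_curves(
    clinical: ClinicalTable, groups: pd.Series
) -> SurvivalCurves:
    """KM curve per group plus the two-group log-rank comparison."""
    clin = clinical.aligned(groups.index).set_index("sample_id")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("expected exactly two groups")
    per_group = {}
    parts = {}
    for lab in labels:
        ids = groups.index[groups == lab]
        sub = clin.loc[[s for s in ids if s in clin.index]]
        per_group[lab] = kaplan_meier(sub["time"], sub["status"])
        parts[lab] = sub
    stat, p = logrank(
        parts[labels[0]]["time"], parts[labels[0]]["status"],
        parts[labels[1]]["time"], parts[labels[1]]["status"],
    )
    return SurvivalCurves(curves=per_group, logrank_statistic=stat, logrank_p=p)


def risk_pipeline(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    eval_features: pd.DataFrame | None = None,
    eval_clinical: ClinicalTable | None = None,
    alpha: float = 0.05,
) -> RiskModel:
    """Screen -> weight -> score -> median split -> log-rank.

    Coefficients are estimated on ``(features, clinical)``; stratification
    is evaluated on ``(eval_features, eval_clinical)`` when given (an
    independent validation cohort), otherwise in-sample.
    """
    screen = cox_screen(features, clinical, alpha=alpha)
    selected = screen.index[screen["selected"].fillna(False)].tolist()
    if not selected:
        raise ValueError("no feature passed the univariate Cox screen")
    betas = screen.loc[selected, "beta"]

    if eval_features is None:
        eval_features = features
        eval_clinical = clinical
    if eval_clinical is None:
        raise ValueError("eval_clinical required with eval_features")

    clin = eval_clinical.aligned(eval_features.index)
    feats = eval_features.loc[clin["sample_id"]]
    scores = risk_scores(betas, feats)
    groups, cutoff = median_split(scores)

    high = clin.set_index("sample_id").loc[groups.index[groups == "high"]]
    low = clin.set_index("sample_id").loc[groups.index[groups == "low"]]
    stat, p = logrank(high["time"], high["status"], low["time"], low["status"])

    return RiskModel(
        features=selected,
        betas=betas,
        cox_table=screen,
        risk_scores=scores,
        groups=groups,
        cutoff=cutoff,
        logrank_statistic=stat,
        logrank_p=p,
    )
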