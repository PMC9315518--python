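"""Self-contained validation experiments on synthetic cohorts.

Each function generates its own data with the package's synthetic-cohort
generator (or direct bivariate-normal draws), runs the method end to end,
and returns the measured quantity.  These are the experiments the test
suite asserts on and the reproduction script reports; the problem sizes are
deliberately desk-scale (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import synthetic_data as sd
from .cohort_survival import risk_pipeline, univariate_cox
from .data_io import ClinicalTable, GeneList, MutationTable, edge_id
from .edge_gsea import analyze_cohort
from .edge_scoring import (
    compute_edge_score_matrix,
    compute_reference_stats,
    edge_score,
    pearson_cc,
)


def null_edge_score_stats(
    n: int = 200,
    n_rep: int = 5000,
    max_abs_rho: float = 0.8,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical (mean, sd) of the edge score when the added sample is null.

    Each replicate draws ``n + 1`` points from a bivariate normal with a
    random correlation in ``[-max_abs_rho, max_abs_rho]``; the first ``n``
    form the reference, the last is the added sample.
    """
    rng = np.random.default_rng(seed)
    scores = np.empty(n_rep)
    for i in range(n_rep):
        rho = rng.uniform(-max_abs_rho, max_abs_rho)
        z1 = rng.standard_normal(n + 1)
        z2 = rng.standard_normal(n + 1)
        x = z1
        y = rho * z1 + np.sqrt(1 - rho * rho) * z2
        r_n = pearson_cc(x[:n], y[:n])
        r_n1 = pearson_cc(x, y)
        scores[i] = edge_score(r_n, r_n1, n)
    return float(scores.mean()), float(scores.std())


def planted_recovery(
    sim_seed: int = 1,
    analysis_seed: int = 101,
    n_tumor: int = 20,
    n_perm: int = 1000,
) -> tuple[float, float]:
    """Planted-pathway recovery on a default synthetic cohort.

    Returns ``(recovery_rate, core_coverage)``: the fraction of tumor
    samples in which the planted pathway attains the smallest FDR, and the
    mean fraction of each sample's planted perturbed edges contained in the
    planted pathway's core-enrichment edges.
    """
    config = sd.SimulationConfig(seed=sim_seed, n_tumor=n_tumor)
    cohort = sd.generate_cohort(config)
    ref_stats = compute_reference_stats(cohort.expression, cohort.pathways)
    esm = compute_edge_score_matrix(cohort.expression, ref_stats)
    enrichments = analyze_cohort(
        esm, cohort.pathways, n_perm=n_perm, seed=analysis_seed
    )
    recovered = 0
    coverage = []
    for sample, enr in enrichments.items():
        table = enr.table
        planted = cohort.truth.planted[sample][0]
        q_planted = table.loc[table["pathway_id"] == planted, "q"].iloc[0]
        recovered += q_planted <= table["q"].min()
        perturbed = set(cohort.truth.perturbed_edges[sample])
        core = {edge_id(e) for e in enr.core_edges.get(planted, [])}
        coverage.append(len(core & perturbed) / len(perturbed))
    return recovered / len(enrichments), float(np.mean(coverage))


def cox_recovery(
    beta: float = 0.8,
    n: int = 300,
    censoring: float = 0.2,
    baseline_hazard: float = 0.01,
    n_rep: int = 100,
    seed: int = 0,
    band: tuple[float, float] = (0.6, 1.0),
) -> tuple[float, float]:
    """Fraction of replicates with the Cox estimate inside ``band``, and the
    mean estimate, for data simulated from h(t|x) = h0 * exp(beta * x)."""
    root = np.random.default_rng(seed)
    hits = 0
    betas = np.empty(n_rep)
    for i in range(n_rep):
        rng = np.random.default_rng(root.integers(2**31))
        x = rng.standard_normal(n)
        t = rng.exponential(1.0 / (baseline_hazard * np.exp(beta * x)))
        cens = rng.random(n) < censoring
        time_obs = np.maximum(np.where(cens, t * rng.random(n), t), 1e-9)
        status = (~cens).astype(int)
        res = univariate_cox(x, time_obs, status)
        betas[i] = res.beta
        hits += band[0] <= res.beta <= band[1]
    return hits / n_rep, float(betas.mean())


#: replicate design for the end-to-end survival experiments: small pathways,
#: a variable number of planted pathways per sample (so the perturbation
#: load varies), and a half/half discovery/validation split
SURVIVAL_REPLICATE = dict(
    n_pathways=6, n_nodes=12, n_reference=60, n_tumor=240,
    planted_per_sample=(0, 4),
)


def survival_rejection_rate(
    gamma: float,
    n_rep: int,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Median-split log-rank rejection rate of the full risk pipeline.

    Each replicate generates a cohort whose hazard depends on perturbation
    load through ``gamma``, computes edge scores, screens all pathway edges
    with univariate Cox on the discovery half, and tests the risk-score
    median split on the validation half.  A replicate with no screened
    feature counts as a non-rejection.
    """
    root = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        config = sd.SimulationConfig(
            seed=int(root.integers(2**31)), gamma=gamma, **SURVIVAL_REPLICATE
        )
        cohort = sd.generate_cohort(config)
        ref_stats = compute_reference_stats(cohort.expression, cohort.pathways)
        esm = compute_edge_score_matrix(cohort.expression, ref_stats)
        features = esm.scores.T  # samples x edges
        samples = list(features.index)
        half = len(samples) // 2
        train, val = samples[:half], samples[half:]
        tbl = cohort.clinical.table
        clin_train = ClinicalTable(
            tbl[tbl["sample_id"].isin(train)].reset_index(drop=True)
        )
        clin_val = ClinicalTable(
            tbl[tbl["sample_id"].isin(val)].reset_index(drop=True)
        )
        try:
            model = risk_pipeline(
                features.loc[train], clin_train,
                eval_features=features.loc[val], eval_clinical=clin_val,
            )
        except ValueError:
            continue
        rejections += model.logrank_p < alpha
    return rejections / n_rep


def permutation_null_pvalues(
    n_rep: int = 200,
    n_genes: int = 60,
    n_samples: int = 40,
    set_size: int = 8,
    R: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Null p-values of the random-gene mutation-ratio test.

    Mutations are drawn with heterogeneous per-gene rates; each replicate's
    "observed" set is itself a random draw, so its p-value should be
    (super-)uniform.
    """
    from .subpathway_genes import random_gene_test

    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    rates = rng.uniform(0.02, 0.3, n_genes)
    rows = []
    for s in range(n_samples):
        hit = rng.random(n_genes) < rates
        rows.extend((f"S{s:03d}", genes[j], "x") for j in np.nonzero(hit)[0])
    import pandas as pd

    mutations = MutationTable(
        records=pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class"])
    )
    universe = GeneList("universe", set(genes))
    ps = np.empty(n_rep)
    for i in range(n_rep):
        observed = list(rng.choice(genes, set_size, replace=False))
        ps[i] = random_gene_test(
            observed, universe, mutations, n_samples, R=R,
            seed=int(rng.integers(2**31)),
        ).p
    return ps


def permutation_calibration_ks_p(n_rep: int = 200, seed: int = 0) -> float:
    """One-sided KS p-value testing the null p-values for anti-conservatism."""
    ps = permutation_null_pvalues(n_rep=n_rep, seed=seed)
    return float(stats.kstest(ps, "uniform", alternative="greater").pvalue)
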