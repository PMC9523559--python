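"""Calibration experiments for the inverted scan.

Self-contained simulation studies used to verify that the estimator is
unbiased, that its Wald test holds its nominal size, and that a planted
(position, metabolite-ratio) signal is recovered end to end.  The tests and
the reproduction script both drive these functions, so the numbers they
report are always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import association, metab_qc, seq_qc
from .pipeline import RunConfig, run_pipeline_frames
from .synthetic import CausalEffect, SimulationConfig, simulate_cohort

#: a within-block metabolite pair of the synthetic panel (correlated, shared
#: log-scale), used as the causal ratio in calibration runs
CAUSAL_NUM = "PC aa C28:0"
CAUSAL_DEN = "PC aa C28:1"

_Z975 = float(stats.norm.ppf(0.975))


def _calibration_config(**overrides) -> dict:
    """Generator settings for estimator calibration: defaults, except that
    the per-position intercept spread and homoplasmic fraction are zeroed so
    the replicates probe the estimator's sampling distribution at a single
    heteroplasmic site."""
    base = dict(
        n_metabolites=4,
        block_size=2,
        position_sd=0.0,
        homoplasmic_fraction=0.0,
        missing_rate=0.0,
        outlier_rate=0.0,
    )
    base.update(overrides)
    return base


def recovery_experiment(
    beta: float,
    n_replicates: int = 200,
    n_individuals: int = 1000,
    seed: int = 1000,
) -> dict:
    """Repeatedly simulate a causal position and refit the inverted model.

    Returns the replicate estimates, their mean, the Monte-Carlo standard
    error of that mean, and the empirical coverage of the nominal 95%
    confidence interval.
    """
    estimates = np.empty(n_replicates)
    std_errors = np.empty(n_replicates)
    covered = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_positions=1,
            causal_effects=(CausalEffect(1, CAUSAL_NUM, CAUSAL_DEN, beta),),
            seed=seed + r,
            **_calibration_config(),
        )
        cohort = simulate_cohort(cfg)
        alleles = seq_qc.call_alleles(cohort.tensor, cohort.truth.reference)
        Y, coverage = association.build_heteroplasmy(cohort.tensor, alleles)
        mr = (cohort.panel.complete[CAUSAL_NUM] / cohort.panel.complete[CAUSAL_DEN]).to_numpy()
        fit = association.fit_inverted_model(Y[:, 0], mr, cohort.covariates, coverage[:, 0])
        estimates[r] = fit.beta
        std_errors[r] = fit.se
        if abs(fit.beta - beta) <= _Z975 * fit.se:
            covered += 1
    mean = float(estimates.mean())
    mc_error = (
        float(estimates.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else float("nan")
    )
    return {
        "beta": beta,
        "estimates": estimates,
        "std_errors": std_errors,
        "mean": mean,
        "bias": mean - beta,
        "mc_error": mc_error,
        "coverage": covered / n_replicates,
    }


def null_calibration(
    n_fits: int = 2000,
    n_individuals: int = 500,
    seed: int = 77,
    alpha: float = 0.05,
) -> dict:
    """Size of the Wald test under the global null.

    One cohort with ``n_fits`` independent null positions is scanned
    against the ratio phenotypes; each position contributes the p-value of
    one ratio (assigned cyclically), so the ``n_fits`` p-values are
    mutually independent and should be Uniform(0,1).
    """
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_positions=n_fits,
        seed=seed,
        **_calibration_config(n_metabolites=10, block_size=5),
    )
    cohort = simulate_cohort(cfg)
    alleles = seq_qc.call_alleles(cohort.tensor, cohort.truth.reference)
    ratio_index, ratios = metab_qc.enumerate_ratios(cohort.panel)
    results = association.run_scan(
        cohort.tensor, alleles, ratio_index, ratios, cohort.panel, cohort.covariates
    )
    ratio_rows = results[results["kind"] == "ratio"]
    order = {r.phenotype_id: i for i, r in enumerate(ratio_index)}
    m = len(ratio_index)
    picked = ratio_rows[
        (ratio_rows["position"] - 1) % m == ratio_rows["phenotype"].map(order)
    ]
    p = picked["p"].to_numpy()
    return {
        "pvalues": p,
        "rejection_rate": float((p < alpha).mean()),
        "n_fits": len(p),
        "ks_pvalue": float(stats.kstest(p, "uniform").pvalue),
        "genomic_lambda": association.genomic_lambda(p),
    }


def planted_signal_experiment(
    n_runs: int = 50,
    seed: int = 4000,
    beta: float = 1.5,
    n_individuals: int = 200,
    n_positions: int = 50,
    n_metabolites: int = 10,
    causal_position: int = 17,
) -> dict:
    """End-to-end recovery: in each seeded run, does the planted
    (position, ratio) pair attain the scan's smallest ratio p-value?"""
    phenotype_id = f"{CAUSAL_NUM}/{CAUSAL_DEN}"
    hits = 0
    for r in range(n_runs):
        cfg = SimulationConfig(
            n_individuals=n_individuals,
            n_metabolites=n_metabolites,
            n_positions=n_positions,
            causal_effects=(CausalEffect(causal_position, CAUSAL_NUM, CAUSAL_DEN, beta),),
            homoplasmic_fraction=0.2,
            seed=seed + r,
        )
        cohort = simulate_cohort(cfg)
        result = run_pipeline_frames(
            cohort.tensor, cohort.covariates, cohort.panel, cohort.truth.reference,
            RunConfig(seed=seed + r),
        )
        ratio = result.results[result.results["kind"] == "ratio"].dropna(subset=["p"])
        top = ratio.loc[ratio["p"].idxmin()]
        if int(top["position"]) == causal_position and top["phenotype"] == phenotype_id:
            hits += 1
    return {"n_runs": n_runs, "hits": hits, "hit_rate": hits / n_runs}
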