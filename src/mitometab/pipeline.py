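"""End-to-end orchestration: QC step 1 -> QC step 2 -> scan -> correction.

``run_pipeline_frames`` drives the full analysis on in-memory objects and
is what the tests exercise; ``run_pipeline`` is a thin file-based wrapper
around it that reads the three input tables plus the reference FASTA and
writes the report bundle (QC ledgers, full results, significant hits,
M_eff report, genomic-control lambda summary, optional plots).
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association, metab_qc, multiple_testing, seq_qc
from .annotation import gene_of
from .counts import AlleleCountTensor
from .metab_qc import MetabolitePanel


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run; threshold defaults equal
    the study's printed values."""

    counts_path: str = ""
    covariates_path: str = ""
    metabolites_path: str = ""
    metabolite_metadata_path: str = ""
    reference_path: str = ""
    output_dir: str = "mitometab_out"
    min_mean_coverage: float = 1000.0
    homoplasmy_threshold: float = 0.007
    completeness_min_fraction: float = 0.8
    outlier_k_sd: float = 3.0
    alpha: float = 0.05
    p_gain_critical: float | None = None  # default: the metabolite count
    log2_ratios: bool = False
    pmm_iterations: int = 10
    pmm_donors: int = 5
    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    individual_report: seq_qc.QCReport
    position_report: seq_qc.QCReport
    alleles: list
    completeness_report: pd.DataFrame
    outlier_report: pd.DataFrame
    results: pd.DataFrame
    meff: multiple_testing.MeffResult
    threshold: float
    p_gain_critical: float
    lambda_summary: pd.DataFrame
    significant: pd.DataFrame


def run_pipeline_frames(
    tensor: AlleleCountTensor,
    covariates: pd.DataFrame,
    panel: MetabolitePanel,
    reference: str,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run QC, the inverted scan and the significance gate in memory."""
    # --- QC step 1: sequencing side --------------------------------------
    tensor, ind_report = seq_qc.exclude_individuals(
        tensor, covariates, config.min_mean_coverage
    )
    alleles = seq_qc.call_alleles(tensor, reference)
    qc_cfg = seq_qc.SeqQCConfig(
        min_mean_coverage=config.min_mean_coverage,
        homoplasmy_threshold=config.homoplasmy_threshold,
    )
    tensor, pos_report = seq_qc.filter_positions(tensor, alleles, qc_cfg)
    retained = set(tensor.positions)
    alleles = [a for a in alleles if a.position in retained]

    # --- QC step 2: metabolite side ---------------------------------------
    shared = [i for i in tensor.individuals if i in panel.values.index]
    if len(shared) < len(tensor.individuals):
        tensor = tensor.select_individuals(np.isin(tensor.individuals, shared))
    panel = panel.select_individuals(list(tensor.individuals))
    panel, completeness_report = metab_qc.apply_completeness_filter(
        panel, config.completeness_min_fraction
    )
    panel, outlier_report = metab_qc.mask_outliers(panel, config.outlier_k_sd)
    panel = metab_qc.impute_pmm(
        panel, config.pmm_iterations, config.pmm_donors, seed=config.seed
    )
    ratio_index, ratios = metab_qc.enumerate_ratios(panel, log2=config.log2_ratios)

    # --- association scan --------------------------------------------------
    results = association.run_scan(
        tensor, alleles, ratio_index, ratios, panel, covariates.loc[list(tensor.individuals)]
    )

    # --- multiple testing ---------------------------------------------------
    meff = multiple_testing.meff_from_data(ratios.to_numpy())
    threshold = multiple_testing.significance_threshold(config.alpha, meff.m_eff)
    p_gain_critical = (
        config.p_gain_critical if config.p_gain_critical is not None else panel.n_metabolites
    )
    results = multiple_testing.add_p_gain(results)
    results = multiple_testing.apply_significance_gate(results, threshold, p_gain_critical)

    ratio_rows = results[results["kind"] == "ratio"]
    lam = (
        ratio_rows.groupby("phenotype", sort=False)["p"]
        .apply(lambda p: association.genomic_lambda(p.dropna()))
        .rename("lambda")
        .reset_index()
    )

    allele_map = {a.position: a for a in alleles}
    significant = ratio_rows[ratio_rows["significant"]].copy()
    significant["ref"] = [allele_map[p].ref_base for p in significant["position"]]
    significant["alt"] = [allele_map[p].alt_base for p in significant["position"]]
    significant["gene"] = [gene_of(int(p)) for p in significant["position"]]
    significant = significant.sort_values("p", kind="stable").reset_index(drop=True)

    return PipelineResult(
        ind_report,
        pos_report,
        alleles,
        completeness_report,
        outlier_report,
        results,
        meff,
        threshold,
        p_gain_critical,
        lam,
        significant,
    )


def _results_table(result: PipelineResult) -> pd.DataFrame:
    allele_map = {a.position: a for a in result.alleles}
    table = result.results.copy()
    table["ref"] = [allele_map[p].ref_base for p in table["position"]]
    table["alt"] = [allele_map[p].alt_base for p in table["position"]]
    table["gene"] = [gene_of(int(p)) for p in table["position"]]
    cols = [
        "position", "ref", "alt", "gene", "phenotype", "kind", "numerator",
        "denominator", "beta", "se", "z", "p", "p_gain", "n", "significant",
    ]
    return table[cols].sort_values("p", kind="stable", na_position="last").reset_index(drop=True)


def write_reports(result: PipelineResult, outdir) -> dict:
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ledger = pd.concat(
        [result.individual_report.to_frame(), result.position_report.to_frame()],
        ignore_index=True,
    )
    paths["qc_ledger"] = out / "qc_ledger.tsv"
    ledger.to_csv(paths["qc_ledger"], sep="\t", index=False)

    table = _results_table(result)
    paths["results"] = out / "results.tsv"
    table.to_csv(paths["results"], sep="\t", index=False, float_format="%.6g")

    paths["significant"] = out / "significant_hits.tsv"
    sig_cols = ["gene", "position", "ref", "alt", "phenotype", "beta", "se", "p", "p_gain"]
    result.significant[sig_cols].to_csv(
        paths["significant"], sep="\t", index=False, float_format="%.6g"
    )

    paths["meff"] = out / "meff_report.tsv"
    pd.DataFrame(
        {
            "eigenvalue_rank": np.arange(1, len(result.meff.eigenvalues) + 1),
            "eigenvalue": np.sort(result.meff.eigenvalues)[::-1],
        }
    ).to_csv(paths["meff"], sep="\t", index=False, float_format="%.8g")

    paths["lambda"] = out / "lambda_summary.tsv"
    result.lambda_summary.to_csv(paths["lambda"], sep="\t", index=False, float_format="%.6g")

    paths["summary"] = out / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(
            {
                "n_individuals_retained": result.individual_report.n_retained,
                "n_individuals_excluded": result.individual_report.n_excluded,
                "n_positions_retained": result.position_report.n_retained,
                "m_phenotypes": result.meff.m,
                "m_eff": result.meff.m_eff,
                "threshold": result.threshold,
                "p_gain_critical": result.p_gain_critical,
                "n_significant": int(len(result.significant)),
            },
            fh,
            indent=2,
        )
    return {k: str(v) for k, v in paths.items()}


def write_plots(result: PipelineResult, outdir) -> dict:
    """Static Manhattan-style and QQ plots of the ratio scan."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ratio = result.results[result.results["kind"] == "ratio"].dropna(subset=["p"])
    best = ratio.groupby("position", sort=True)["p"].min()

    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.scatter(best.index, -np.log10(best.to_numpy()), s=6, color="#30618c")
    ax.axhline(-np.log10(result.threshold), color="firebrick", lw=0.8, ls="--")
    ax.set_xlabel("mtDNA position (rCRS)")
    ax.set_ylabel(r"$-\log_{10} p$ (best ratio)")
    fig.tight_layout()
    manhattan = out / "manhattan.png"
    fig.savefig(manhattan, dpi=150)
    plt.close(fig)

    p = np.sort(ratio["p"].to_numpy())
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(exp, -np.log10(p), s=4, color="#30618c")
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    qq = out / "qq.png"
    fig.savefig(qq, dpi=150)
    plt.close(fig)
    return {"manhattan": str(manhattan), "qq": str(qq)}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based entry point: read inputs, run, write the report bundle."""
    try:
        tensor = AlleleCountTensor.read_tsv(config.counts_path)
        covariates = pd.read_csv(config.covariates_path, index_col="individual_id")
        panel = MetabolitePanel.read_csv(
            config.metabolites_path, config.metabolite_metadata_path
        )
        reference = seq_qc.read_reference(config.reference_path)
    except (KeyError, ValueError) as err:
        raise ValueError(f"input schema mismatch: {err}") from err
    result = run_pipeline_frames(tensor, covariates, panel, reference, config)
    write_reports(result, config.output_dir)
    if config.make_plots:
        write_plots(result, config.output_dir)
    return result
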