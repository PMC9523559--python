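"""Multiple-testing correction for the ratio scan.

The 11k+ metabolite-ratio phenotypes are strongly correlated, so a plain
Bonferroni correction is far too severe.  The effective number of
independent tests M_eff is estimated from the eigenvalue spectrum of the
phenotype correlation matrix with the Li & Ji estimator (as popularized by
the matSpD family of tools): each eigenvalue contributes 1 if it is at
least 1 plus its fractional part,

    M_eff = sum_i [ 1{|l_i| >= 1} + (|l_i| - floor(|l_i|)) ],

and the per-test significance level becomes alpha / M_eff.

A metabolite ratio is only biologically interesting when it strengthens the
association beyond its two component concentrations.  The P-gain,

    p_gain = min(p_numerator, p_denominator) / p_ratio,

quantifies that improvement; a conservative critical value is the number of
metabolites on the panel (151 for a Biocrates p150-style panel).  The final
significance gate requires both p < alpha/M_eff and p_gain > critical,
strictly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MeffResult:
    """Li-Ji spectral estimate of the effective number of tests."""

    m: int
    eigenvalues: np.ndarray
    m_eff: float

    def threshold(self, alpha: float = 0.05) -> float:
        return significance_threshold(alpha, self.m_eff)


@dataclass(frozen=True)
class PGainRecord:
    p_ratio: float
    p_numerator: float
    p_denominator: float
    p_gain: float


def _li_ji_from_eigenvalues(eigenvalues: np.ndarray) -> float:
    lam = np.abs(np.asarray(eigenvalues, dtype=float))
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def li_ji_meff(correlation: np.ndarray) -> MeffResult:
    """M_eff from a phenotype correlation matrix (symmetric, unit diagonal)."""
    corr = np.asarray(correlation, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have a unit diagonal")
    eigenvalues = np.linalg.eigvalsh(corr)
    return MeffResult(corr.shape[0], eigenvalues, _li_ji_from_eigenvalues(eigenvalues))


def meff_from_data(matrix: np.ndarray) -> MeffResult:
    """M_eff straight from an individuals x phenotypes matrix.

    The correlation-matrix eigenvalues are recovered from the singular
    values of the standardized data (eigenvalues = s^2/(n-1), padded with
    zeros up to the number of phenotypes), which is exact and avoids
    materializing an m x m matrix for m in the tens of thousands.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    Z = X - X.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant phenotypes have no correlation structure")
    Z = Z / sd
    svals = np.linalg.svd(Z, compute_uv=False)
    eigenvalues = np.zeros(m)
    eigenvalues[: len(svals)] = svals**2 / (n - 1)
    return MeffResult(m, eigenvalues, _li_ji_from_eigenvalues(eigenvalues))


def significance_threshold(alpha: float, m_eff: float) -> float:
    """Per-test significance level alpha / M_eff."""
    if m_eff < 1:
        raise ValueError("M_eff must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m_eff


def p_gain(p_num: float, p_den: float, p_ratio: float) -> PGainRecord:
    """P-gain of a ratio association over its component concentrations."""
    for p in (p_num, p_den, p_ratio):
        if not 0 < p <= 1:
            raise ValueError("p-values must lie in (0, 1]")
    return PGainRecord(p_ratio, p_num, p_den, min(p_num, p_den) / p_ratio)


def add_p_gain(results: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``p_gain`` column to a scan table.

    Ratio rows get min(p of numerator single, p of denominator single) /
    p of the ratio, matched within the same position; single rows get NaN.
    """
    singles = results[results["kind"] == "single"]
    lookup = singles.set_index(["position", "phenotype"])["p"]
    out = results.copy()
    out["p_gain"] = np.nan
    is_ratio = out["kind"] == "ratio"
    num_p = lookup.reindex(
        pd.MultiIndex.from_arrays([out.loc[is_ratio, "position"], out.loc[is_ratio, "numerator"]])
    ).to_numpy()
    den_p = lookup.reindex(
        pd.MultiIndex.from_arrays([out.loc[is_ratio, "position"], out.loc[is_ratio, "denominator"]])
    ).to_numpy()
    out.loc[is_ratio, "p_gain"] = np.minimum(num_p, den_p) / out.loc[is_ratio, "p"].to_numpy()
    return out


def apply_significance_gate(
    results: pd.DataFrame, threshold: float, p_gain_critical: float
) -> pd.DataFrame:
    """Flag rows significant iff p < threshold AND p_gain > critical (both
    strict).  Rows without a P-gain (singles, failed fits) are never
    significant."""
    out = results.copy()
    p = out["p"].to_numpy(dtype=float)
    pg = out["p_gain"].to_numpy(dtype=float) if "p_gain" in out else np.full(len(out), np.nan)
    with np.errstate(invalid="ignore"):
        out["significant"] = (p < threshold) & (pg > p_gain_critical)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out
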