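"""The inverted regression scan.

Instead of the usual GWAS orientation, the genetic quantity is the
response: for position i and individual k the phenotype is the heteroplasmy
log-ratio

    y_ik = log2((B_ik + 2) / (A_ik + 2)),

where A is the reference-allele read count and B the count of the
cohort-wide second most frequent allele; the pseudocount of 2 keeps the
logarithm finite for individuals carrying only the reference allele and is
negligible at ~3500x coverage.  Each metabolite ratio MR_j (and, for the
P-gain, each single metabolite) enters as predictor in

    y_ik = b0 + b1 MR_jk + b2 age_k + b3 sex_k + b4 Cov_ik + b5 batch_k + e,

fit by ordinary least squares with the total coverage Cov_ik = A+B and the
sequencing plate (one-hot, first level as reference) as nuisance terms.
P-values are two-sided Wald tests using the asymptotic normal distribution
of b1/SE(b1).

``fit_inverted_model`` fits a single model via statsmodels;
``run_scan`` evaluates all positions x phenotypes through a
Frisch-Waugh-Lovell decomposition: covariates shared across positions are
projected out once, the position-specific coverage column once per
position, after which every phenotype reduces to a univariate fit.  The two
routes agree to numerical precision (a tested invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .counts import AlleleCountTensor
from .metab_qc import MetabolitePanel, RatioIndex
from .seq_qc import PositionAlleles

#: median of the chi-square distribution with one degree of freedom
CHI2_1_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class AssociationResult:
    """One fitted (position, phenotype) pair."""

    position: int
    phenotype_id: str
    beta: float
    se: float
    z: float
    p: float
    n_used: int


def heteroplasmy_logratio(A, B, pseudocount: float = 2.0):
    """y = log2((B + pseudocount) / (A + pseudocount)) for read counts A, B.

    Antisymmetric under swapping A and B; zero when A == B.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(A < 0) or np.any(B < 0):
        raise ValueError("read counts must be non-negative")
    out = np.log2((B + pseudocount) / (A + pseudocount))
    return out if out.ndim else float(out)


def build_heteroplasmy(
    tensor: AlleleCountTensor,
    alleles: list[PositionAlleles],
    pseudocount: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Response matrix y (individuals x positions) and total coverage A+B."""
    ref = np.array([a.ref_base for a in alleles])
    alt = np.array([a.alt_base for a in alleles])
    a_counts = tensor.base_plane(ref)
    b_counts = tensor.base_plane(alt)
    y = heteroplasmy_logratio(a_counts, b_counts, pseudocount)
    return y, (a_counts + b_counts).astype(float)


def _shared_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept, age, sex and one-hot batch contrasts (first level dropped);
    constant columns other than the intercept are removed."""
    n = len(covariates)
    cols = [np.ones(n)]
    names = ["const"]
    for c in ("age", "sex"):
        cols.append(covariates[c].to_numpy(dtype=float))
        names.append(c)
    batch = pd.get_dummies(covariates["batch"], prefix="batch", drop_first=True)
    for c in batch.columns:
        cols.append(batch[c].to_numpy(dtype=float))
        names.append(str(c))
    X = np.column_stack(cols)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.ptp(X[:, j]) > 0]
    return X[:, keep], [names[j] for j in keep]


def fit_inverted_model(
    y: np.ndarray,
    mr: np.ndarray,
    covariates: pd.DataFrame,
    coverage: np.ndarray,
    position: int = 0,
    phenotype_id: str = "MR",
) -> AssociationResult:
    """OLS fit of the inverted model for one (position, phenotype) pair.

    Raises on a constant predictor; redundant covariate contrasts (constant
    coverage, collinear batch dummies) are dropped before fitting so the
    reported degrees of freedom stay honest.
    """
    y = np.asarray(y, dtype=float)
    mr = np.asarray(mr, dtype=float)
    if np.ptp(mr) == 0:
        raise ValueError("constant metabolite predictor: degenerate design")
    X_shared, names = _shared_design(covariates)
    cols = [mr, X_shared[:, 0]] + [X_shared[:, j] for j in range(1, X_shared.shape[1])]
    names = ["MR"] + names
    cov = np.asarray(coverage, dtype=float)
    if np.ptp(cov) > 0:
        cols.append(cov)
        names.append("Cov")
    X = np.column_stack(cols)
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("not enough complete rows for the design")
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(position, phenotype_id, beta, se, z, max(p, np.nextafter(0, 1)), len(y))


def _residualize(Z: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return Z - Q @ (Q.T @ Z)


def run_scan(
    tensor: AlleleCountTensor,
    alleles: list[PositionAlleles],
    ratio_index: list[RatioIndex],
    ratios: pd.DataFrame,
    singles: MetabolitePanel,
    covariates: pd.DataFrame,
    pseudocount: float = 2.0,
) -> pd.DataFrame:
    """Fit every retained position against every metabolite ratio and every
    single metabolite (singles are required downstream for the P-gain).

    Returns one row per fit with columns position, phenotype, kind
    ('ratio'/'single'), numerator, denominator, beta, se, z, p, n.
    Degenerate fits (zero-variance predictor after covariate projection)
    yield NaN statistics and ``kind`` suffixed ledger notes rather than
    silent omission.

    Individuals are aligned on the tensor's ordering; the phenotype tables
    and covariates must be indexed by the same ids (complete cases: QC and
    imputation run upstream).
    """
    ids = list(tensor.individuals)
    ratios = ratios.loc[ids]
    single_values = singles.values.loc[ids]
    covariates = covariates.loc[ids]
    if single_values.isna().to_numpy().any():
        raise ValueError("single-metabolite phenotypes must be complete (impute first)")

    Y, coverage = build_heteroplasmy(tensor, alleles, pseudocount)
    X_shared, _ = _shared_design(covariates)
    n, p0 = X_shared.shape
    Q, _ = np.linalg.qr(X_shared)

    phen = np.column_stack([ratios.to_numpy(dtype=float), single_values.to_numpy(dtype=float)])
    meta = [(r.phenotype_id, "ratio", r.numerator, r.denominator) for r in ratio_index] + [
        (m, "single", m, "") for m in single_values.columns
    ]

    R_P = _residualize(phen, Q)  # phenotypes, shared covariates projected out
    R_Y = _residualize(Y, Q)
    R_C = _residualize(coverage, Q)

    PP = np.einsum("ij,ij->j", R_P, R_P)  # ||phenotype residual||^2
    PY = R_P.T @ R_Y  # (m_total, s)
    PC = R_P.T @ R_C  # (m_total, s)
    CC = np.einsum("ij,ij->j", R_C, R_C)  # (s,)
    CY = np.einsum("ij,ij->j", R_C, R_Y)  # (s,)
    YY = np.einsum("ij,ij->j", R_Y, R_Y)  # (s,)

    # project the position-specific coverage column out of phenotype and y
    cov_ok = CC > 1e-10 * max(1.0, float(np.abs(coverage).max()) ** 2)
    safe_CC = np.where(cov_ok, CC, 1.0)
    num = PY - np.where(cov_ok, PC * (CY / safe_CC), 0.0)  # (m, s)
    den = PP[:, None] - np.where(cov_ok, PC**2 / safe_CC, 0.0)  # (m, s)
    yty = YY - np.where(cov_ok, CY**2 / safe_CC, 0.0)  # (s,)
    df = n - p0 - 1 - cov_ok.astype(int)  # minus phenotype, minus coverage if used

    tol = np.maximum(PP[:, None], 1.0) * 1e-12
    ok = den > tol
    den_safe = np.where(ok, den, np.nan)
    beta = num / den_safe
    rss = np.maximum(yty[None, :] - num**2 / den_safe, 0.0)
    sigma2 = rss / np.maximum(df[None, :], 1)
    se = np.sqrt(sigma2 / den_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)
    pvals[~ok] = np.nan

    s = tensor.n_positions
    m_total = phen.shape[1]
    out = pd.DataFrame(
        {
            "position": np.repeat(tensor.positions, m_total),
            "phenotype": np.tile([mm[0] for mm in meta], s),
            "kind": np.tile([mm[1] for mm in meta], s),
            "numerator": np.tile([mm[2] for mm in meta], s),
            "denominator": np.tile([mm[3] for mm in meta], s),
            "beta": beta.T.reshape(-1),
            "se": se.T.reshape(-1),
            "z": z.T.reshape(-1),
            "p": pvals.T.reshape(-1),
            "n": n,
        }
    )
    return out


def genomic_lambda(pvalues) -> float:
    """Genomic-control inflation factor: the median association chi-square
    statistic divided by the chi-square(1 df) median (~0.4549)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("genomic lambda needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)
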