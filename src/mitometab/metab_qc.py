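"""Metabolite-side quality control (QC step 2).

The serum panel (Biocrates-style targeted metabolomics, concentrations in
uM-like units) goes through: a completeness filter (metabolites need at
least 80% non-missing values), masking of extreme values (more than three
standard deviations off the per-metabolite mean), chained-equation
imputation with predictive mean matching (PMM), and exhaustive enumeration
of the N(N-1)/2 pairwise concentration ratios that serve as phenotypes for
the inverted scan.

Masked outliers are re-imputed, so downstream stages always see one
complete, strictly positive matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METABOLITE_CLASSES = (
    "hexose",
    "acylcarnitine",
    "amino acid",
    "sphingolipid",
    "glycerophospholipid",
)


@dataclass
class MetabolitePanel:
    """Individuals x metabolites concentration matrix.

    ``values`` holds observed concentrations with NaN marking missing
    entries; ``metadata`` is indexed by metabolite short name and carries at
    least a ``class`` column.  ``complete`` optionally stores the latent
    noise-free matrix a simulator generated before masking (ground truth for
    tests; never consumed by the QC itself).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    complete: pd.DataFrame | None = None
    outlier_cells: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        obs = self.values.to_numpy(dtype=float)
        if np.any(obs[np.isfinite(obs)] <= 0):
            raise ValueError("observed concentrations must be strictly positive")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def observed_fraction(self) -> pd.Series:
        return self.values.notna().mean(axis=0)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "MetabolitePanel":
        return MetabolitePanel(
            self.values.copy(),
            self.metadata.copy(),
            None if self.complete is None else self.complete.copy(),
            list(self.outlier_cells),
        )

    def select_individuals(self, ids) -> "MetabolitePanel":
        return MetabolitePanel(
            self.values.loc[ids],
            self.metadata,
            None if self.complete is None else self.complete.loc[ids],
            list(self.outlier_cells),
        )

    # -- I/O ---------------------------------------------------------------
    def write_csv(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path, index_label="individual_id")
        self.metadata.to_csv(metadata_path, index_label="metabolite")

    @classmethod
    def read_csv(cls, values_path, metadata_path) -> "MetabolitePanel":
        values = pd.read_csv(values_path, index_col="individual_id")
        metadata = pd.read_csv(metadata_path, index_col="metabolite")
        return cls(values, metadata.loc[values.columns])


@dataclass(frozen=True)
class RatioIndex:
    """One unordered metabolite pair, oriented by panel column order:
    the earlier column is the numerator."""

    numerator: str
    denominator: str
    phenotype_id: str


def apply_completeness_filter(
    panel: MetabolitePanel, min_fraction: float = 0.8
) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Drop metabolites observed in less than ``min_fraction`` of
    individuals (at least 80% non-missing required; exactly 80% is kept)."""
    if panel.n_metabolites == 0 or panel.n_individuals == 0:
        raise ValueError("empty metabolite panel")
    frac = panel.observed_fraction()
    keep = frac >= min_fraction
    report = pd.DataFrame(
        {"metabolite": frac.index, "observed_fraction": frac.to_numpy(), "kept": keep.to_numpy()}
    )
    kept_cols = frac.index[keep]
    filtered = MetabolitePanel(
        panel.values[kept_cols],
        panel.metadata.loc[kept_cols],
        None if panel.complete is None else panel.complete[kept_cols],
        [c for c in panel.outlier_cells if c[1] in set(kept_cols)],
    )
    return filtered, report


def mask_outliers(
    panel: MetabolitePanel, k_sd: float = 3.0
) -> tuple[MetabolitePanel, pd.DataFrame]:
    """Set observed values lying more than ``k_sd`` standard deviations off
    the per-metabolite mean (both computed on observed values) to missing.

    Constant metabolites (zero SD) mask nothing; the strict ``>`` keeps a
    value at exactly k_sd.
    """
    values = panel.values.copy()
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        z = (values - mean).abs() / sd.replace(0.0, np.nan)
    mask = z > k_sd
    rows, cols = np.nonzero(mask.to_numpy())
    report = pd.DataFrame(
        {
            "individual_id": values.index[rows],
            "metabolite": values.columns[cols],
            "value": values.to_numpy()[rows, cols],
        }
    )
    values = values.mask(mask)
    masked = MetabolitePanel(values, panel.metadata, panel.complete, list(panel.outlier_cells))
    return masked, report


def impute_pmm(
    panel: MetabolitePanel,
    n_iterations: int = 10,
    n_donors: int = 5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MetabolitePanel:
    """Chained-equation imputation with predictive mean matching.

    Each incomplete metabolite is cyclically regressed (OLS) on all other
    metabolites using its originally observed rows; every missing entry then
    receives the observed value of one of the ``n_donors`` donors whose
    fitted means are closest to its own fitted mean, drawn at random.
    Because donors are observed values, imputations always lie inside the
    observed support, preserving positivity.  One completed panel is
    returned (single imputation); the result is deterministic under a fixed
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    values = panel.values.to_numpy(dtype=float).copy()
    n, m = values.shape
    miss = np.isnan(values)
    n_obs = (~miss).sum(axis=0)
    if np.any(n_obs < 2):
        bad = panel.values.columns[n_obs < 2].tolist()
        raise ValueError(f"metabolites with <2 observed values cannot be imputed: {bad}")
    if not miss.any():
        return panel.copy()

    # initialize missing entries with random observed draws per column
    filled = values.copy()
    for j in np.nonzero(miss.any(axis=0))[0]:
        obs_vals = values[~miss[:, j], j]
        filled[miss[:, j], j] = rng.choice(obs_vals, size=miss[:, j].sum(), replace=True)

    incomplete = np.nonzero(miss.any(axis=0))[0]
    for _ in range(n_iterations):
        for j in incomplete:
            obs_rows = ~miss[:, j]
            mis_rows = miss[:, j]
            X = np.delete(filled, j, axis=1)
            X = np.column_stack([np.ones(n), X])
            beta, *_ = np.linalg.lstsq(X[obs_rows], values[obs_rows, j], rcond=None)
            pred = X @ beta
            pred_obs = pred[obs_rows]
            obs_vals = values[obs_rows, j]
            k = min(n_donors, len(obs_vals))
            dist = np.abs(pred[mis_rows][:, None] - pred_obs[None, :])
            donor_idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
            # tie-stable: order the k candidates by (distance, index)
            order = np.argsort(dist[np.arange(dist.shape[0])[:, None], donor_idx], axis=1, kind="stable")
            donor_idx = donor_idx[np.arange(dist.shape[0])[:, None], order]
            pick = rng.integers(0, k, size=donor_idx.shape[0])
            filled[mis_rows, j] = obs_vals[donor_idx[np.arange(donor_idx.shape[0]), pick]]

    completed = pd.DataFrame(filled, index=panel.values.index, columns=panel.values.columns)
    return MetabolitePanel(completed, panel.metadata, panel.complete, list(panel.outlier_cells))


def enumerate_ratios(
    panel: MetabolitePanel, log2: bool = False
) -> tuple[list[RatioIndex], pd.DataFrame]:
    """All N(N-1)/2 pairwise concentration ratios as phenotypes.

    Pairs follow panel column order with the earlier column as numerator;
    in log2 mode the phenotype is log2(numerator/denominator), so swapping
    the orientation negates it.  Requires a completed (no-missing) panel.
    """
    if panel.n_missing():
        raise ValueError("ratio enumeration requires a completed panel (no missing values)")
    cols = list(panel.values.columns)
    values = panel.values.to_numpy(dtype=float)
    pairs = list(itertools.combinations(range(len(cols)), 2))
    index: list[RatioIndex] = []
    data = np.empty((values.shape[0], len(pairs)))
    for p, (i, j) in enumerate(pairs):
        pid = f"{cols[i]}/{cols[j]}"
        index.append(RatioIndex(cols[i], cols[j], pid))
        data[:, p] = values[:, i] / values[:, j]
    if log2:
        data = np.log2(data)
    ratios = pd.DataFrame(data, index=panel.values.index, columns=[r.phenotype_id for r in index])
    return index, ratios
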