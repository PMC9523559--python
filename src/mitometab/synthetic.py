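"""Synthetic cohorts with the statistical structure the scan assumes.

The study population (a German population-based cohort with whole-mtDNA
sequencing at ~3500x mean coverage and a 151-metabolite targeted serum
panel) is not publicly deposited, so this module generates cohorts that
reproduce the features the analysis relies on:

* per-position read counts with Poisson coverage around a 3500x mean,
  per-individual library-size variation, heteroplasmic minor-allele
  fractions reaching down to the 0.007 calling floor, and homoplasmic
  positions carrying no minor reads;
* a positive, log-normal metabolite panel with block correlation,
  missing-at-random entries and injected outliers, with a Biocrates-like
  class mix (hexose, acylcarnitines, amino acids, sphingomyelins,
  glycerophospholipids);
* causal positions whose log2 heteroplasmy odds depend linearly on a
  chosen metabolite ratio, so the inverted regression's b1 is a true,
  recoverable parameter;
* exact-count QC fixtures reproducing the study's exclusion arithmetic.

All randomness flows from one master seed; per-stage streams are derived
deterministically so, e.g., regenerating metabolites does not perturb the
count draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import BASES, GENOME_LENGTH, AlleleCountTensor
from .metab_qc import MetabolitePanel
from .seq_qc import (
    BLACKLIST_POSITIONS,
    PHANTOM_POSITIONS,
    PRIMER_REGION,
    REFERENCE_GAPS,
)

_STAGES = {"covariates": 1, "metabolites": 2, "counts": 3, "fixture": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible stream for one generation stage."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGES[stage])))


@dataclass(frozen=True)
class CausalEffect:
    """A planted association: the log2 heteroplasmy odds at ``position``
    increase by ``beta`` per unit of the (centered) ratio
    numerator/denominator."""

    position: int
    numerator: str
    denominator: str
    beta: float

    @property
    def phenotype_id(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters; defaults mirror the emulated study.

    ``mean_coverage`` (reads) and the metabolite count follow the study
    design; ``baseline_logit`` is the log2-odds of the minor-allele
    fraction at heteroplasmic sites (the study does not report the
    heteroplasmy distribution, so this is a free parameter), ``noise_sd``
    the residual spread of the log2 heteroplasmy ratio, ``position_sd``
    the across-position spread of baseline heteroplasmy levels.
    """

    n_individuals: int = 1163
    n_metabolites: int = 151
    n_positions: int = GENOME_LENGTH
    mean_coverage: float = 3500.0
    block_correlation: float = 0.5
    block_size: int = 5
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    causal_effects: tuple[CausalEffect, ...] = ()
    baseline_logit: float = -2.5
    noise_sd: float = 1.0
    position_sd: float = 0.75
    batch_count: int = 4
    batch_effect_sd: float = 0.1
    homoplasmic_fraction: float = 0.43
    coverage_log_sd: float = 0.15
    log_conc_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_metabolites", "n_positions", "batch_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("missing_rate", "outlier_rate", "homoplasmic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        for eff in self.causal_effects:
            if not 1 <= eff.position <= self.n_positions:
                raise ValueError(f"causal position {eff.position} outside [1, {self.n_positions}]")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    true_betas: dict[tuple[int, str], float]
    true_theta: np.ndarray  # (n_individuals, n_positions) minor fractions
    homoplasmic_positions: np.ndarray
    reference: str


@dataclass(frozen=True)
class QCFixtureSpec:
    """Exact-count specification of a sequencing-QC fixture; defaults are
    the study's printed accounting (3021 individuals, 37 contaminated,
    8 low-coverage, 213 diabetic; 49 primer + 1 gap + 3 phantom + 5
    blacklist + 233 low-coverage + 7106 homoplasmic positions)."""

    n_total: int = 3021
    n_contaminated: int = 37
    n_low_coverage_individuals: int = 8
    n_diabetic: int = 213
    n_lowcov_positions: int = 233
    n_homoplasmic_positions: int = 7106
    genome_length: int = GENOME_LENGTH

    def __post_init__(self) -> None:
        if self.n_contaminated + self.n_low_coverage_individuals + self.n_diabetic > self.n_total:
            raise ValueError("individual flag groups exceed the cohort size")
        fixed = len(self.fixed_positions())
        if fixed + self.n_lowcov_positions + self.n_homoplasmic_positions > self.genome_length:
            raise ValueError("position flag groups exceed the genome length")

    def fixed_positions(self) -> set[int]:
        lo, hi = PRIMER_REGION
        fixed = set(range(lo, hi + 1)) | set(REFERENCE_GAPS) | set(PHANTOM_POSITIONS)
        fixed |= set(BLACKLIST_POSITIONS)
        return {p for p in fixed if p <= self.genome_length}


# ---------------------------------------------------------------------------
# metabolite panel
# ---------------------------------------------------------------------------

_AMINO_ACIDS = (
    "Ala", "Arg", "Gln", "Gly", "His", "Met", "Orn",
    "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "xLeu",
)


def _acylcarnitine_names():
    for chain in (0, 2, 3, 4, 5, 6, 8, 9, 10, 12, 14, 16, 18):
        yield f"C{chain}"
        yield f"C{chain}:1"
        yield f"C{chain}-OH"


def _sphingomyelin_names():
    for chain in (16, 18, 20, 22, 24, 26):
        yield f"SM C{chain}:0"
        yield f"SM C{chain}:1"
    for chain in (14, 16, 22, 24):
        yield f"SM (OH) C{chain}:1"


def _glycerophospholipid_names():
    for kind in ("aa", "ae"):
        for chain in range(28, 45, 2):
            for sat in range(0, 7):
                yield f"PC {kind} C{chain}:{sat}"
    for chain in range(14, 29, 2):
        yield f"lysoPC a C{chain}:0"


def panel_metadata(n_metabolites: int) -> pd.DataFrame:
    """Short names and class labels for a synthetic panel, with a class mix
    proportional to the Biocrates p150 composition (1 hexose, 35
    acylcarnitines, 14 amino acids, 14 sphingomyelins, 87
    glycerophospholipids at N=151)."""
    mix = (
        ("hexose", 1, ["H1"]),
        ("acylcarnitine", 35, list(_acylcarnitine_names())),
        ("amino acid", 14, list(_AMINO_ACIDS)),
        ("sphingolipid", 14, list(_sphingomyelin_names())),
        ("glycerophospholipid", 87, list(_glycerophospholipid_names())),
    )
    total_ref = sum(m[1] for m in mix)
    names: list[str] = []
    classes: list[str] = []
    counts = [max(0, round(n_metabolites * m[1] / total_ref)) for m in mix]
    counts[-1] += n_metabolites - sum(counts)  # absorb rounding in the largest class
    for (cls, _, pool), k in zip(mix, counts):
        for i in range(k):
            name = pool[i] if i < len(pool) else f"{cls[:3].upper()}{i + 1}"
            names.append(name)
            classes.append(cls)
    return pd.DataFrame({"class": classes}, index=pd.Index(names, name="metabolite"))


def simulate_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Age, sex, sequencing plate and (clean) QC flags per individual."""
    rng = stage_rng(config.seed, "covariates")
    n = config.n_individuals
    ids = [f"ind{k:05d}" for k in range(1, n + 1)]
    batch = rng.permutation(np.arange(n) % config.batch_count)
    return pd.DataFrame(
        {
            "age": rng.uniform(32.0, 81.0, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "batch": batch,
            "contaminated": np.zeros(n, dtype=bool),
            "diabetes": np.zeros(n, dtype=bool),
        },
        index=pd.Index(ids, name="individual_id"),
    )


def simulate_metabolites(config: SimulationConfig) -> MetabolitePanel:
    """Log-normal concentrations with within-block equicorrelation, MCAR
    missingness and injected >3-SD outliers.

    Blocks are consecutive runs of ``block_size`` metabolites within a
    class, sharing one latent factor with loading sqrt(rho) and one log
    scale, which mirrors the strong within-class correlation of targeted
    panels.  The pre-masking matrix is kept on the panel (``complete``) as
    simulation ground truth.
    """
    rng = stage_rng(config.seed, "metabolites")
    n, m = config.n_individuals, config.n_metabolites
    meta = panel_metadata(m)
    ids = [f"ind{k:05d}" for k in range(1, n + 1)]

    # block structure: consecutive within class
    blocks: list[int] = []
    b = -1
    prev_cls, run = None, 0
    for cls in meta["class"]:
        if cls != prev_cls or run >= config.block_size:
            b += 1
            run = 0
            prev_cls = cls
        blocks.append(b)
        run += 1
    blocks_arr = np.array(blocks)
    n_blocks = b + 1

    rho = config.block_correlation
    factors = rng.normal(size=(n, n_blocks))
    eps = rng.normal(size=(n, m))
    z = np.sqrt(rho) * factors[:, blocks_arr] + np.sqrt(1.0 - rho) * eps
    mu_block = rng.uniform(np.log(10.0), np.log(100.0), size=n_blocks)
    mu = mu_block[blocks_arr] + rng.uniform(-0.2, 0.2, size=m)
    conc = np.exp(mu[None, :] + config.log_conc_sd * z)

    complete = pd.DataFrame(conc, index=pd.Index(ids, name="individual_id"), columns=meta.index)
    values = complete.copy()

    # outliers injected after the correlation structure is in place
    outlier_cells: list[tuple] = []
    n_out = int(round(config.outlier_rate * n * m))
    if n_out:
        flat = rng.choice(n * m, size=n_out, replace=False)
        rows, cols = np.unravel_index(flat, (n, m))
        col_mean = conc.mean(axis=0)
        col_sd = conc.std(axis=0, ddof=1)
        mags = rng.uniform(3.5, 6.0, size=n_out)
        signs = rng.choice([-1.0, 1.0], size=n_out)
        for r, c, mag, sign in zip(rows, cols, mags, signs):
            val = col_mean[c] + sign * mag * col_sd[c]
            if val <= 0:
                val = col_mean[c] + mag * col_sd[c]
            values.iloc[r, c] = val
            outlier_cells.append((ids[r], meta.index[c]))

    if config.missing_rate > 0:
        mask = rng.random(size=(n, m)) < config.missing_rate
        values = values.mask(pd.DataFrame(mask, index=values.index, columns=values.columns))

    return MetabolitePanel(values, meta, complete=complete, outlier_cells=outlier_cells)


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def _generative_ratio(panel: MetabolitePanel, effect: CausalEffect) -> np.ndarray:
    source = panel.complete if panel.complete is not None else panel.values.fillna(panel.values.mean())
    for name in (effect.numerator, effect.denominator):
        if name not in source.columns:
            raise KeyError(f"causal ratio references unknown metabolite {name!r}")
    return (source[effect.numerator] / source[effect.denominator]).to_numpy(dtype=float)


def simulate_counts(
    config: SimulationConfig,
    panel: MetabolitePanel,
    covariates: pd.DataFrame,
) -> tuple[AlleleCountTensor, CohortTruth]:
    """Draw the allele-count tensor from the inverted model run forwards.

    Per heteroplasmic position the minor-allele fraction is
    theta = inverse-log2-odds(baseline + position shift + batch shift
    + b1 * centered MR + noise); coverage is Poisson around the mean
    coverage scaled by a log-normal per-individual library factor;
    B ~ Binomial(coverage, theta), A = coverage - B, and the two remaining
    bases stay at zero.  Homoplasmic positions have theta = 0 exactly.
    """
    if not panel.values.index.equals(covariates.index):
        raise ValueError("panel and covariates must share individual identifiers")
    rng = stage_rng(config.seed, "counts")
    n, s = config.n_individuals, config.n_positions
    positions = np.arange(1, s + 1)
    causal_pos = {e.position for e in config.causal_effects}

    # which positions are homoplasmic (never the causal ones)
    candidates = positions[~np.isin(positions, sorted(causal_pos))]
    n_homo = min(int(round(config.homoplasmic_fraction * s)), len(candidates))
    homoplasmic = np.sort(rng.choice(candidates, size=n_homo, replace=False))

    eta = np.empty((n, s))
    eta[:] = config.baseline_logit
    eta += rng.normal(0.0, config.position_sd, size=s)[None, :]
    batch_shift = rng.normal(0.0, config.batch_effect_sd, size=config.batch_count)
    eta += batch_shift[covariates["batch"].to_numpy()][:, None]
    eta += rng.normal(0.0, config.noise_sd, size=(n, s))

    true_betas: dict[tuple[int, str], float] = {}
    for eff in config.causal_effects:
        mr = _generative_ratio(panel, eff)
        eta[:, eff.position - 1] += eff.beta * (mr - mr.mean())
        true_betas[(eff.position, eff.phenotype_id)] = eff.beta

    theta = np.exp2(eta)
    theta /= 1.0 + theta
    np.clip(theta, 0.0, 0.999, out=theta)
    theta[:, homoplasmic - 1] = 0.0

    lib = np.exp(rng.normal(-config.coverage_log_sd**2 / 2, config.coverage_log_sd, size=n))
    coverage = rng.poisson(config.mean_coverage * lib[:, None], size=(n, s))
    b_counts = rng.binomial(coverage, theta)
    a_counts = coverage - b_counts

    ref_idx = rng.integers(0, 4, size=s)
    alt_idx = (ref_idx + rng.integers(1, 4, size=s)) % 4

    dtype = np.uint16 if coverage.max(initial=0) < np.iinfo(np.uint16).max else np.int32
    counts = np.zeros((n, s, 4), dtype=dtype)
    pos_ix = np.arange(s)
    counts[:, pos_ix, ref_idx] = a_counts.astype(dtype)
    counts[:, pos_ix, alt_idx] = b_counts.astype(dtype)

    reference = "".join(BASES[i] for i in ref_idx)
    if s >= 3107:  # mimic the rCRS gap at mt3107
        reference = reference[:3106] + "N" + reference[3107:]

    tensor = AlleleCountTensor(covariates.index.to_numpy(), positions, counts)
    truth = CohortTruth(true_betas, theta, homoplasmic, reference)
    return tensor, truth


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    covariates: pd.DataFrame
    panel: MetabolitePanel
    tensor: AlleleCountTensor
    truth: CohortTruth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Covariates, metabolite panel and allele counts in one call."""
    covariates = simulate_covariates(config)
    panel = simulate_metabolites(config)
    tensor, truth = simulate_counts(config, panel, covariates)
    return SyntheticCohort(config, covariates, panel, tensor, truth)


# ---------------------------------------------------------------------------
# exact-count QC fixture
# ---------------------------------------------------------------------------


@dataclass
class QCFixture:
    tensor: AlleleCountTensor
    covariates: pd.DataFrame
    reference: str
    expected: dict


def make_qc_fixture(spec: QCFixtureSpec = QCFixtureSpec(), seed: int = 0) -> QCFixture:
    """A cohort whose QC accounting matches ``spec`` exactly.

    Flags are realized in the data itself: contaminated/diabetic status in
    the covariate table, low-coverage individuals as a 500x mean, low-
    coverage positions as a 900x cohort mean, homoplasmic positions as
    all-reference read counts (minor fraction 0 < 0.007 everywhere) and
    heteroplasmic ones at a 1% minor fraction.  Flag groups are pairwise
    disjoint by construction.
    """
    rng = stage_rng(seed, "fixture")
    n, s = spec.n_total, spec.genome_length
    positions = np.arange(1, s + 1)
    ids = np.array([f"ind{k:05d}" for k in range(1, n + 1)])

    order = rng.permutation(n)
    contaminated_ix = order[: spec.n_contaminated]
    lowcov_ix = order[spec.n_contaminated : spec.n_contaminated + spec.n_low_coverage_individuals]
    diab_lo = spec.n_contaminated + spec.n_low_coverage_individuals
    diabetic_ix = order[diab_lo : diab_lo + spec.n_diabetic]

    covariates = pd.DataFrame(
        {
            "age": rng.uniform(32.0, 81.0, size=n).round(1),
            "sex": rng.integers(0, 2, size=n),
            "batch": np.arange(n) % 8,
            "contaminated": np.zeros(n, dtype=bool),
            "diabetes": np.zeros(n, dtype=bool),
        },
        index=pd.Index(ids, name="individual_id"),
    )
    covariates.iloc[contaminated_ix, covariates.columns.get_loc("contaminated")] = True
    covariates.iloc[diabetic_ix, covariates.columns.get_loc("diabetes")] = True

    fixed = spec.fixed_positions()
    pool = positions[~np.isin(positions, sorted(fixed))]
    pool = rng.permutation(pool)
    lowcov_pos = np.sort(pool[: spec.n_lowcov_positions])
    homo_pos = np.sort(
        pool[spec.n_lowcov_positions : spec.n_lowcov_positions + spec.n_homoplasmic_positions]
    )

    coverage = np.full((n, s), 3500, dtype=np.int32)
    coverage[lowcov_ix, :] = 500
    coverage[:, lowcov_pos - 1] = 900
    b_counts = np.round(coverage * 0.01).astype(np.int32)  # 1% minor fraction
    b_counts[:, homo_pos - 1] = 0

    counts = np.zeros((n, s, 4), dtype=np.uint16)
    counts[:, :, BASES.index("G")] = (coverage - b_counts).astype(np.uint16)
    counts[:, :, BASES.index("A")] = b_counts.astype(np.uint16)

    reference = "G" * s
    for gap in REFERENCE_GAPS:
        if gap <= s:
            reference = reference[: gap - 1] + "N" + reference[gap:]

    tensor = AlleleCountTensor(ids, positions, counts)
    expected = {
        "contaminated": set(ids[contaminated_ix]),
        "low_coverage_individuals": set(ids[lowcov_ix]),
        "diabetic": set(ids[diabetic_ix]),
        "lowcov_positions": set(int(p) for p in lowcov_pos),
        "homoplasmic_positions": set(int(p) for p in homo_pos),
        "n_individuals_retained": n
        - spec.n_contaminated
        - spec.n_low_coverage_individuals
        - spec.n_diabetic,
        "n_positions_retained": s
        - len(fixed)
        - spec.n_lowcov_positions
        - spec.n_homoplasmic_positions,
    }
    return QCFixture(tensor, covariates, reference, expected)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------


def write_fasta(path, sequence: str, name: str = "synthetic_mt") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def write_cohort(outdir, cohort: SyntheticCohort) -> dict:
    """Write counts (long TSV), covariates, metabolite panel + metadata and
    the reference FASTA; returns the path map."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "covariates": out / "covariates.csv",
        "metabolites": out / "metabolites.csv",
        "metabolite_metadata": out / "metabolite_metadata.csv",
        "reference": out / "reference.fasta",
        "config": out / "simulation.yaml",
    }
    cohort.tensor.write_tsv(paths["counts"])
    cohort.covariates.to_csv(paths["covariates"], index_label="individual_id")
    cohort.panel.write_csv(paths["metabolites"], paths["metabolite_metadata"])
    write_fasta(paths["reference"], cohort.truth.reference)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cohort.config).items()
        if k != "causal_effects"
    }
    cfg["causal_effects"] = [vars(e) for e in cohort.config.causal_effects]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh)
    return {k: str(v) for k, v in paths.items()}
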