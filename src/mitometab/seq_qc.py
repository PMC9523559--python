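"""Sequencing-side quality control (QC step 1).

Individuals are excluded for DNA contamination, low overall mean coverage
(<1000x) or a type-2-diabetes diagnosis; positions are excluded for falling
in the PCR primer region (rCRS 16401-16449), carrying a reference gap
(mt3107 is 'N' in the rCRS), being a known phantom mutation or a blacklisted
site, having cohort mean coverage <1000x, or being homoplasmic for the
reference allele (maximum minor-read fraction below 0.007 across the
cohort).  NUMT-derived reads are deliberately retained: the long-range PCR
design makes nuclear contamination of the amplicons unlikely, so an
annotation hook is all that is offered.

Every exclusion is recorded in a :class:`QCReport` ledger whose counts are
conserved: per-rule exclusions plus retained items always sum to the input.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .counts import BASES, AlleleCountTensor

#: PCR primer region (1-based, inclusive): 49 bases without reliable signal.
PRIMER_REGION: tuple[int, int] = (16401, 16449)
#: rCRS positions with a gap ('N') in the reference base.
REFERENCE_GAPS: frozenset[int] = frozenset({3107})
#: Known phantom mutations (systematic sequencing artifacts).
PHANTOM_POSITIONS: frozenset[int] = frozenset({3166, 3170, 16390})
#: Blacklisted sites (GATK recommendation for mtDNA).
BLACKLIST_POSITIONS: frozenset[int] = frozenset({301, 302, 310, 316, 16182})


@dataclass(frozen=True)
class PositionAlleles:
    """Reference base (from the rCRS FASTA) and cohort-wide alternative
    allele (the non-reference base with the largest summed read count) for
    one position."""

    position: int
    ref_base: str
    alt_base: str
    ref_is_gap: bool = False


@dataclass
class QCReport:
    """Accounting ledger for one QC pass over individuals or positions."""

    scope: str
    n_input: int
    excluded: "OrderedDict[str, list]" = field(default_factory=OrderedDict)

    def add(self, rule: str, items) -> None:
        self.excluded[rule] = list(items)

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.excluded.values())

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def counts(self) -> "OrderedDict[str, int]":
        return OrderedDict((k, len(v)) for k, v in self.excluded.items())

    def is_conserved(self) -> bool:
        """Per-rule exclusions + retained == input, with no double counting."""
        all_items: list = sum(self.excluded.values(), [])
        return len(all_items) == len(set(all_items)) == self.n_excluded

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scope": self.scope, "rule": rule, "n_excluded": len(items)}
            for rule, items in self.excluded.items()
        ]
        rows.append({"scope": self.scope, "rule": "retained", "n_excluded": self.n_retained})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SeqQCConfig:
    """Thresholds and fixed position sets for QC step 1 (defaults are the
    study's printed values)."""

    min_mean_coverage: float = 1000.0
    homoplasmy_threshold: float = 0.007
    primer_region: tuple[int, int] = PRIMER_REGION
    gap_positions: frozenset[int] = REFERENCE_GAPS
    phantom_positions: frozenset[int] = PHANTOM_POSITIONS
    blacklist_positions: frozenset[int] = BLACKLIST_POSITIONS


def read_reference(path) -> str:
    """First record of a FASTA file as an upper-case string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def exclude_individuals(
    tensor: AlleleCountTensor,
    covariates: pd.DataFrame,
    min_mean_coverage: float = 1000.0,
) -> tuple[AlleleCountTensor, QCReport]:
    """Drop contaminated, low-coverage and diabetic individuals.

    ``covariates`` must be indexed by individual id and carry boolean
    ``contaminated`` and ``diabetes`` columns.  Rules are applied in that
    order with mean coverage in between; an individual matching several
    rules is attributed to the first.  Mean coverage is the mean over all
    positions of the total read count, compared strictly (``< 1000`` is
    out, ``1000.0`` exactly stays).
    """
    missing = [i for i in tensor.individuals if i not in covariates.index]
    if missing:
        raise KeyError(f"individuals missing from covariates: {missing[:5]!r}...")
    cov = covariates.loc[tensor.individuals]

    contaminated = cov["contaminated"].to_numpy(dtype=bool)
    diabetic = cov["diabetes"].to_numpy(dtype=bool)
    low_cov = tensor.mean_coverage_per_individual() < min_mean_coverage

    report = QCReport("individuals", tensor.n_individuals)
    taken = np.zeros(tensor.n_individuals, dtype=bool)
    for rule, mask in (
        ("contamination", contaminated),
        ("mean_coverage", low_cov),
        ("diabetes", diabetic),
    ):
        hit = mask & ~taken
        report.add(rule, list(tensor.individuals[hit]))
        taken |= hit
    return tensor.select_individuals(~taken), report


def call_alleles(tensor: AlleleCountTensor, reference: str) -> list[PositionAlleles]:
    """Define per-position reference and alternative alleles.

    The reference base comes from the FASTA; the alternative allele is the
    non-reference base with the largest read count summed over the cohort.
    Ties break alphabetically (A < C < G < T), which also covers the
    degenerate all-reference case.  A reference base outside {A,C,G,T} is
    reported as a gap and the overall top base is recorded as alternative.
    """
    if tensor.n_positions and len(reference) < int(tensor.positions.max()):
        raise ValueError(
            f"reference length {len(reference)} shorter than max position "
            f"{tensor.positions.max()}"
        )
    totals = tensor.counts.sum(axis=0, dtype=np.int64)  # (s, 4)
    out: list[PositionAlleles] = []
    base_arr = np.array(BASES)
    for i, pos in enumerate(tensor.positions):
        ref = reference[pos - 1]
        row = totals[i]
        if ref in BASES:
            masked = row.copy()
            masked[BASES.index(ref)] = -1
            alt = base_arr[int(np.argmax(masked))]  # argmax: first max, alphabetical
            out.append(PositionAlleles(int(pos), ref, str(alt)))
        else:
            alt = base_arr[int(np.argmax(row))]
            out.append(PositionAlleles(int(pos), ref, str(alt), ref_is_gap=True))
    return out


def minor_fraction_matrix(
    tensor: AlleleCountTensor, alleles: list[PositionAlleles]
) -> np.ndarray:
    """B/(A+B) per (individual, position); 0 where A+B == 0."""
    ref = np.array([a.ref_base for a in alleles])
    alt = np.array([a.alt_base for a in alleles])
    a_counts = tensor.base_plane(ref)
    b_counts = tensor.base_plane(alt)
    denom = a_counts + b_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, b_counts / np.maximum(denom, 1), 0.0)
    return frac


def filter_positions(
    tensor: AlleleCountTensor,
    alleles: list[PositionAlleles],
    config: SeqQCConfig = SeqQCConfig(),
) -> tuple[AlleleCountTensor, QCReport]:
    """Apply the position-level exclusion rules, in order.

    Order: primer region, reference gap, phantom mutations, blacklist,
    cohort mean coverage < threshold, homoplasmic (max over individuals of
    the minor-read fraction strictly below the threshold).  A position
    matching several rules is attributed to the first.  Coverage and
    homoplasmy statistics are computed on the individuals present in
    ``tensor`` (individual-level QC is expected to have run first).
    """
    if tensor.n_individuals == 0:
        raise ValueError("cannot run position QC on an empty cohort")
    if len(alleles) != tensor.n_positions:
        raise ValueError("alleles must be defined for every position")

    positions = tensor.positions
    lo, hi = config.primer_region
    in_primer = (positions >= lo) & (positions <= hi)
    gap_set = set(config.gap_positions) | {a.position for a in alleles if a.ref_is_gap}
    in_gap = np.isin(positions, sorted(gap_set))
    in_phantom = np.isin(positions, sorted(config.phantom_positions))
    in_blacklist = np.isin(positions, sorted(config.blacklist_positions))
    low_cov = tensor.mean_coverage_per_position() < config.min_mean_coverage
    homoplasmic = (
        minor_fraction_matrix(tensor, alleles).max(axis=0) < config.homoplasmy_threshold
    )

    report = QCReport("positions", tensor.n_positions)
    taken = np.zeros(tensor.n_positions, dtype=bool)
    for rule, mask in (
        ("primer_region", in_primer),
        ("reference_gap", in_gap),
        ("phantom", in_phantom),
        ("blacklist", in_blacklist),
        ("low_coverage", low_cov),
        ("homoplasmic", homoplasmic),
    ):
        hit = mask & ~taken
        report.add(rule, [int(p) for p in positions[hit]])
        taken |= hit
    return tensor.select_positions(~taken), report
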