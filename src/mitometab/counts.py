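"""Per-individual, per-position mtDNA allele read counts.

The whole-genome sequencing input to the scan is a dense tensor of read
counts over individuals x rCRS positions x the four bases.  Heteroplasmy is
quantified downstream from two planes of this tensor: the reference-allele
counts A and the cohort-wide second-most-frequent-allele counts B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES: tuple[str, ...] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: length of the revised Cambridge Reference Sequence (rCRS, NC_012920)
GENOME_LENGTH: int = 16569


@dataclass
class AlleleCountTensor:
    """Read counts for a cohort: ``counts[k, i, b]`` is the number of reads
    of base ``BASES[b]`` at position ``positions[i]`` for ``individuals[k]``.

    Positions are 1-based rCRS coordinates.  Counts are non-negative
    integers; the dtype is left to the caller (uint16 suffices at ~3500x
    coverage and keeps full-genome cohorts small in memory).
    """

    individuals: np.ndarray
    positions: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.individuals = np.asarray(self.individuals)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        n, s = len(self.individuals), len(self.positions)
        if self.counts.shape != (n, s, 4):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {s}, 4)"
            )
        if s and (self.positions.min() < 1 or self.positions.max() > GENOME_LENGTH):
            raise ValueError("positions must lie in [1, 16569] (1-based rCRS)")
        if np.issubdtype(self.counts.dtype, np.signedinteger) and self.counts.min(initial=0) < 0:
            raise ValueError("read counts must be non-negative")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def position_index(self) -> pd.Index:
        return pd.Index(self.positions, name="position")

    # -- coverage ----------------------------------------------------------
    def total_coverage(self) -> np.ndarray:
        """Total reads per (individual, position), summed over bases."""
        return self.counts.sum(axis=2, dtype=np.int64)

    def mean_coverage_per_individual(self) -> np.ndarray:
        return self.total_coverage().mean(axis=1)

    def mean_coverage_per_position(self) -> np.ndarray:
        return self.total_coverage().mean(axis=0)

    # -- subsetting --------------------------------------------------------
    def select_individuals(self, mask: np.ndarray) -> "AlleleCountTensor":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.individuals, mask)
        return AlleleCountTensor(self.individuals[mask], self.positions, self.counts[mask])

    def select_positions(self, mask: np.ndarray) -> "AlleleCountTensor":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.positions, mask)
        return AlleleCountTensor(self.individuals, self.positions[mask], self.counts[:, mask])

    # -- per-base extraction ----------------------------------------------
    def base_plane(self, bases_per_position: np.ndarray) -> np.ndarray:
        """Counts of one base per position, e.g. the reference or alternative
        allele: ``bases_per_position`` is a length-``n_positions`` array of
        base characters; positions whose base is not in {A,C,G,T} (reference
        gaps) yield zeros.
        """
        bases_per_position = np.asarray(bases_per_position)
        if len(bases_per_position) != self.n_positions:
            raise ValueError("need one base per position")
        out = np.zeros((self.n_individuals, self.n_positions), dtype=np.int64)
        for b, idx in BASE_INDEX.items():
            sel = bases_per_position == b
            if sel.any():
                out[:, sel] = self.counts[:, sel, idx]
        return out

    # -- long-format I/O ---------------------------------------------------
    def to_long_frame(self, drop_zero: bool = True) -> pd.DataFrame:
        """Long table with columns individual_id, position, base, count."""
        n, s = self.n_individuals, self.n_positions
        frame = pd.DataFrame(
            {
                "individual_id": np.repeat(self.individuals, s * 4),
                "position": np.tile(np.repeat(self.positions, 4), n),
                "base": np.tile(np.array(BASES), n * s),
                "count": self.counts.reshape(-1),
            }
        )
        if drop_zero:
            frame = frame[frame["count"] > 0].reset_index(drop=True)
        return frame

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "AlleleCountTensor":
        individuals = pd.unique(frame["individual_id"])
        positions = np.sort(pd.unique(frame["position"].astype(np.int64)))
        ind_idx = pd.Series(np.arange(len(individuals)), index=individuals)
        pos_idx = pd.Series(np.arange(len(positions)), index=positions)
        counts = np.zeros((len(individuals), len(positions), 4), dtype=np.int64)
        base_codes = frame["base"].map(BASE_INDEX)
        if base_codes.isna().any():
            bad = frame.loc[base_codes.isna(), "base"].unique()
            raise ValueError(f"unknown bases in count table: {bad!r}")
        counts[
            ind_idx[frame["individual_id"]].to_numpy(),
            pos_idx[frame["position"]].to_numpy(),
            base_codes.to_numpy(dtype=np.int64),
        ] = frame["count"].to_numpy()
        return cls(individuals, positions, counts)

    def write_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AlleleCountTensor":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"))
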