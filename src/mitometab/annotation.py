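"""rCRS gene annotation (NC_012920 feature coordinates).

Standard 1-based inclusive coordinates of the 13 protein-coding genes, the
two rRNAs, the 22 tRNAs and the control-region segments of the human
mitochondrial genome.  Gene names follow the short convention used in
mtDNA association tables (ND1, CO1, 12SrRNA, ...).  A handful of features
overlap (ATP8/ATP6, ND4L/ND4, tRNA-Ile/tRNA-Gln); lookups resolve to the
first feature in table order, which keeps them deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .counts import GENOME_LENGTH


@dataclass(frozen=True)
class MTAnnotation:
    """One annotated rCRS feature (1-based inclusive interval)."""

    name: str
    start: int
    end: int
    feature_class: str  # protein | rRNA | tRNA | control | non-coding


#: NC_012920 features in coordinate order (overlaps resolved first-wins).
RCRS_FEATURES: tuple[MTAnnotation, ...] = (
    MTAnnotation("tRNA-Phe", 577, 647, "tRNA"),
    MTAnnotation("12SrRNA", 648, 1601, "rRNA"),
    MTAnnotation("tRNA-Val", 1602, 1670, "tRNA"),
    MTAnnotation("16SrRNA", 1671, 3229, "rRNA"),
    MTAnnotation("tRNA-Leu(UUR)", 3230, 3304, "tRNA"),
    MTAnnotation("ND1", 3307, 4262, "protein"),
    MTAnnotation("tRNA-Ile", 4263, 4331, "tRNA"),
    MTAnnotation("tRNA-Gln", 4329, 4400, "tRNA"),
    MTAnnotation("tRNA-Met", 4402, 4469, "tRNA"),
    MTAnnotation("ND2", 4470, 5511, "protein"),
    MTAnnotation("tRNA-Trp", 5512, 5579, "tRNA"),
    MTAnnotation("tRNA-Ala", 5587, 5655, "tRNA"),
    MTAnnotation("tRNA-Asn", 5657, 5729, "tRNA"),
    MTAnnotation("tRNA-Cys", 5761, 5826, "tRNA"),
    MTAnnotation("tRNA-Tyr", 5826, 5891, "tRNA"),
    MTAnnotation("CO1", 5904, 7445, "protein"),
    MTAnnotation("tRNA-Ser(UCN)", 7446, 7514, "tRNA"),
    MTAnnotation("tRNA-Asp", 7518, 7585, "tRNA"),
    MTAnnotation("CO2", 7586, 8269, "protein"),
    MTAnnotation("tRNA-Lys", 8295, 8364, "tRNA"),
    MTAnnotation("ATP8", 8366, 8572, "protein"),
    MTAnnotation("ATP6", 8527, 9207, "protein"),
    MTAnnotation("CO3", 9207, 9990, "protein"),
    MTAnnotation("tRNA-Gly", 9991, 10058, "tRNA"),
    MTAnnotation("ND3", 10059, 10404, "protein"),
    MTAnnotation("tRNA-Arg", 10405, 10469, "tRNA"),
    MTAnnotation("ND4L", 10470, 10766, "protein"),
    MTAnnotation("ND4", 10760, 12137, "protein"),
    MTAnnotation("tRNA-His", 12138, 12206, "tRNA"),
    MTAnnotation("tRNA-Ser(AGY)", 12207, 12265, "tRNA"),
    MTAnnotation("tRNA-Leu(CUN)", 12266, 12331, "tRNA"),
    MTAnnotation("ND5", 12337, 14148, "protein"),
    MTAnnotation("ND6", 14149, 14673, "protein"),
    MTAnnotation("tRNA-Glu", 14674, 14742, "tRNA"),
    MTAnnotation("CYB", 14747, 15887, "protein"),
    MTAnnotation("tRNA-Thr", 15888, 15953, "tRNA"),
    MTAnnotation("tRNA-Pro", 15956, 16023, "tRNA"),
    # control region wraps the origin: HVR-I then the remainder on each side
    MTAnnotation("HVR-I", 16024, 16383, "control"),
    MTAnnotation("control-region", 16384, GENOME_LENGTH, "control"),
    MTAnnotation("control-region", 1, 576, "control"),
)

_LOOKUP: list[MTAnnotation] | None = None


def _build_lookup() -> list[MTAnnotation]:
    table: list[MTAnnotation | None] = [None] * (GENOME_LENGTH + 1)
    for feat in RCRS_FEATURES:
        for pos in range(feat.start, feat.end + 1):
            if table[pos] is None:
                table[pos] = feat
    gap = MTAnnotation("non-coding", 0, 0, "non-coding")
    return [feat if feat is not None else gap for feat in table]


def annotate_position(position: int) -> MTAnnotation:
    """Containing rCRS feature for a 1-based position.

    Covers every position in [1, 16569]: spacer positions between annotated
    features return a 'non-coding' record, control-region positions a
    'control' one.
    """
    global _LOOKUP
    if not 1 <= position <= GENOME_LENGTH:
        raise ValueError(f"position {position} outside [1, {GENOME_LENGTH}]")
    if _LOOKUP is None:
        _LOOKUP = _build_lookup()
    return _LOOKUP[position]


def gene_of(position: int) -> str:
    return annotate_position(position).name
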