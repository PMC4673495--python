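"""Combinatorial setae beta-keratin classifier.

Setae beta-keratins are recognised by five features, each a strict threshold:

1. presence of the S-core box motif (``SEVTIQPPPCTVVVPGPVLA``) at >= 70%
   ungapped identity,
2. cysteine-rich composition (Cys > 10%),
3. glycine-rich composition (Gly > 15%),
4. basic isoelectric point (pI > 7),
5. low molecular weight (< 15,000 Da).

A protein's label is the concatenation of its sorted feature flags ("0" when
none apply).  Motif similarity is the maximum over all ungapped placements of
the motif against the sequence of identities divided by the motif length, so
overhangs and deletions count as mismatches.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .proteins import ProteinRecord, PropertyProfile, property_profile

__all__ = [
    "SCORE_BOX",
    "CoreBoxMotif",
    "ClassifierThresholds",
    "KeratinFeatureProfile",
    "FamilySummary",
    "corebox_similarity",
    "classify_keratin",
    "summarize_family",
    "write_classification_table",
]

#: The conserved 20-residue setae diagnostic motif.
SCORE_BOX = "SEVTIQPPPCTVVVPGPVLA"


@dataclass(frozen=True)
class CoreBoxMotif:
    sequence: str = SCORE_BOX
    similarity_threshold: float = 70.0

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError("core-box motif must be at least 5 residues")
        if not (0.0 < self.similarity_threshold <= 100.0):
            raise ValueError("similarity threshold must be in (0, 100]")


@dataclass(frozen=True)
class ClassifierThresholds:
    """All five cut-offs; every inequality is strict except the motif's >=."""

    min_identity: float = 70.0
    cys_fraction: float = 0.10
    gly_fraction: float = 0.15
    pi: float = 7.0
    max_mw: float = 15000.0


@dataclass(frozen=True)
class KeratinFeatureProfile:
    record_id: str
    corebox_pct: float
    flags: frozenset[int]
    label: str
    property_profile: PropertyProfile = field(compare=False)


@dataclass(frozen=True)
class FamilySummary:
    n: int
    flag_counts: dict[int, int]
    label_counts: dict[str, int]


def corebox_similarity(seq: str, motif: CoreBoxMotif | str = SCORE_BOX) -> float:
    """Best ungapped percent identity of the motif anywhere along ``seq``.

    Every placement of the motif relative to the sequence is scored, including
    partial overlaps; the denominator is always the motif length, so overhang
    positions count as mismatches.
    """
    motif_seq = motif.sequence if isinstance(motif, CoreBoxMotif) else motif
    seq = seq.upper()
    motif_seq = motif_seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    m = len(motif_seq)
    best = 0
    for offset in range(-(m - 1), len(seq)):
        matches = 0
        for j in range(m):
            i = offset + j
            if 0 <= i < len(seq) and seq[i] == motif_seq[j]:
                matches += 1
        best = max(best, matches)
    return 100.0 * best / m


def _gapped_similarity(seq: str, motif_seq: str) -> float:
    """Optional gapped (local-alignment) similarity mode; not the default."""
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local", match_score=1, mismatch_score=0,
        open_gap_score=-1, extend_gap_score=-0.5,
    )
    score = aligner.score(seq.upper(), motif_seq.upper())
    return 100.0 * score / len(motif_seq)


def classify_keratin(
    record: ProteinRecord,
    motif: CoreBoxMotif = CoreBoxMotif(),
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    gapped: bool = False,
) -> KeratinFeatureProfile:
    """Apply the five-feature classifier to one protein."""
    prof = property_profile(record)
    if gapped:
        pct = _gapped_similarity(record.sequence, motif.sequence)
    else:
        pct = corebox_similarity(record.sequence, motif)
    flags = set()
    if pct >= thresholds.min_identity:
        flags.add(1)
    if prof.fractions["C"] > thresholds.cys_fraction:
        flags.add(2)
    if prof.fractions["G"] > thresholds.gly_fraction:
        flags.add(3)
    if prof.pI > thresholds.pi:
        flags.add(4)
    if prof.mol_weight < thresholds.max_mw:
        flags.add(5)
    label = "".join(str(f) for f in sorted(flags)) or "0"
    return KeratinFeatureProfile(
        record_id=record.id,
        corebox_pct=pct,
        flags=frozenset(flags),
        label=label,
        property_profile=prof,
    )


def summarize_family(profiles: Sequence[KeratinFeatureProfile]) -> FamilySummary:
    """Per-flag counts and label cross-tabulation; empty input gives an empty summary."""
    flag_counts = Counter()
    label_counts = Counter()
    for p in profiles:
        label_counts[p.label] += 1
        for f in p.flags:
            flag_counts[f] += 1
    return FamilySummary(
        n=len(profiles),
        flag_counts={f: flag_counts.get(f, 0) for f in (1, 2, 3, 4, 5)},
        label_counts=dict(sorted(label_counts.items())),
    )


def write_classification_table(
    profiles: Iterable[KeratinFeatureProfile], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "corebox_pct", "flags", "label", "mw", "pI", "frac_C", "frac_G"])
        for p in profiles:
            prof = p.property_profile
            writer.writerow([
                p.record_id, f"{p.corebox_pct:.2f}",
                ",".join(str(f) for f in sorted(p.flags)) or "-",
                p.label, f"{prof.mol_weight:.2f}", f"{prof.pI:.4f}",
                f"{prof.fractions['C']:.6f}", f"{prof.fractions['G']:.6f}",
            ])
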