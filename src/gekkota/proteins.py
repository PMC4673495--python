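"""Physicochemical protein properties underlying the beta-keratin classifier.

Setae beta-keratins (corneous beta-proteins) are small (~10 kDa), cysteine- or
glycine-rich structural proteins with high isoelectric points.  The classifier
thresholds these quantities, so they are computed here from first principles:
residue composition, average-isotopic molecular weight, and a
Henderson-Hasselbalch isoelectric point solved by bisection.

Conventions (fixed once, documented, and used consistently):

* Masses are average (not monoisotopic) residue masses; a peptide's weight is
  the sum of residue masses plus one water.
* ``X`` (unknown residue) is excluded from composition denominators,
  contributes the mean residue mass (111.1 Da) to molecular weight, and is
  never ionisable.
* The pKa set is the EMBOSS-style table.  Absolute pI values depend on the
  table chosen; only classification against a threshold (pI > 7) is meant to
  be portable across tables.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "PropertyProfile",
    "DegenerateSequenceError",
    "residue_fraction",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "property_profile",
    "read_protein_fasta",
    "write_protein_fasta",
    "write_property_table",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(STANDARD_RESIDUES + "X")

#: Average residue (monomer minus water) masses in Daltons.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
MEAN_RESIDUE_MASS = 111.1  # stand-in for 'X'

#: EMBOSS-style pKa values for the ionisable groups.
PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
POSITIVE_GROUPS = ("Nterm", "H", "K", "R")
NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


class DegenerateSequenceError(ValueError):
    """Raised when a sequence has no countable residues after filtering."""


def _validate(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - ALLOWED_RESIDUES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with a free-text source tag."""

    id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate(self.sequence))
        if not self.id:
            raise ValueError("ProteinRecord requires a non-empty id")


@dataclass(frozen=True)
class PropertyProfile:
    """Measured physicochemical quantities for one protein."""

    length: int
    mol_weight: float
    pI: float
    fractions: Mapping[str, float]
    pI_is_convention: bool = field(default=False, compare=False)


def residue_fraction(seq: str, residue: str) -> float:
    """Fraction of ``residue`` among the counted (non-X) residues of ``seq``."""
    seq = _validate(seq)
    residue = residue.upper()
    counted = [c for c in seq if c != "X"]
    if not counted:
        raise DegenerateSequenceError("sequence has no countable residues (all X)")
    return counted.count(residue) / len(counted)


def molecular_weight(seq: str) -> float:
    """Average-isotopic molecular weight in Daltons (residues + one water)."""
    seq = _validate(seq)
    total = WATER_MASS
    for c in seq:
        total += MEAN_RESIDUE_MASS if c == "X" else AVERAGE_RESIDUE_MASS[c]
    return total


def net_charge(seq: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at ``pH``.

    Positive groups (N-terminus, H, K, R) contribute ``+1/(1+10^(pH-pKa))``;
    negative groups (C-terminus, D, E, C, Y) contribute ``-1/(1+10^(pKa-pH))``.
    This is strictly decreasing in pH.
    """
    seq = _validate(seq)
    counts = {"Nterm": 1, "Cterm": 1}
    for group in PKA:
        if len(group) == 1:
            counts[group] = seq.count(group)
    charge = 0.0
    for group in POSITIVE_GROUPS:
        charge += counts[group] / (1.0 + 10.0 ** (pH - PKA[group]))
    for group in NEGATIVE_GROUPS:
        charge -= counts[group] / (1.0 + 10.0 ** (PKA[group] - pH))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    A peptide whose charge does not change sign on the interval (no effective
    ionisable groups) is reported at the neutral convention value 7.0 with a
    warning rather than an error.
    """
    seq = _validate(seq)
    lo, hi = 0.0, 14.0
    f_lo, f_hi = net_charge(seq, lo), net_charge(seq, hi)
    if f_lo <= 0.0 or f_hi >= 0.0:
        warnings.warn("no zero-charge crossing on [0, 14]; reporting pI = 7.0 by convention")
        return 7.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def property_profile(record: ProteinRecord) -> PropertyProfile:
    """Full physicochemical profile of ``record``."""
    seq = record.sequence
    counted = [c for c in seq if c != "X"]
    if not counted:
        raise DegenerateSequenceError(f"{record.id}: all residues are X")
    n = len(counted)
    fractions = {r: counted.count(r) / n for r in STANDARD_RESIDUES}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        pi = isoelectric_point(seq)
        convention = any("convention" in str(w.message) for w in caught)
    return PropertyProfile(
        length=len(seq),
        mol_weight=molecular_weight(seq),
        pI=pi,
        fractions=fractions,
        pI_is_convention=convention,
    )


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from FASTA; the id is the first whitespace token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq), source=str(path)))
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")  # Biopython wraps at 60 columns


def write_property_table(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """One TSV row per record: id, length, mol_weight, pI, fraction_C, fraction_G."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "length", "mol_weight", "pI", "fraction_C", "fraction_G"])
        for rec in records:
            prof = property_profile(rec)
            writer.writerow([
                rec.id, prof.length,
                f"{prof.mol_weight:.2f}", f"{prof.pI:.4f}",
                f"{prof.fractions['C']:.6f}", f"{prof.fractions['G']:.6f}",
            ])
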