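"""Nei-Gojobori (1986) Ka/Ks estimation and the positive-selection screen.

The regeneration analysis asks, for each single-copy ortholog of the focal
species against a comparator, whether the nonsynonymous substitution rate Ka
exceeds the synonymous rate Ks (omega = Ka/Ks > 1 indicates positive
selection).  The estimator is the classic NG86 pathway-counting method:

* every sense codon contributes fractional synonymous site counts
  ``s = sum over positions of (synonymous one-step changes at that
  position)/3`` and ``n = 3 - s`` (changes to stop codons count as
  nonsynonymous);
* differences between a codon pair are resolved by averaging the synonymous /
  nonsynonymous step counts over all minimal mutational pathways, weighting
  pathways equally and excluding those that pass through a stop codon;
* proportions pS = Sd/S and pN = Nd/N are Jukes-Cantor corrected,
  ``K = -(3/4) ln(1 - 4p/3)``, undefined at p >= 3/4 (saturated).

Upstream of the estimate, alignment columns of dubious homology are removed
by a codon-column conservation/gap filter playing the Gblocks role.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "OverlapResult",
    "GENETIC_CODE",
    "SENSE_CODONS",
    "STOP_CODONS",
    "filter_blocks",
    "ng86_sites",
    "ng86_kaks",
    "screen_psg",
    "expression_overlap",
    "read_codon_fasta",
    "read_expression_table",
    "write_expression_table",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
STOP_CODONS = frozenset(_TABLE.stop_codons)
GENETIC_CODE: Mapping[str, str] = dict(_TABLE.forward_table)
SENSE_CODONS = frozenset(GENETIC_CODE)
NUCLEOTIDES = "ACGT"
GAP = "-"

#: the nine single-nucleotide neighbours of each sense codon
_NEIGHBOURS: dict[str, list[tuple[int, str]]] = {
    codon: [
        (pos, codon[:pos] + nt + codon[pos + 1:])
        for pos in range(3)
        for nt in NUCLEOTIDES
        if nt != codon[pos]
    ]
    for codon in SENSE_CODONS
}


@dataclass(frozen=True)
class CodonAlignment:
    """Two or more in-frame gapped CDS sequences of equal length.

    No sequence may contain an internal stop codon in its ungapped frame;
    a terminal stop is allowed.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 2 or len(self.ids) != len(self.seqs):
            raise ValueError("need >= 2 ids with matching sequences")
        length = len(self.seqs[0])
        if length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        object.__setattr__(self, "seqs", tuple(s.upper() for s in self.seqs))
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise ValueError(f"{sid}: unequal alignment length")
            ungapped = s.replace(GAP, "")
            codons = [ungapped[i:i + 3] for i in range(0, len(ungapped) - 3, 3)]
            if any(c in STOP_CODONS for c in codons):
                raise ValueError(f"{sid}: internal stop codon in ungapped frame")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codon_column(self, k: int) -> tuple[str, ...]:
        return tuple(s[3 * k: 3 * k + 3] for s in self.seqs)


@dataclass(frozen=True)
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ka: float | None
    Ks: float | None
    ratio: float | None
    flag: str = ""  # "", "Ks_zero", "saturated"
    compared_codons: int = 0


@dataclass(frozen=True)
class OverlapResult:
    numerator: int
    denominator: int
    fraction: float | None
    missing_ids: tuple[str, ...] = ()


class EmptyAlignmentError(ValueError):
    """Raised when block filtering removes every codon column."""


def filter_blocks(
    aln: CodonAlignment,
    min_conserved_fraction: float = 0.5,
    max_gap_fraction: float = 0.2,
    min_block_codons: int = 3,
) -> CodonAlignment:
    """Codon-column filter in the Gblocks role.

    A codon column is dropped when the fraction of sequences gapped there
    exceeds ``max_gap_fraction`` or when the modal codon's share of the
    ungapped entries falls below ``min_conserved_fraction``; surviving runs
    shorter than ``min_block_codons`` columns are then dropped too.
    """
    n_seq = len(aln.seqs)
    keep: list[bool] = []
    for k in range(aln.n_codons):
        col = aln.codon_column(k)
        gapped = sum(1 for c in col if GAP in c)
        if gapped / n_seq > max_gap_fraction:
            keep.append(False)
            continue
        ungapped = [c for c in col if GAP not in c]
        if not ungapped:
            keep.append(False)
            continue
        modal = max(ungapped.count(c) for c in set(ungapped))
        keep.append(modal / len(ungapped) >= min_conserved_fraction)
    # drop surviving runs shorter than min_block_codons
    kept_cols: list[int] = []
    run: list[int] = []
    for k, ok in enumerate(keep):
        if ok:
            run.append(k)
        else:
            if len(run) >= min_block_codons:
                kept_cols.extend(run)
            run = []
    if len(run) >= min_block_codons:
        kept_cols.extend(run)
    if not kept_cols:
        raise EmptyAlignmentError("all codon columns filtered out")
    new_seqs = tuple(
        "".join(s[3 * k: 3 * k + 3] for k in kept_cols) for s in aln.seqs
    )
    return CodonAlignment(ids=aln.ids, seqs=new_seqs)


def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    Each position contributes the fraction of its three one-step changes that
    are synonymous; changes into stop codons count as nonsynonymous.
    """
    codon = codon.upper()
    if codon not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for _, neighbour in _NEIGHBOURS[codon]:
        if neighbour not in STOP_CODONS and GENETIC_CODE[neighbour] == aa:
            s += 1.0 / 3.0
    return s, 3.0 - s


def _step_type(c1: str, c2: str) -> str:
    """'syn' or 'nonsyn' for a one-step change between sense codons."""
    return "syn" if GENETIC_CODE[c1] == GENETIC_CODE[c2] else "nonsyn"


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (Sd, Nd) over minimal mutational pathways between two codons.

    Pathways through stop codons are excluded; in the degenerate case where
    every pathway is blocked, all pathways are averaged instead.
    """
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    nd = len(diff_positions)
    if nd == 0:
        return 0.0, 0.0
    if nd == 1:
        return (1.0, 0.0) if _step_type(c1, c2) == "syn" else (0.0, 1.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = c1
        sd = nds = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                return None
            if _step_type(cur, nxt) == "syn":
                sd += 1.0
            else:
                nds += 1.0
            cur = nxt
        return sd, nds

    valid = [r for order in itertools.permutations(diff_positions) if (r := walk(order))]
    if not valid:
        # every minimal path traverses a stop; fall back to counting steps
        # through stops as nonsynonymous
        valid = []
        for order in itertools.permutations(diff_positions):
            cur = c1
            sd = nds = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS or GENETIC_CODE.get(cur, "*") != GENETIC_CODE.get(nxt, "*"):
                    nds += 1.0
                else:
                    sd += 1.0
                cur = nxt
            valid.append((sd, nds))
    sd = sum(v[0] for v in valid) / len(valid)
    nds = sum(v[1] for v in valid) / len(valid)
    return sd, nds


def _jc_correct(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(pair: CodonAlignment) -> KaKsResult:
    """NG86 Ka, Ks and their ratio for a two-sequence codon alignment.

    Codons where either sequence is gapped, or where either codon is not a
    sense codon (terminal stops included), are skipped pairwise.  Site counts
    are averaged over the two sequences.
    """
    if len(pair.seqs) != 2:
        raise ValueError("ng86_kaks takes exactly two sequences")
    a, b = pair.seqs
    S = N = Sd = Nd = 0.0
    compared = 0
    for k in range(pair.n_codons):
        ca, cb = a[3 * k: 3 * k + 3], b[3 * k: 3 * k + 3]
        if ca not in SENSE_CODONS or cb not in SENSE_CODONS:
            continue
        compared += 1
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = _pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    if compared == 0:
        raise ValueError("no shared ungapped sense codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    if Ks is None or Ka is None:
        return KaKsResult(S, N, Sd, Nd, pS, pN, Ka, Ks, None,
                          flag="saturated", compared_codons=compared)
    if Ks == 0.0:
        return KaKsResult(S, N, Sd, Nd, pS, pN, Ka, Ks, None,
                          flag="Ks_zero", compared_codons=compared)
    return KaKsResult(S, N, Sd, Nd, pS, pN, Ka, Ks, Ka / Ks,
                      compared_codons=compared)


def screen_psg(
    orthologs: Mapping[str, CodonAlignment],
    threshold: float = 1.0,
    min_codons: int = 30,
    filter_params: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Positive-selection screen over per-gene codon alignments.

    Each alignment lists the focal species first followed by one or more
    comparators.  The gene's reported estimate is the focal-vs-comparator
    pair with the largest defined ratio; a gene is a PSG candidate when that
    ratio exceeds ``threshold`` with at least ``min_codons`` compared codons.
    Returns the candidate table (sorted by gene) and a log of exclusions.
    """
    rows = []
    log: list[str] = []
    for gene in sorted(orthologs):
        aln = orthologs[gene]
        if filter_params is not None:
            try:
                aln = filter_blocks(aln, **filter_params)
            except EmptyAlignmentError:
                log.append(f"{gene}: all columns filtered; skipped")
                continue
        best: KaKsResult | None = None
        best_comp = ""
        any_pair = False
        for i in range(1, len(aln.seqs)):
            pair = CodonAlignment(
                ids=(aln.ids[0], aln.ids[i]), seqs=(aln.seqs[0], aln.seqs[i])
            )
            try:
                res = ng86_kaks(pair)
            except ValueError as exc:
                log.append(f"{gene} vs {aln.ids[i]}: {exc}")
                continue
            any_pair = True
            if res.ratio is None:
                continue
            if res.compared_codons < min_codons:
                log.append(
                    f"{gene} vs {aln.ids[i]}: only {res.compared_codons} compared codons"
                )
                continue
            if best is None or res.ratio > best.ratio:
                best = res
                best_comp = aln.ids[i]
        if best is None:
            if any_pair:
                log.append(f"{gene}: no pair with a defined ratio; excluded")
            continue
        if best.ratio > threshold:
            rows.append({
                "gene": gene, "comparator": best_comp,
                "S": best.S_sites, "N": best.N_sites,
                "Sd": best.Sd, "Nd": best.Nd,
                "Ka": best.Ka, "Ks": best.Ks, "ratio": best.ratio,
                "compared_codons": best.compared_codons,
            })
    columns = ["gene", "comparator", "S", "N", "Sd", "Nd", "Ka", "Ks",
               "ratio", "compared_codons"]
    return pd.DataFrame(rows, columns=columns), log


TIMEPOINTS = ("d0", "d1", "d3", "d7")
POST_TIMEPOINTS = ("d1", "d3", "d7")


def expression_overlap(
    psg_ids: Iterable[str],
    table: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> OverlapResult:
    """Fraction of PSGs upregulated at any post-autotomy timepoint.

    A gene counts as upregulated when expression at day 1, 3 or 7 is at least
    ``fold_threshold`` times its day-0 baseline.  Genes with a zero baseline
    count as upregulated iff any later value is positive.  PSG ids absent
    from the table are excluded from the denominator and reported.
    """
    for col in TIMEPOINTS:
        if col not in table.columns:
            raise ValueError(f"expression table lacks column {col!r}")
    if (table[list(TIMEPOINTS)] < 0).any().any():
        raise ValueError("expression values must be non-negative")
    psg_ids = list(psg_ids)
    missing = tuple(g for g in psg_ids if g not in table.index)
    present = [g for g in psg_ids if g in table.index]
    up = 0
    for g in present:
        base = table.at[g, "d0"]
        later = [table.at[g, t] for t in POST_TIMEPOINTS]
        if base == 0:
            if any(v > 0 for v in later):
                up += 1
        elif any(v / base >= fold_threshold for v in later):
            up += 1
    fraction = up / len(present) if present else None
    return OverlapResult(
        numerator=up, denominator=len(present), fraction=fraction,
        missing_ids=missing,
    )


# ---------------------------------------------------------------------------
# flat-file interfaces

def read_codon_fasta(path: str | Path) -> CodonAlignment:
    """Read an aligned in-frame CDS FASTA (frame-checked on read)."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    return CodonAlignment(
        ids=tuple(r.id for r in recs), seqs=tuple(str(r.seq) for r in recs)
    )


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, d0, d1, d3, d7 -> DataFrame indexed by gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("gene")
    return df


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
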