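"""ORF/exon disruption scanning for pseudogene calling.

A gene copy is called a pseudogene when its open reading frame or exon
structure is broken relative to a functional ortholog: lost initiation or
termination codon, premature stops, frameshifting indels, or exons that are
missing, incomplete or frame-shifted compared with the reference.  This is
the procedure behind calling the gecko rod opsin RH1 and cone opsin SWS2
nonfunctional while SWS1/LWS/RH2 remain intact.

Coordinates are 0-based half-open throughout; GFF3 input (1-based closed) is
converted on read.  Exon lists are stored in transcript (5'->3') order, so a
minus-strand gene lists its highest-coordinate exon first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "OrfScan",
    "DisruptionReport",
    "splice_cds",
    "exon_sequences",
    "scan_orf",
    "compare_to_functional",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_contigs_fasta",
    "write_disruption_table",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene copy on a contig.

    ``exons`` are (start, end) 0-based half-open genomic intervals in
    transcript orientation: ascending genomic order on '+', descending on '-'.
    """

    id: str
    exons: tuple[tuple[int, int], ...]
    strand: str
    contig_id: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon interval ({s}, {e})")
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        genomic_order = [s for s, _ in self.exons]
        expected = sorted(genomic_order, reverse=(self.strand == "-"))
        if genomic_order != expected:
            raise ValueError("exons must be listed in transcript orientation")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class OrfScan:
    lost_start: bool
    premature_stops: tuple[int, ...]
    lost_stop: bool
    terminal_frameshift: bool = False


@dataclass(frozen=True)
class DisruptionReport:
    """Structured list of ORF/exon defects for one candidate gene."""

    gene_id: str
    lost_start: bool = False
    lost_stop: bool = False
    premature_stops: tuple[int, ...] = ()
    frameshifts: tuple[tuple[int, int], ...] = ()
    missing_exons: tuple[int, ...] = ()
    shifted_exons: tuple[tuple[int, int], ...] = ()
    incomplete_exons: tuple[int, ...] = ()
    terminal_frameshift: bool = False
    verdict: str = "functional"  # functional | pseudogene | unresolvable

    @property
    def disruptions(self) -> bool:
        return bool(
            self.lost_start or self.lost_stop or self.premature_stops
            or self.frameshifts or self.missing_exons or self.shifted_exons
            or self.incomplete_exons or self.terminal_frameshift
        )


def exon_sequences(model: GeneModel, contig: str) -> list[str]:
    """Per-exon sequences in transcript orientation."""
    out = []
    for idx, (s, e) in enumerate(model.exons):
        if e > len(contig):
            raise ValueError(
                f"{model.id}: exon {idx} ({s}, {e}) out of range for contig of "
                f"length {len(contig)}"
            )
        piece = contig[s:e].upper()
        if model.strand == "-":
            piece = str(Seq(piece).reverse_complement())
        out.append(piece)
    return out


def splice_cds(model: GeneModel, contig: str) -> str:
    """Concatenate exons in transcript order (reverse-complemented on '-')."""
    return "".join(exon_sequences(model, contig))


def scan_orf(cds: str) -> OrfScan:
    """Check start codon, internal stops, and the terminal stop of a CDS.

    A length not divisible by 3 is flagged as a terminal frameshift and the
    truncated in-frame portion is scanned.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    terminal_frameshift = len(cds) % 3 != 0
    usable = cds[: len(cds) - len(cds) % 3]
    codons = [usable[i:i + 3] for i in range(0, len(usable), 3)]
    lost_start = codons[0] != START_CODON
    premature = tuple(i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS)
    lost_stop = codons[-1] not in STOP_CODONS
    return OrfScan(
        lost_start=lost_start,
        premature_stops=premature,
        lost_stop=lost_stop,
        terminal_frameshift=terminal_frameshift,
    )


def _make_aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-4, extend_gap_score=-1,
    )


def _align_stats(cand: str, ref: str) -> tuple[float, float, list[tuple[int, int]]]:
    """Identity (matches/len(ref)), coverage (aligned ref/len(ref)), and
    internal indel runs as (candidate CDS-local position, length)."""
    aln = _make_aligner().align(cand, ref)[0]
    cand_blocks, ref_blocks = aln.aligned
    matches = 0
    aligned_ref = 0
    for (cs, ce), (rs, re) in zip(cand_blocks, ref_blocks):
        aligned_ref += re - rs
        matches += sum(1 for a, b in zip(cand[cs:ce], ref[rs:re]) if a == b)
    indels: list[tuple[int, int]] = []
    for k in range(len(cand_blocks) - 1):
        gap_c = cand_blocks[k + 1][0] - cand_blocks[k][1]  # insertion in candidate
        gap_r = ref_blocks[k + 1][0] - ref_blocks[k][1]    # deletion from reference
        if gap_c:
            indels.append((int(cand_blocks[k][1]), int(gap_c)))
        if gap_r:
            indels.append((int(cand_blocks[k][1]), -int(gap_r)))
    return matches / len(ref), aligned_ref / len(ref), indels


def _pair_exons(
    cand_seqs: Sequence[str],
    ref_seqs: Sequence[str],
    identity_floor: float,
) -> tuple[list[tuple[int, int]], dict[tuple[int, int], tuple[float, float, list]]]:
    """Order-preserving best-identity assignment of candidate to reference
    exons (collinear: no rearrangement assumed).  Returns matched (cand_idx,
    ref_idx) pairs and their alignment statistics."""
    m, n = len(cand_seqs), len(ref_seqs)
    stats: dict[tuple[int, int], tuple[float, float, list]] = {}
    score = [[0.0] * n for _ in range(m)]
    for i in range(m):
        for j in range(n):
            st = _align_stats(cand_seqs[i], ref_seqs[j])
            stats[(i, j)] = st
            score[i][j] = st[0] if st[0] >= identity_floor else -1.0
    # DP: best total identity over collinear matchings with skips allowed.
    best = [[0.0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best[i][j] = max(best[i - 1][j], best[i][j - 1])
            if score[i - 1][j - 1] >= 0:
                best[i][j] = max(best[i][j], best[i - 1][j - 1] + score[i - 1][j - 1])
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        if (
            score[i - 1][j - 1] >= 0
            and abs(best[i][j] - (best[i - 1][j - 1] + score[i - 1][j - 1])) < 1e-12
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif best[i][j] == best[i - 1][j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs, stats


def compare_to_functional(
    candidate: GeneModel,
    contig: str,
    reference_cds: str,
    reference_exon_lengths: Sequence[int],
    identity_floor: float = 0.5,
    coverage_floor: float = 0.8,
) -> DisruptionReport:
    """Compare a candidate gene copy against a functional ortholog.

    Reference exons are paired collinearly with candidate exons by best
    identity; a reference exon is *missing* when unpaired (best identity
    below ``identity_floor``) and *incomplete* when its aligned coverage is
    below ``coverage_floor``.  Indel runs whose length is not a multiple of 3
    are frameshifts; an exon whose cumulative CDS offset differs from the
    reference's by a non-multiple of 3 is shifted.  ORF flags come from
    scanning the spliced candidate CDS.
    """
    reference_cds = reference_cds.upper()
    if sum(reference_exon_lengths) != len(reference_cds):
        raise ValueError("reference exon lengths do not sum to the CDS length")
    ref_scan = scan_orf(reference_cds)
    if ref_scan.premature_stops:
        raise ValueError("reference CDS has internal stop codons; not a functional ortholog")

    cand_seqs = exon_sequences(candidate, contig)
    ref_seqs = []
    pos = 0
    for ln in reference_exon_lengths:
        ref_seqs.append(reference_cds[pos:pos + ln])
        pos += ln

    pairs, stats = _pair_exons(cand_seqs, ref_seqs, identity_floor)
    if not pairs:
        return DisruptionReport(gene_id=candidate.id, verdict="unresolvable")

    matched_refs = {j for _, j in pairs}
    missing = tuple(j for j in range(len(ref_seqs)) if j not in matched_refs)

    cand_offsets = [0]
    for s in cand_seqs:
        cand_offsets.append(cand_offsets[-1] + len(s))
    ref_offsets = [0]
    for ln in reference_exon_lengths:
        ref_offsets.append(ref_offsets[-1] + ln)

    frameshifts: list[tuple[int, int]] = []
    shifted: list[tuple[int, int]] = []
    incomplete: list[int] = []
    for ci, rj in pairs:
        identity, coverage, indels = stats[(ci, rj)]
        if coverage < coverage_floor:
            incomplete.append(rj)
        for pos_in_exon, length in indels:
            if length % 3 != 0:
                frameshifts.append((cand_offsets[ci] + pos_in_exon, length % 3))
        offset = cand_offsets[ci] - ref_offsets[rj]
        if offset % 3 != 0:
            shifted.append((rj, offset))

    orf = scan_orf(splice_cds(candidate, contig))
    report = DisruptionReport(
        gene_id=candidate.id,
        lost_start=orf.lost_start,
        lost_stop=orf.lost_stop,
        premature_stops=orf.premature_stops,
        frameshifts=tuple(frameshifts),
        missing_exons=missing,
        shifted_exons=tuple(shifted),
        incomplete_exons=tuple(incomplete),
        terminal_frameshift=orf.terminal_frameshift,
    )
    verdict = "pseudogene" if report.disruptions else "functional"
    return DisruptionReport(**{**report.__dict__, "verdict": verdict})


# ---------------------------------------------------------------------------
# flat-file interfaces

def read_contigs_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (genes with exon children via Parent=).

    Handles the flat gene/exon subset this pipeline emits; 1-based closed
    coordinates are converted to 0-based half-open.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {"contig": contig, "strand": strand, "exons": []}
            elif ftype == "exon":
                parent = attr["Parent"]
                if parent not in genes:
                    genes[parent] = {"contig": contig, "strand": strand, "exons": []}
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        exons = sorted(g["exons"], reverse=(g["strand"] == "-"))
        models.append(
            GeneModel(id=gid, exons=tuple(exons), strand=g["strand"], contig_id=g["contig"])
        )
    return models


def write_gff3_genes(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(
                f"{m.contig_id}\tgekkota\tgene\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\tID={m.id}\n"
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.contig_id}\tgekkota\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\tParent={m.id}\n"
                )


def write_disruption_table(reports: Iterable[DisruptionReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "gene", "verdict", "lost_start", "lost_stop", "premature_stops",
            "frameshifts", "missing_exons", "shifted_exons", "incomplete_exons",
            "terminal_frameshift",
        ])
        for r in reports:
            writer.writerow([
                r.gene_id, r.verdict, int(r.lost_start), int(r.lost_stop),
                ",".join(map(str, r.premature_stops)) or "-",
                ",".join(f"{p}:{m}" for p, m in r.frameshifts) or "-",
                ",".join(map(str, r.missing_exons)) or "-",
                ",".join(f"{j}:{o}" for j, o in r.shifted_exons) or "-",
                ",".join(map(str, r.incomplete_exons)) or "-",
                int(r.terminal_frameshift),
            ])
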