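"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume, not the
biology in full detail:

* ``simulate_family`` grows a gene family by a forward birth-death process
  (duplication rate lambda, loss rate mu, over T Myr), evolving protein
  sequences site-wise under a single-parameter equal-rates model at clock
  rate r subst/site/Myr, with motif columns slowed by a conservation factor
  c (c = 0 freezes the motif).  True duplication ages of surviving nodes are
  the planted truth for classification and dating.
* ``simulate_codon_pair`` runs a continuous-time mutation-selection walk per
  codon: nucleotide proposals with transition bias kappa, stop codons
  rejected, nonsynonymous changes accepted at relative rate omega.  Realised
  synonymous/nonsynonymous counts are returned, making it an independent
  oracle for NG86 estimation.  Time t is expected substitutions per codon
  site under neutrality; each lineage evolves t/2.
* ``inject_disruptions`` plants start/stop losses, frameshifts, exon
  deletions and exon shifts into a gene model + contig, mirroring the edits
  in a truth record.
* ``simulate_expression`` builds a 4-timepoint (0/1/3/7 day) expression
  table with a planted upregulated subset.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .proteins import STANDARD_RESIDUES, ProteinRecord
from .pseudogene import GeneModel, splice_cds
from .selection import GENETIC_CODE, SENSE_CODONS, STOP_CODONS, CodonAlignment

__all__ = [
    "FamilySimConfig",
    "FamilySimResult",
    "CodonSimConfig",
    "Disruption",
    "simulate_family",
    "make_clock_tree",
    "make_setae_root",
    "random_background_proteins",
    "simulate_codon_pair",
    "inject_disruptions",
    "simulate_expression",
    "write_truth_table",
]


# ---------------------------------------------------------------------------
# gene-family birth-death simulation

@dataclass(frozen=True)
class FamilySimConfig:
    """Birth-death family simulation parameters.

    Rates are per lineage per Myr; ``clock_rate`` is substitutions/site/Myr;
    ``motif_conservation`` scales the motif columns' rate (0 freezes them).
    """

    birth_rate: float
    death_rate: float
    time: float
    clock_rate: float
    motif_conservation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.birth_rate, self.death_rate, self.time, self.clock_rate) < 0:
            raise ValueError("rates and time must be non-negative")
        if not (0.0 <= self.motif_conservation <= 1.0):
            raise ValueError("motif conservation factor must be in [0, 1]")


@dataclass(frozen=True)
class FamilySimResult:
    tree: dendropy.Tree
    records: tuple[ProteinRecord, ...]
    duplication_ages: tuple[float, ...]


class ExtinctFamilyError(RuntimeError):
    """All lineages died before the present in every attempt."""


_RESIDUES = np.frombuffer(STANDARD_RESIDUES.encode(), dtype="S1").astype("U1")


def _evolve_protein(
    seq: np.ndarray,
    duration: float,
    cfg: FamilySimConfig,
    motif_span: tuple[int, int] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Site-wise Poisson substitution under equal rates; motif slowed by c."""
    seq = seq.copy()
    rates = np.full(len(seq), cfg.clock_rate)
    if motif_span is not None:
        rates[motif_span[0]: motif_span[1]] *= cfg.motif_conservation
    hits = rng.poisson(rates * duration)
    for i in np.nonzero(hits)[0]:
        for _ in range(hits[i]):
            choices = _RESIDUES[_RESIDUES != seq[i]]
            seq[i] = rng.choice(choices)
    return seq


def simulate_family(
    config: FamilySimConfig,
    root_protein: str,
    motif_span: tuple[int, int] | None = None,
    max_retries: int = 100,
) -> FamilySimResult:
    """Forward birth-death simulation of a protein family.

    Returns the reconstructed tree over surviving lineages (branch lengths in
    substitutions/site), the leaf proteins, and the true ages (Myr) of the
    duplication nodes present in that tree.  Retries on total extinction up
    to ``max_retries`` before raising :class:`ExtinctFamilyError`.
    """
    rng = np.random.default_rng(config.seed)
    root_arr = np.array(list(root_protein.upper()), dtype="U1")
    total = config.birth_rate + config.death_rate
    counter = [0]

    def grow(start_age: float, seq: np.ndarray):
        """Returns (node, leaf_records, dup_ages) or None if extinct."""
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        event_age = start_age - wait
        if event_age <= 0:  # survives to the present
            leaf_seq = _evolve_protein(seq, start_age, config, motif_span, rng)
            counter[0] += 1
            name = f"L{counter[0]:04d}"
            node = dendropy.Node()
            node.age_myr = 0.0
            node._leaf_name = name
            node.edge.length = start_age * config.clock_rate
            rec = ProteinRecord(id=name, sequence="".join(leaf_seq), source="simulated")
            return node, [rec], []
        if rng.random() < config.birth_rate / total:  # duplication
            seq_here = _evolve_protein(seq, wait, config, motif_span, rng)
            left = grow(event_age, seq_here)
            right = grow(event_age, seq_here)
            children = [c for c in (left, right) if c is not None]
            if not children:
                return None
            if len(children) == 1:  # collapse through the dead side
                node, recs, dups = children[0]
                node.edge.length += wait * config.clock_rate
                return node, recs, dups
            node = dendropy.Node()
            node.age_myr = event_age
            node.edge.length = wait * config.clock_rate
            recs, dups = [], [event_age]
            for child, crecs, cdups in children:
                node.add_child(child)
                recs.extend(crecs)
                dups.extend(cdups)
            return node, recs, dups
        return None  # death

    for attempt in range(max_retries):
        counter[0] = 0
        result = grow(config.time, root_arr)
        if result is not None:
            break
    else:
        raise ExtinctFamilyError(f"family extinct in {max_retries} attempts")

    root_node, records, dup_ages = result
    root_node.edge.length = None
    tree = dendropy.Tree(seed_node=root_node)
    tree.is_rooted = True
    ns = tree.taxon_namespace
    for leaf in tree.leaf_node_iter():
        leaf.taxon = ns.new_taxon(leaf._leaf_name)
    return FamilySimResult(
        tree=tree,
        records=tuple(records),
        duplication_ages=tuple(sorted(dup_ages, reverse=True)),
    )


def make_clock_tree(
    duplication_ages: Sequence[float], rate: float
) -> dendropy.Tree:
    """Deterministic ultrametric caterpillar tree with duplications at the
    given ages (Myr, descending) and branch lengths in substitutions/site
    (= duration x rate).  Leaves are named T01, T02, ..."""
    ages = sorted(duplication_ages, reverse=True)
    if not ages or rate <= 0:
        raise ValueError("need at least one age and a positive rate")
    tree = dendropy.Tree()
    tree.is_rooted = True
    ns = tree.taxon_namespace
    leaf_i = [0]

    def new_leaf(parent_age: float) -> dendropy.Node:
        leaf_i[0] += 1
        node = dendropy.Node()
        node.taxon = ns.new_taxon(f"T{leaf_i[0]:02d}")
        node.edge.length = parent_age * rate
        node.age_myr = 0.0
        return node

    current = tree.seed_node
    current.age_myr = ages[0]
    for i, age in enumerate(ages):
        current.add_child(new_leaf(age))
        if i + 1 < len(ages):
            inner = dendropy.Node()
            inner.age_myr = ages[i + 1]
            inner.edge.length = (age - ages[i + 1]) * rate
            current.add_child(inner)
            current = inner
        else:
            current.add_child(new_leaf(age))
    return tree


def make_setae_root(
    length: int = 90,
    motif: str = "SEVTIQPPPCTVVVPGPVLA",
    motif_at: int = 30,
    cys_fraction: float = 0.12,
    seed: int = 0,
) -> tuple[str, tuple[int, int]]:
    """A setae-like root protein: random background with the core-box motif
    embedded and an elevated cysteine share.  Returns (sequence, motif span)."""
    rng = np.random.default_rng(seed)
    probs = np.full(20, (1.0 - cys_fraction) / 19)
    probs[STANDARD_RESIDUES.index("C")] = cys_fraction
    seq = list(rng.choice(_RESIDUES, size=length, p=probs))
    if motif_at + len(motif) > length:
        raise ValueError("motif does not fit at the requested position")
    seq[motif_at: motif_at + len(motif)] = list(motif)
    return "".join(seq), (motif_at, motif_at + len(motif))


def random_background_proteins(
    n: int, length: int = 90, seed: int = 0
) -> tuple[ProteinRecord, ...]:
    """Uniform-composition random proteins (no planted motif)."""
    rng = np.random.default_rng(seed)
    return tuple(
        ProteinRecord(
            id=f"B{i + 1:04d}",
            sequence="".join(rng.choice(_RESIDUES, size=length)),
            source="background",
        )
        for i in range(n)
    )


# ---------------------------------------------------------------------------
# codon-pair simulation

@dataclass(frozen=True)
class CodonSimConfig:
    """Mutation-selection codon walk parameters.

    ``t`` is the pair's expected substitutions per codon site under
    neutrality (each lineage runs t/2); ``kappa`` is the
    transition/transversion rate ratio (1 = unbiased, the regime the NG86
    estimator assumes); ``omega`` the relative acceptance rate of
    nonsynonymous changes.
    """

    omega: float
    kappa: float = 1.0
    t: float = 0.3
    length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.omega < 0 or self.kappa <= 0 or self.t < 0 or self.length < 1:
            raise ValueError("invalid codon simulation parameters")


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: per sense codon: (targets, per-event neutral weights, is_synonymous flags)
_CODON_EVENTS: dict[str, tuple[list[str], np.ndarray, np.ndarray]] = {}
for _codon in SENSE_CODONS:
    _targets, _weights, _syn = [], [], []
    for _pos in range(3):
        for _nt in "ACGT":
            if _nt == _codon[_pos]:
                continue
            _tgt = _codon[:_pos] + _nt + _codon[_pos + 1:]
            if _tgt in STOP_CODONS:
                continue
            _targets.append(_tgt)
            # sign marks transitions; resolved against kappa at walk time
            _weights.append(-1.0 if (_codon[_pos], _nt) in _TRANSITIONS else 1.0)
            _syn.append(GENETIC_CODE[_tgt] == GENETIC_CODE[_codon])
    _CODON_EVENTS[_codon] = (
        _targets, np.array(_weights), np.array(_syn, dtype=bool)
    )


def _evolve_codon(
    codon: str,
    duration: float,
    omega: float,
    kappa: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Gillespie walk of one codon; returns (codon, syn count, nonsyn count).

    Neutral rates are normalised so the whole codon's total rate is 1, i.e.
    each position contributes 1/3 (transversions 1/(3(kappa+2)) each, the
    transition kappa/(3(kappa+2))); ``duration`` is therefore in expected
    neutral substitutions per codon site.
    """
    syn_n = nonsyn_n = 0
    t = 0.0
    norm = 3.0 * (kappa + 2.0)
    while True:
        targets, signed, is_syn = _CODON_EVENTS[codon]
        rates = np.where(signed < 0, kappa / norm, 1.0 / norm)
        rates = np.where(is_syn, rates, rates * omega)
        total = rates.sum()
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > duration:
            break
        k = rng.choice(len(targets), p=rates / total)
        if is_syn[k]:
            syn_n += 1
        else:
            nonsyn_n += 1
        codon = targets[k]
    return codon, syn_n, nonsyn_n


def simulate_codon_pair(
    config: CodonSimConfig,
) -> tuple[CodonAlignment, dict[str, int]]:
    """Simulate a diverged in-frame CDS pair from a random sense-codon
    ancestor; returns the pair and the realised substitution counts."""
    rng = np.random.default_rng(config.seed)
    sense = sorted(SENSE_CODONS)
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=config.length)]
    half = config.t / 2.0
    seqs = []
    syn_total = nonsyn_total = 0
    for _ in range(2):
        out = []
        for codon in ancestor:
            c, s, n = _evolve_codon(codon, half, config.omega, config.kappa, rng)
            out.append(c)
            syn_total += s
            nonsyn_total += n
        seqs.append("".join(out))
    aln = CodonAlignment(ids=("seq1", "seq2"), seqs=tuple(seqs))
    return aln, {"synonymous": syn_total, "nonsynonymous": nonsyn_total}


# ---------------------------------------------------------------------------
# pseudogene disruption injection

@dataclass(frozen=True)
class Disruption:
    """One requested defect.

    kind: start_loss | stop_loss | frameshift | delete_exon | shift_exon.
    ``position`` is a CDS coordinate (frameshift); ``exon`` a transcript-order
    exon index; ``shift`` the bp truncated from an exon's 5' end (shift_exon)
    or inserted (frameshift, default 1).
    """

    kind: str
    position: int = 0
    exon: int = 0
    shift: int = 1


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _cds_to_genomic(model: GeneModel, cds_pos: int) -> tuple[int, bool]:
    """Map a CDS coordinate to (genomic position, needs_complement)."""
    offset = cds_pos
    for s, e in model.exons:
        ln = e - s
        if offset < ln:
            if model.strand == "+":
                return s + offset, False
            return e - 1 - offset, True
        offset -= ln
    raise ValueError(f"CDS position {cds_pos} beyond CDS of length {model.cds_length}")


def inject_disruptions(
    model: GeneModel,
    contig: str,
    disruptions: Sequence[Disruption],
) -> tuple[GeneModel, str, list[dict]]:
    """Apply the requested defects exactly once each.

    Returns the mutated (model, contig) and a truth record mirroring the
    request.  Conflicting edits at one CDS position raise ``ValueError``.
    """
    contig = contig.upper()
    cds = splice_cds(model, contig)
    touched: set[int] = set()
    subs: list[tuple[int, str]] = []        # (cds position, new base)
    insertions: list[tuple[int, str]] = []  # (genomic position, bases)
    exon_deletes: list[int] = []
    exon_shifts: list[tuple[int, int]] = []
    truth: list[dict] = []

    def claim(pos: int) -> None:
        if pos in touched:
            raise ValueError(f"conflicting edits at CDS position {pos}")
        touched.add(pos)

    for d in disruptions:
        if d.kind == "start_loss":
            if cds[:3] != "ATG":
                raise ValueError("gene does not start with ATG")
            claim(0)
            subs.append((0, "G"))  # ATG -> GTG
            truth.append({"kind": "start_loss", "cds_position": 0})
        elif d.kind == "stop_loss":
            last = len(cds) - 3
            if cds[last:] not in ("TAA", "TAG", "TGA"):
                raise ValueError("gene does not end with a stop codon")
            claim(last)
            subs.append((last, "C"))  # TAA/TAG/TGA -> CAA/CAG/CGA
            truth.append({"kind": "stop_loss", "cds_position": last})
        elif d.kind == "frameshift":
            if not (0 < d.position < len(cds)):
                raise ValueError(f"frameshift position {d.position} outside CDS")
            claim(d.position)
            gpos, comp = _cds_to_genomic(model, d.position)
            bases = "A" * d.shift
            insertions.append((gpos, bases.translate(_COMPLEMENT) if comp else bases))
            truth.append({
                "kind": "frameshift", "cds_position": d.position,
                "indel_mod3": d.shift % 3,
            })
        elif d.kind == "delete_exon":
            if not (0 <= d.exon < len(model.exons)):
                raise ValueError(f"no exon {d.exon}")
            exon_deletes.append(d.exon)
            truth.append({"kind": "delete_exon", "exon": d.exon})
        elif d.kind == "shift_exon":
            s, e = model.exons[d.exon]
            if d.shift >= e - s:
                raise ValueError("shift would remove the whole exon")
            exon_shifts.append((d.exon, d.shift))
            truth.append({"kind": "shift_exon", "exon": d.exon, "offset_bp": d.shift})
        else:
            raise ValueError(f"unknown disruption kind {d.kind!r}")

    new_contig = list(contig)
    for cds_pos, base in subs:
        gpos, comp = _cds_to_genomic(model, cds_pos)
        new_contig[gpos] = base.translate(_COMPLEMENT) if comp else base
    exons = [list(x) for x in model.exons]
    for gpos, bases in sorted(insertions, reverse=True):
        new_contig[gpos + 1: gpos + 1] = list(bases)
        for ex in exons:
            if ex[0] > gpos:
                ex[0] += len(bases)
            if ex[1] > gpos + 1:
                ex[1] += len(bases)
    for idx, k in exon_shifts:
        if model.strand == "+":
            exons[idx][0] += k
        else:
            exons[idx][1] -= k
    for idx in sorted(set(exon_deletes), reverse=True):
        del exons[idx]
    new_model = replace(model, exons=tuple(tuple(x) for x in exons))
    return new_model, "".join(new_contig), truth


# ---------------------------------------------------------------------------
# expression table

def simulate_expression(
    n_genes: int,
    planted_up_ids: Iterable[str],
    fold: float = 2.0,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression table over genes G0001..G{n}; planted genes reach >= fold
    times their day-0 baseline at one random post-autotomy timepoint.

    With ``noise_cv = 0`` unplanted genes are exactly flat and planted genes
    hit exactly ``fold``, so the overlap statistic recovers the planted
    fraction exactly.
    """
    if fold <= 1.0:
        raise ValueError("fold must exceed 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    planted = set(planted_up_ids)
    unknown = planted - set(genes)
    if unknown:
        raise ValueError(f"planted ids not in gene set: {sorted(unknown)}")
    rows = []
    for g in genes:
        base = float(rng.lognormal(mean=3.0, sigma=0.8))
        values = {"d0": base}
        for tp in ("d1", "d3", "d7"):
            noise = 1.0 + noise_cv * float(rng.standard_normal()) if noise_cv else 1.0
            values[tp] = base * max(noise, 0.0)
        if g in planted:
            tp = ("d1", "d3", "d7")[rng.integers(0, 3)]
            bump = 1.0 + abs(noise_cv * float(rng.standard_normal()))
            values[tp] = base * fold * bump
        rows.append({"gene": g, **values})
    return pd.DataFrame(rows).set_index("gene")


def write_truth_table(rows: Iterable[dict], path: str | Path) -> None:
    """Machine-readable truth sidecar (TSV; union of row keys as columns)."""
    rows = list(rows)
    keys: list[str] = []
    for r in rows:
        for k in r:
            if k not in keys:
                keys.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=keys, delimiter="\t", restval="-", lineterminator="\n"
        )
        writer.writeheader()
        writer.writerows(rows)
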