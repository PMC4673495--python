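"""Orchestration of the three gecko adaptive-evolution analyses.

Each runner chains library stages over flat files so every intermediate is
inspectable, writes atomically (temp file + rename), and emits a resolved
copy of its configuration next to the outputs.  Outputs carry a header with
the tool version and resolved parameters; reruns with the same inputs and
seed are byte-identical (no timestamps anywhere).

* ``run_keratin_analysis`` — classify beta-keratins, build/load the family
  tree, fit a calibrated clock rate, and date expansion bursts.
* ``run_vision_olfaction_analysis`` — pseudogene-scan candidate gene models
  and assign subgroup labels to query sequences by reference placement.
* ``run_regeneration_analysis`` — block-filter ortholog alignments, screen
  for Ka/Ks > threshold, and overlap the candidates with post-autotomy
  expression.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Any, Callable, Mapping

import yaml

from . import __version__
from .keratin import (
    ClassifierThresholds, CoreBoxMotif, classify_keratin, summarize_family,
)
from .phylo import (
    ReferenceSeq, classify_by_placement, date_expansions, fit_rate,
    neighbor_joining, pairwise_distance, read_calibrations, read_tree,
    write_tree,
)
from .proteins import read_protein_fasta
from .pseudogene import (
    compare_to_functional, read_contigs_fasta, read_gff3_genes,
)
from .selection import (
    expression_overlap, read_codon_fasta, read_expression_table, screen_psg,
)

__all__ = [
    "run_keratin_analysis",
    "run_vision_olfaction_analysis",
    "run_regeneration_analysis",
    "run_pipeline",
]

log = logging.getLogger("gekkota")

KERATIN_DEFAULTS: dict[str, Any] = {
    "proteins": None,          # protein FASTA (required)
    "alignment": None,         # aligned protein FASTA (to build a tree)
    "tree": None,              # newick (alternative to alignment)
    "calibrations": None,      # YAML calibration blocks
    "clade": None,             # leaf names; default: flag-1 records
    "max_gap": 5.0,
    "distance_model": "p",
    "motif": CoreBoxMotif().sequence,
    "min_identity": 70.0,
    "cys": 0.10,
    "gly": 0.15,
    "pi": 7.0,
    "max_mw": 15000.0,
    "interval_mode": "midpoint",
    "seed": 0,
}

VISION_DEFAULTS: dict[str, Any] = {
    "candidates_gff": None,        # GFF3 gene models (required)
    "contigs": None,               # contig FASTA (required)
    "reference_cds": None,         # FASTA, one functional CDS per gene id
    "reference_exons": None,       # TSV: gene <tab> comma-separated exon lengths
    "references_aligned": None,    # FASTA, ids "name|label" (placement refs)
    "queries_aligned": None,       # FASTA of aligned queries
    "identity_floor": 0.5,
    "coverage_floor": 0.8,
    "distance_model": "p",
    "seed": 0,
}

REGEN_DEFAULTS: dict[str, Any] = {
    "genes_dir": None,            # directory of per-gene aligned CDS FASTA
    "expression": None,           # TSV gene,d0,d1,d3,d7 (optional)
    "threshold": 1.0,
    "min_codons": 30,
    "fold_threshold": 2.0,
    "filter": True,
    "min_conserved_fraction": 0.5,
    "max_gap_fraction": 0.2,
    "min_block_codons": 3,
    "seed": 0,
}


def _resolve(config: Mapping[str, Any], defaults: Mapping[str, Any]) -> dict[str, Any]:
    unknown = set(config) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return {**defaults, **config}


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header(params: Mapping[str, Any]) -> str:
    items = " ".join(f"{k}={params[k]}" for k in sorted(params))
    return f"# gekkota v{__version__} | {items}\n"


def _dump_config(resolved: Mapping[str, Any], outdir: Path, name: str) -> None:
    _atomic_write(
        outdir / name,
        yaml.safe_dump({k: resolved[k] for k in sorted(resolved)}, sort_keys=False),
    )


def run_keratin_analysis(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    cfg = _resolve(config, KERATIN_DEFAULTS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not cfg["proteins"]:
        raise ValueError("keratin analysis requires a protein FASTA")
    records = read_protein_fasta(cfg["proteins"])
    if not records:
        raise ValueError(f"no records in {cfg['proteins']}")

    motif = CoreBoxMotif(sequence=cfg["motif"], similarity_threshold=cfg["min_identity"])
    thresholds = ClassifierThresholds(
        min_identity=cfg["min_identity"], cys_fraction=cfg["cys"],
        gly_fraction=cfg["gly"], pi=cfg["pi"], max_mw=cfg["max_mw"],
    )
    profiles = [classify_keratin(r, motif, thresholds) for r in records]
    summary = summarize_family(profiles)

    head = _header({k: cfg[k] for k in ("motif", "min_identity", "cys", "gly", "pi", "max_mw")})
    lines = [head, "id\tcorebox_pct\tflags\tlabel\tmw\tpI\tfrac_C\tfrac_G\n"]
    for p in profiles:
        prof = p.property_profile
        flags = ",".join(str(f) for f in sorted(p.flags)) or "-"
        lines.append(
            f"{p.record_id}\t{p.corebox_pct:.2f}\t{flags}\t{p.label}\t"
            f"{prof.mol_weight:.2f}\t{prof.pI:.4f}\t"
            f"{prof.fractions['C']:.6f}\t{prof.fractions['G']:.6f}\n"
        )
    _atomic_write(outdir / "classification.tsv", "".join(lines))

    result: dict[str, Any] = {"summary": summary, "profiles": profiles}
    tree = None
    if cfg["tree"]:
        tree = read_tree(cfg["tree"])
    elif cfg["alignment"]:
        aligned = read_protein_fasta(cfg["alignment"])
        ids_seqs = [(r.id, r.sequence) for r in aligned]
        ids, mat = pairwise_distance(ids_seqs, model=cfg["distance_model"])
        tree = neighbor_joining(ids, mat)
        write_tree(tree, outdir / "tree.nwk")

    if tree is not None and cfg["calibrations"]:
        calibrations = read_calibrations(cfg["calibrations"])
        rate = fit_rate(tree, calibrations, interval_mode=cfg["interval_mode"])
        clade = cfg["clade"]
        if clade is None:
            leaf_names = {l.taxon.label for l in tree.leaf_node_iter()}
            clade = [p.record_id for p in profiles if 1 in p.flags and p.record_id in leaf_names]
        report = date_expansions(tree, rate, clade, max_gap=cfg["max_gap"])
        body = [_header({"rate": f"{rate:.6g}", "max_gap": cfg["max_gap"]})]
        body.append("kind\tstart_myr\tend_myr\tcount\n")
        for start, end, count in report.bursts:
            body.append(f"burst\t{start:.3f}\t{end:.3f}\t{count}\n")
        for age in report.singletons:
            body.append(f"singleton\t{age:.3f}\t{age:.3f}\t1\n")
        _atomic_write(outdir / "expansion.tsv", "".join(body))
        result.update({"rate": rate, "expansion": report})
    elif tree is not None:
        log.warning("no calibrations supplied; expansion dating skipped")

    _dump_config(cfg, outdir, "resolved_config.keratin.yaml")
    return result


def run_vision_olfaction_analysis(
    config: Mapping[str, Any], outdir: str | Path
) -> dict[str, Any]:
    cfg = _resolve(config, VISION_DEFAULTS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result: dict[str, Any] = {}

    if cfg["candidates_gff"]:
        from Bio import SeqIO

        contigs = read_contigs_fasta(cfg["contigs"])
        models = read_gff3_genes(cfg["candidates_gff"])
        ref_cds = {
            r.id: str(r.seq).upper()
            for r in SeqIO.parse(str(cfg["reference_cds"]), "fasta")
        }
        ref_exons: dict[str, list[int]] = {}
        with open(cfg["reference_exons"]) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene, lengths = line.split("\t")
                ref_exons[gene] = [int(x) for x in lengths.split(",")]
        reports = []
        for model in models:
            if model.id not in ref_cds:
                log.warning("no reference CDS for %s; skipped", model.id)
                continue
            try:
                reports.append(
                    compare_to_functional(
                        model, contigs[model.contig_id],
                        ref_cds[model.id], ref_exons[model.id],
                        identity_floor=cfg["identity_floor"],
                        coverage_floor=cfg["coverage_floor"],
                    )
                )
            except (ValueError, KeyError) as exc:  # per-gene failure; run continues
                log.warning("pseudoscan failed for %s: %s", model.id, exc)
        head = _header({k: cfg[k] for k in ("identity_floor", "coverage_floor")})
        lines = [head, "gene\tverdict\tlost_start\tlost_stop\tpremature_stops\t"
                       "frameshifts\tmissing_exons\tshifted_exons\tincomplete_exons\n"]
        for r in sorted(reports, key=lambda r: r.gene_id):
            lines.append(
                f"{r.gene_id}\t{r.verdict}\t{int(r.lost_start)}\t{int(r.lost_stop)}\t"
                f"{','.join(map(str, r.premature_stops)) or '-'}\t"
                f"{','.join(f'{p}:{m}' for p, m in r.frameshifts) or '-'}\t"
                f"{','.join(map(str, r.missing_exons)) or '-'}\t"
                f"{','.join(f'{j}:{o}' for j, o in r.shifted_exons) or '-'}\t"
                f"{','.join(map(str, r.incomplete_exons)) or '-'}\n"
            )
        _atomic_write(outdir / "disruptions.tsv", "".join(lines))
        result["disruptions"] = reports

    if cfg["references_aligned"] and cfg["queries_aligned"]:
        refs = [
            ReferenceSeq(id=r.id.split("|")[0], label=r.id.split("|")[1], sequence=r.sequence)
            for r in read_protein_fasta(cfg["references_aligned"])
        ]
        placements = {}
        for q in read_protein_fasta(cfg["queries_aligned"]):
            placements[q.id] = classify_by_placement(
                q.sequence, refs, model=cfg["distance_model"]
            )
        lines = [_header({"distance_model": cfg["distance_model"]}),
                 "query\tlabel\tsupport\tnearest\tdistance\n"]
        counts: dict[str, int] = {}
        for qid in sorted(placements):
            p = placements[qid]
            counts[p.label] = counts.get(p.label, 0) + 1
            lines.append(
                f"{qid}\t{p.label}\t{p.support:.6g}\t{p.nearest_id}\t{p.distance:.6g}\n"
            )
        _atomic_write(outdir / "placements.tsv", "".join(lines))
        count_lines = [_header({}), "label\tcount\n"] + [
            f"{label}\t{n}\n" for label, n in sorted(counts.items())
        ]
        _atomic_write(outdir / "class_counts.tsv", "".join(count_lines))
        result["placements"] = placements

    _dump_config(cfg, outdir, "resolved_config.vision.yaml")
    return result


def run_regeneration_analysis(
    config: Mapping[str, Any], outdir: str | Path
) -> dict[str, Any]:
    cfg = _resolve(config, REGEN_DEFAULTS)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not cfg["genes_dir"]:
        raise ValueError("regeneration analysis requires a gene alignment directory")

    orthologs = {}
    for path in sorted(Path(cfg["genes_dir"]).glob("*.fa*")):
        orthologs[path.stem] = read_codon_fasta(path)
    if not orthologs:
        raise ValueError(f"no gene alignments found in {cfg['genes_dir']}")

    filter_params = None
    if cfg["filter"]:
        filter_params = {
            "min_conserved_fraction": cfg["min_conserved_fraction"],
            "max_gap_fraction": cfg["max_gap_fraction"],
            "min_block_codons": cfg["min_block_codons"],
        }
    table, exclusions = screen_psg(
        orthologs, threshold=cfg["threshold"], min_codons=cfg["min_codons"],
        filter_params=filter_params,
    )
    head = _header({k: cfg[k] for k in ("threshold", "min_codons", "filter")})
    _atomic_write(
        outdir / "psg.tsv",
        head + table.to_csv(sep="\t", index=False, float_format="%.6g"),
    )
    if exclusions:
        _atomic_write(outdir / "exclusions.log", "".join(x + "\n" for x in exclusions))

    result: dict[str, Any] = {"psg_table": table, "exclusions": exclusions}
    if cfg["expression"]:
        expr = read_expression_table(cfg["expression"])
        overlap = expression_overlap(
            table["gene"].tolist(), expr, fold_threshold=cfg["fold_threshold"]
        )
        frac = "NA" if overlap.fraction is None else f"{overlap.fraction:.6g}"
        flag = "empty_psg_table" if overlap.denominator == 0 else "-"
        body = (
            _header({"fold_threshold": cfg["fold_threshold"]})
            + "numerator\tdenominator\tfraction\tflag\n"
            + f"{overlap.numerator}\t{overlap.denominator}\t{frac}\t{flag}\n"
        )
        _atomic_write(outdir / "overlap.tsv", body)
        result["overlap"] = overlap

    _dump_config(cfg, outdir, "resolved_config.regeneration.yaml")
    return result


_RUNNERS: dict[str, Callable[[Mapping[str, Any], Path], dict[str, Any]]] = {
    "keratin": run_keratin_analysis,
    "vision": run_vision_olfaction_analysis,
    "regeneration": run_regeneration_analysis,
}


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict[str, Any]:
    """Run the analysis named by the config file's ``analysis`` key."""
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    analysis = raw.pop("analysis", None)
    if analysis not in _RUNNERS:
        raise ValueError(f"config must set analysis to one of {sorted(_RUNNERS)}")
    outdir = Path(outdir if outdir is not None else raw.pop("outdir", "gekkota_out"))
    raw.pop("outdir", None)
    return _RUNNERS[analysis](raw, outdir)
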