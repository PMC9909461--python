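"""End-to-end orchestration: extract -> annotate -> harmonize -> downstream.

Stages communicate via plain-text files (FASTA/TSV/BED/SVG) so each stage
is independently runnable and auditable; ``run_landscape`` wires them into
one report bundle.  All thresholds and seeds are recorded in the output
directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import g4, mola, popgen
from .alignment import project_to_reference
from .extraction import AnchorPair, locate_gene
from .harmonize import LocusCatalog, assign_ids, summarize_catalog
from .repeats import annotate_gene
from .seqio import GeneInterval, read_fasta, write_bed, write_fasta, write_table
from .synthetic import default_cohort_spec, generate_cohort

logger = logging.getLogger("tandemscape")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All thresholds and seeds for a landscape run, serialized for provenance."""

    out_dir: str = "tandemscape_run"
    genes_fasta: str | None = None  # pre-extracted genes; else simulate
    contigs_fasta: str | None = None  # raw contigs needing anchor extraction
    anchor_5p: str | None = None
    anchor_3p: str | None = None
    simulate: bool = True
    seed: int = 1
    min_unit: int = 7
    max_unit: int = 200
    max_divergence: float = 0.05
    alpha: float = 0.05
    n_shuffles: int = 200
    maf_min: float = 0.05
    g4_window: int = 25
    g4_threshold: float = 1.6
    g4_bin_size: int = 500
    homopolymer_min_run: int = 4
    mola_seed: int = 7
    n_individuals: int = 32  # simulated cohort size
    n_invariant: int = 25  # simulated invariant locus count

    def __post_init__(self) -> None:
        if not (0 < self.max_divergence <= 1 and 0 < self.alpha <= 1):
            raise PipelineError("thresholds out of range")
        if not (0 <= self.maf_min < 0.5):
            raise PipelineError("maf_min out of range")
        if self.contigs_fasta is not None and not (self.anchor_5p and self.anchor_3p):
            raise PipelineError("contig extraction requires both anchors")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _load_genes(config: RunConfig, out: Path):
    """Obtain oriented gene sequences: simulate, load, or extract from contigs."""
    if config.contigs_fasta:
        anchors = AnchorPair(config.anchor_5p, config.anchor_3p)
        rows = []
        genes = []
        for header, contig in read_fasta(config.contigs_fasta):
            name = header.split()[0]
            interval, seq = locate_gene(contig, anchors, contig_name=name)
            genes.append((name, seq))
            rows.append(
                {"contig": name, "start": interval.start, "end": interval.end,
                 "strand": interval.strand, "length": len(seq)}
            )
        write_table(rows, out / "extraction_report.tsv", sort_by="contig")
        write_fasta(genes, out / "genes.fasta")
        return {name: seq for name, seq in genes}, None
    if config.genes_fasta:
        return {h.split()[0]: s for h, s in read_fasta(config.genes_fasta)}, None
    cohort = generate_cohort(
        default_cohort_spec(
            n_individuals=config.n_individuals, n_invariant=config.n_invariant
        ),
        seed=config.seed,
    )
    write_fasta(
        [(r.label, r.sequence) for r in cohort.records], out / "genes.fasta"
    )
    return cohort.sequences(), cohort


def run_landscape(config: RunConfig) -> dict:
    """Run every stage; returns a dict of output paths and headline numbers."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    config.dump(out / "config.yaml")
    report: dict = {"out_dir": str(out)}
    try:
        stage = "load"
        sequences, cohort = _load_genes(config, out)
        logger.info("loaded %d gene sequences", len(sequences))

        stage = "annotate"
        rng = np.random.default_rng(config.seed)
        per_hap = {}
        for lab in sorted(sequences):
            per_hap[lab] = annotate_gene(
                sequences[lab],
                min_unit=config.min_unit,
                max_unit=config.max_unit,
                max_divergence=config.max_divergence,
                alpha=config.alpha,
                n_shuffles=config.n_shuffles,
                seed=int(rng.integers(2**31)),
                contig=lab,
            )
        ann_rows = [
            {"haplotype": lab, "start": a.interval.start, "end": a.interval.end,
             "unit_length": a.unit_length, "copy_number": a.copy_number,
             "divergence": round(a.divergence, 4), "p_value": a.p_value,
             "consensus": a.consensus}
            for lab, anns in per_hap.items()
            for a in anns
        ]
        write_table(ann_rows, out / "repeats.tsv", sort_by="haplotype")
        write_bed(
            [(a.interval, f"{lab}:{a.unit_length}bp") for lab, anns in per_hap.items() for a in anns],
            out / "repeats.bed",
        )

        stage = "harmonize"
        catalog = assign_ids(per_hap, sequences)
        genotypes = popgen.genotype_table(catalog, on_missing="drop")
        het = {
            locus.tr_id: popgen.heterozygosity(genotypes, locus.tr_id)
            for locus in catalog.vntrs
            if not genotypes[genotypes["locus"] == locus.tr_id].empty
        }
        summary = summarize_catalog(catalog, het)
        write_table(summary, out / "catalog.tsv")
        cn_table = pd.DataFrame(
            {locus.tr_id: pd.Series(locus.copy_numbers()) for locus in catalog.vntrs}
        )
        cn_table.index.name = "haplotype"
        cn_table.to_csv(out / "copy_numbers.tsv", sep="\t")
        report["n_loci"] = len(catalog)
        report["n_vntr"] = len(catalog.vntrs)
        logger.info("catalog: %d loci, %d VNTRs", len(catalog), len(catalog.vntrs))

        stage = "mola"
        for locus in catalog.vntrs:
            multicolor = mola.build_multicolor(locus, seed=config.mola_seed)
            threecolor = mola.build_threecolor(locus)
            multicolor.write_svg(out / f"mola_{locus.tr_id}_multicolor.svg")
            threecolor.write_svg(out / f"mola_{locus.tr_id}_threecolor.svg")
            write_table(multicolor.to_table(), out / f"mola_{locus.tr_id}_cells.tsv")
            before, after = mola.homopolymer_sensitivity(
                locus, min_run=config.homopolymer_min_run
            )
            report.setdefault("unique_units", {})[locus.tr_id] = {
                "before_collapse": before, "after_collapse": after,
            }

        stage = "snps"
        ref_label = sorted(sequences)[0]
        if cohort is not None:
            ref_seq = cohort.template
            excluded = [
                GeneInterval("gene", *cohort.loci[nm].template_interval)
                for nm in cohort.vntr_names
            ]
        else:
            ref_seq = sequences[ref_label]
            excluded = [
                locus.annotations[ref_label].interval
                for locus in catalog.vntrs
                if ref_label in locus.annotations
            ]
        projections = {
            lab: project_to_reference(ref_seq, seq) for lab, seq in sequences.items()
        }
        variants = popgen.call_snps(
            projections, ref_seq, maf_min=config.maf_min, excluded_regions=excluded
        )
        write_table(variants.to_vcf_table(), out / "snps.tsv")
        report["n_snps"] = len(variants)

        stage = "ld"
        cn_frame = pd.DataFrame(
            {locus.tr_id: pd.Series(locus.copy_numbers()) for locus in catalog.vntrs}
        ).reindex(variants.haplotype_labels)
        ld = popgen.ld_matrix(variants, cn_frame)
        ld.to_frame().to_csv(out / "ld_matrix.tsv", sep="\t")

        stage = "g4"
        longest = max(sequences, key=lambda lab: len(sequences[lab]))
        params = g4.G4Params(
            window=config.g4_window, threshold=config.g4_threshold,
            bin_size=config.g4_bin_size,
        )
        profiles = []
        for tag, lab in (("reference", ref_label), ("longest", longest)):
            hits = g4.scan_g4(sequences[lab], params)
            prof = g4.g4_profile(hits, len(sequences[lab]), params)
            prof.insert(0, "sequence", lab)
            prof.insert(1, "role", tag)
            profiles.append(prof)
        write_table(pd.concat(profiles), out / "g4_profile.tsv")

        stage = "trio"
        if cohort is not None and cohort.trios:
            trio_rows = []
            for trio in cohort.trios:
                six = {r.label: r.sequence for r in trio.mother + trio.father + trio.child}
                trio_rng = np.random.default_rng(config.seed + 7919)
                trio_anns = {
                    lab: annotate_gene(
                        s, seed=int(trio_rng.integers(2**31)), contig=lab
                    )
                    for lab, s in sorted(six.items())
                }
                trio_catalog = assign_ids(trio_anns, six)
                results = popgen.trio_transmission(
                    {r.label: r.sequence for r in trio.child},
                    {r.label: r.sequence for r in trio.mother},
                    {r.label: r.sequence for r in trio.father},
                    trio_catalog,
                )
                for res in results:
                    for _, row in res.per_locus.iterrows():
                        trio_rows.append(
                            {"trio": trio.name, "child_hap": res.child_hap,
                             "parent": res.parent, "parent_hap": res.parent_hap,
                             "similarity_percent": round(res.similarity_percent, 3),
                             **row.to_dict()}
                        )
            write_table(trio_rows, out / "trio_report.tsv")
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
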