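"""End-to-end orchestration producing the summary report.

The report carries a per-sample novelty/region accounting matrix, the de novo
spectrum, candidate tables (de novo, compound het, homozygous recessive,
CNV segments), and the optional TEQ block.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import cnv as tcnv
from . import io as tio
from . import recessive as trec
from . import teq as tteq
from .annotate import (
    classify_region,
    cpg_context,
    most_severe_effect,
    transition_flag,
)
from .denovo import (
    DEFAULT_EDGE_MARGIN,
    DEFAULT_GENOME_LENGTH,
    QcThresholds,
    detect_denovo,
    spectrum,
)
from .io import KnownSitesCatalog, VariantCall

log = logging.getLogger(__name__)

REGION_ROWS = [
    "intronic",
    "exonic",
    "UTR5",
    "UTR3",
    "ncRNA_intronic",
    "ncRNA_exonic",
    "splicing",
    "intergenic",
]


@dataclass
class RunConfig:
    vcf: str
    reference: str
    genes: str
    out_dir: str
    dbsnp_sites: Optional[str] = None
    kg_sites: Optional[str] = None
    af_table: Optional[str] = None
    panel_sites: Optional[str] = None
    depth_table: Optional[str] = None
    congener_table: Optional[str] = None
    seed: int = 0
    min_dp: int = 10
    min_gq: int = 20
    edge_margin: int = DEFAULT_EDGE_MARGIN
    genome_length: int = DEFAULT_GENOME_LENGTH
    max_af: float = 0.01
    cbs_alpha: float = 0.01
    cbs_permutations: int = 1000
    cbs_min_width: int = 3
    tef_scheme: str = "who1998"
    nd_policy: str = "half"
    run_denovo: bool = True
    run_recessive: bool = True
    run_cnv: bool = True
    run_teq: bool = True

    def validate(self) -> None:
        for path in (self.vcf, self.reference, self.genes):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        if not 0 <= self.max_af <= 1:
            raise ValueError("max_af outside [0,1]")
        if not 0 < self.cbs_alpha < 1:
            raise ValueError("cbs_alpha outside (0,1)")


def filter_known(
    variants: Sequence[VariantCall],
    dbsnp: Optional[KnownSitesCatalog],
    kg: Optional[KnownSitesCatalog],
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Disjoint partition (shared_dbsnp, shared_1000g, novel), dbSNP first."""
    in_db: list[VariantCall] = []
    in_kg: list[VariantCall] = []
    novel: list[VariantCall] = []
    for v in variants:
        if dbsnp is not None and v.key in dbsnp:
            in_db.append(v)
        elif kg is not None and v.key in kg:
            in_kg.append(v)
        else:
            novel.append(v)
    return in_db, in_kg, novel


def _variant_matrix(
    variants: Sequence[VariantCall],
    dbsnp: Optional[KnownSitesCatalog],
    kg: Optional[KnownSitesCatalog],
    models,
    samples: Sequence[str] = tio.TRIO_SAMPLES,
) -> dict:
    """Per-sample counts by variant type, novelty, and region (novel only)."""
    matrix: dict = {}
    for vtype_label, keep in (("SNV", True), ("indel", False)):
        per_sample = {}
        for sample in samples:
            carried = [
                v for v in variants if v.has_alt(sample) and (v.is_snv == keep)
            ]
            in_db, in_kg, novel = filter_known(carried, dbsnp, kg)
            regions = {row: 0 for row in REGION_ROWS}
            for v in novel:
                regions[classify_region(v, models)] += 1
            per_sample[sample] = {
                "total": len(carried),
                "shared_dbsnp": len(in_db),
                "shared_1000g": len(in_kg),
                "novel": len(novel),
                "novel_by_region": regions,
            }
        matrix[vtype_label] = per_sample
    return matrix


def _annotate_for_recessive(variants, models, reference) -> list[trec.AnnotatedVariant]:
    out = []
    for v in variants:
        hit = most_severe_effect(v, models, reference)
        if hit is None:
            continue
        gene, effect = hit
        out.append(trec.AnnotatedVariant(variant=v, gene=gene, effect=effect))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write report.json plus TSV tables.

    A stage failure aborts the run with the failing stage named; outputs are
    written only after every enabled stage has succeeded.
    """
    config.validate()
    report: dict = {"seed": config.seed}
    stage = "load"
    try:
        variants = tio.read_trio_vcf(config.vcf)
        reference = tio.read_fasta(config.reference)
        models = tio.read_gene_models(config.genes)
        dbsnp = (
            tio.read_known_sites(config.dbsnp_sites, "dbsnp")
            if config.dbsnp_sites
            else None
        )
        kg = (
            tio.read_known_sites(config.kg_sites, "1000g") if config.kg_sites else None
        )
        panel = (
            tio.read_known_sites(config.panel_sites, "panel")
            if config.panel_sites
            else None
        )
        af_records = trec.read_af_table(config.af_table) if config.af_table else None

        stage = "summary"
        report["variant_matrix"] = _variant_matrix(variants, dbsnp, kg, models)

        denovo_candidates = []
        if config.run_denovo:
            stage = "denovo"
            qc = QcThresholds(min_dp=config.min_dp, min_gq=config.min_gq)
            denovo_candidates = detect_denovo(
                variants,
                qc=qc,
                edge_margin=config.edge_margin,
                models=models,
                reference=reference,
            )
            spec = spectrum(denovo_candidates, genome_length=config.genome_length)
            report["denovo"] = {
                "n_candidates": len(denovo_candidates),
                "n_exonic": sum(1 for c in denovo_candidates if c.region == "exonic"),
                "by_region": _count_regions(denovo_candidates),
                "spectrum": spec.report(),
                "candidates": [
                    {
                        "contig": c.variant.contig,
                        "pos": c.variant.pos,
                        "ref": c.variant.ref,
                        "alt": c.variant.alt,
                        "region": c.region,
                        "is_cpg": c.is_cpg,
                        "is_transition": c.is_transition,
                    }
                    for c in denovo_candidates
                ],
            }

        if config.run_recessive:
            stage = "recessive"
            annotated = _annotate_for_recessive(variants, models, reference)
            comp = trec.find_compound_het(
                annotated, af_records, config.max_af, panel
            )
            hom = trec.find_homozygous_recessive(
                annotated, af_records, config.max_af, panel
            )
            report["recessive"] = {
                "compound_het_genes": sorted({c.gene for c in comp}),
                "n_compound_het_genes": len({c.gene for c in comp}),
                "compound_het": [
                    {
                        "gene": c.gene,
                        "paternal": _brief(c.paternal),
                        "maternal": _brief(c.maternal),
                    }
                    for c in comp
                ],
                "homozygous_recessive": [
                    {"gene": h.gene, **_brief(h.variant)} for h in hom
                ],
            }

        segments = []
        if config.run_cnv and config.depth_table:
            stage = "cnv"
            raw = tio.read_depth_table(config.depth_table)
            bins = tcnv.normalize_depth(raw)
            segments = tcnv.call_copy_states(
                bins,
                alpha=config.cbs_alpha,
                n_permutations=config.cbs_permutations,
                min_width=config.cbs_min_width,
                seed=config.seed,
            )
            hom_del = [
                s for s in segments if s.copy_state["proband"] == "hom_del"
            ]
            report["cnv"] = {
                "n_segments": len(segments),
                "hom_del_proband": [
                    {
                        "contig": s.contig,
                        "start": s.start,
                        "end": s.end,
                        "length": s.length,
                        "inheritance": tcnv.classify_inheritance(s),
                    }
                    for s in hom_del
                ],
            }

        if config.run_teq and config.congener_table:
            stage = "teq"
            df = tio.read_congener_table(config.congener_table)
            measurements = tteq.measurements_from_frame(df)
            result = tteq.compute_teq(
                measurements, scheme=config.tef_scheme, nd_policy=config.nd_policy
            )
            report["teq"] = result.report()
    except Exception as exc:  # noqa: BLE001 - reraise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_outputs(config, report, segments)
    return report


def _count_regions(candidates) -> dict:
    counts = {row: 0 for row in REGION_ROWS}
    for c in candidates:
        counts[c.region] += 1
    return counts


def _brief(av: trec.AnnotatedVariant) -> dict:
    return {
        "contig": av.variant.contig,
        "pos": av.variant.pos,
        "ref": av.variant.ref,
        "alt": av.variant.alt,
        "effect": av.effect.kind,
        "aa_change": av.effect.aa_change(),
    }


def _write_outputs(config: RunConfig, report: dict, segments) -> None:
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    matrix = report.get("variant_matrix", {})
    with open(os.path.join(config.out_dir, "table2.tsv"), "w") as fh:
        fh.write("vtype\trow\tfather\tmother\tproband\n")
        for vtype, per_sample in matrix.items():
            rows = ["total", "shared_dbsnp", "shared_1000g", "novel"]
            for row in rows:
                vals = [str(per_sample[s][row]) for s in tio.TRIO_SAMPLES]
                fh.write("\t".join([vtype, row] + vals) + "\n")
            for region in REGION_ROWS:
                vals = [
                    str(per_sample[s]["novel_by_region"][region])
                    for s in tio.TRIO_SAMPLES
                ]
                fh.write("\t".join([vtype, f"novel_{region}"] + vals) + "\n")
    if segments:
        tcnv.segments_to_frame(segments).to_csv(
            os.path.join(config.out_dir, "segments.tsv"), sep="\t", index=False
        )
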