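"""Seeded generator of Mendelian-consistent trio datasets with planted events.

Every pipeline stage is testable without external data: the simulator emits
a reference FASTA, a gene-model table, a trio VCF, per-sample depth bins,
population catalogs, and a machine-readable truth table listing exactly the
planted de novo, compound-heterozygous and CNV events.

Randomness is drawn from per-stage substreams derived from the master seed,
so adding events in one stage does not shuffle draws in another.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .annotate import CODON_TABLE, revcomp
from .io import GeneModel, KnownSitesCatalog, VariantCall

_BASES = "ACGT"
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

_STATE_FACTOR = {"hom_del": 0.0, "hemi": 0.5, "normal": 1.0, "gain": 1.5}

# substream indices of the master seed
_STAGE_REF, _STAGE_GENES, _STAGE_DENOVO, _STAGE_COMPHET, _STAGE_INHERITED, \
    _STAGE_DEPTH, _STAGE_READS = range(7)


@dataclass(frozen=True)
class CnvEvent:
    contig: str
    start: int  # 0-based half-open, bp
    end: int
    child_state: str
    parent_state: str


@dataclass
class SimulationConfig:
    seed: int
    contigs: list[tuple[str, int]]
    n_genes: int = 0
    n_inherited_variants: int = 0
    n_denovo_snv: int = 0
    n_denovo_indel: int = 0
    n_denovo_exonic: int = 0
    cpg_fraction: float = 0.0
    ts_fraction: float = 0.5
    compound_het_genes: int = 0
    cnv_events: list[CnvEvent] = field(default_factory=list)
    bin_size: int = 1000
    depth_mean: float = 30.0
    depth_noise_sd: float = 0.0
    read_length: int = 101
    inherited_indel_fraction: float = 0.1
    plant_tggac_deletion: bool = False

    def validate(self) -> None:
        lengths = dict(self.contigs)
        if not self.contigs:
            raise ValueError("at least one contig required")
        if self.n_denovo_exonic > self.n_denovo_snv + self.n_denovo_indel:
            raise ValueError("n_denovo_exonic exceeds total de novo events")
        if not 0 <= self.cpg_fraction <= 1 or not 0 <= self.ts_fraction <= 1:
            raise ValueError("fractions must lie in [0,1]")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        by_contig: dict[str, list[CnvEvent]] = {}
        for ev in self.cnv_events:
            if ev.contig not in lengths:
                raise ValueError(f"CNV on unknown contig {ev.contig}")
            if not (0 <= ev.start < ev.end <= lengths[ev.contig]):
                raise ValueError(f"CNV interval out of range: {ev}")
            if ev.child_state not in _STATE_FACTOR or ev.parent_state not in _STATE_FACTOR:
                raise ValueError(f"unknown copy state in {ev}")
            by_contig.setdefault(ev.contig, []).append(ev)
        for events in by_contig.values():
            events = sorted(events, key=lambda e: e.start)
            for a, b in zip(events, events[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping CNV events: {a} / {b}")


@dataclass
class DenovoTruth:
    contig: str
    pos: int
    ref: str
    alt: str
    is_exonic: bool
    is_cpg: Optional[bool]
    is_transition: Optional[bool]


@dataclass
class CompoundHetTruth:
    gene: str
    variants: list[tuple[str, int, str, str, str]]  # contig,pos,ref,alt,origin


@dataclass
class TruthTable:
    denovo_events: list[DenovoTruth] = field(default_factory=list)
    compound_het_events: list[CompoundHetTruth] = field(default_factory=list)
    cnv_events: list[CnvEvent] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "denovo_events": [asdict(d) for d in self.denovo_events],
                "compound_het_events": [asdict(c) for c in self.compound_het_events],
                "cnv_events": [asdict(c) for c in self.cnv_events],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthTable":
        raw = json.loads(text)
        return cls(
            denovo_events=[DenovoTruth(**d) for d in raw["denovo_events"]],
            compound_het_events=[
                CompoundHetTruth(
                    gene=c["gene"],
                    variants=[tuple(v) for v in c["variants"]],
                )
                for c in raw["compound_het_events"]
            ],
            cnv_events=[CnvEvent(**c) for c in raw["cnv_events"]],
        )


@dataclass
class TrioDataset:
    config: SimulationConfig
    reference: dict[str, str]
    models: list[GeneModel]
    variants: list[VariantCall]
    truth: TruthTable
    af_records: dict[tuple[str, int, str, str], dict[str, float]]
    dbsnp: KnownSitesCatalog
    kg: KnownSitesCatalog
    panel: KnownSitesCatalog

    def depth_bins(self) -> pd.DataFrame:
        return generate_depth_profile(self.config)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        tio.write_fasta(self.reference, os.path.join(outdir, "reference.fa"))
        tio.write_gene_models(self.models, os.path.join(outdir, "genes.tsv"))
        tio.write_trio_vcf(
            self.variants, os.path.join(outdir, "trio.vcf"), self.config.contigs
        )
        tio.write_known_sites(self.dbsnp, os.path.join(outdir, "sites_dbsnp.tsv"))
        tio.write_known_sites(self.kg, os.path.join(outdir, "sites_1000g.tsv"))
        tio.write_known_sites(self.panel, os.path.join(outdir, "panel.sites"))
        with open(os.path.join(outdir, "af.tsv"), "w") as fh:
            for (contig, pos, ref, alt), pops in sorted(self.af_records.items()):
                for pop, af in sorted(pops.items()):
                    fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{pop}\t{af:.6g}\n")
        tio.write_depth_table(self.depth_bins(), os.path.join(outdir, "depth.tsv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json() + "\n")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 42) -> SimulationConfig:
    """Named study-scale configurations.

    ``paper_trio`` plants 93 de novo heterozygous variants (92 SNVs plus the
    validated 5-bp TGGAC deletion), 3 of them exonic, 18 SNVs in CpG context
    and 62 transitions, plus 2 compound-heterozygous genes, among ≥10,000
    Mendelian-inherited sites. ``paper_cnv`` plants a 150-kb and a 10-kb
    child-homozygous / parent-hemizygous deletion on a 5-Mb contig.
    """
    if name == "paper_trio":
        return SimulationConfig(
            seed=seed,
            contigs=[("sim1", 800_000), ("sim2", 500_000)],
            n_genes=60,
            n_inherited_variants=12_000,
            n_denovo_snv=92,
            n_denovo_indel=1,
            n_denovo_exonic=3,
            cpg_fraction=18 / 92,
            ts_fraction=62 / 92,
            compound_het_genes=2,
            cnv_events=[],
            bin_size=1000,
            depth_mean=30.0,
            depth_noise_sd=0.0,
            plant_tggac_deletion=True,
        )
    if name == "paper_cnv":
        return SimulationConfig(
            seed=seed,
            contigs=[("cnv1", 5_000_000)],
            cnv_events=[
                CnvEvent("cnv1", 2_040_000, 2_190_000, "hom_del", "hemi"),
                CnvEvent("cnv1", 3_580_000, 3_590_000, "hom_del", "hemi"),
            ],
            bin_size=1000,
            depth_mean=30.0,
            depth_noise_sd=3.0,
        )
    raise KeyError(f"unknown preset {name!r}")


PRESET_NAMES = ("paper_trio", "paper_cnv")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _make_reference(config: SimulationConfig) -> dict[str, bytearray]:
    rng = _stage_rng(config, _STAGE_REF)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        name: bytearray(lut[rng.integers(0, 4, size=length)].tobytes())
        for name, length in config.contigs
    }


_MIN_GENE_SLOT = 4500  # worst-case gene span (4 exons × 300 + 3 introns × 800) + margin


def _make_genes(config: SimulationConfig) -> list[GeneModel]:
    if config.n_genes == 0:
        return []
    rng = _stage_rng(config, _STAGE_GENES)
    total = sum(length for _, length in config.contigs)
    models: list[GeneModel] = []
    gene_idx = 0
    remaining = config.n_genes
    for ci, (contig, length) in enumerate(config.contigs):
        if ci == len(config.contigs) - 1:
            n_here = remaining
        else:
            n_here = int(round(config.n_genes * length / total))
            n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        slot = length // n_here
        if slot < _MIN_GENE_SLOT:
            raise ValueError(
                f"contig {contig} too short for {n_here} genes "
                f"(need ≥ {_MIN_GENE_SLOT} bp per gene)"
            )
        for k in range(n_here):
            slot_start, slot_end = k * slot, (k + 1) * slot
            models.append(
                _make_one_gene(gene_idx, contig, slot_start, slot_end, rng)
            )
            gene_idx += 1
    return models


def _make_one_gene(
    idx: int, contig: str, slot_start: int, slot_end: int, rng: np.random.Generator
) -> GeneModel:
    n_ex = int(rng.integers(2, 5))
    ex_lens = rng.integers(150, 301, n_ex)
    in_lens = rng.integers(300, 801, max(n_ex - 1, 0))
    span = int(ex_lens.sum() + in_lens.sum())
    lo = slot_start + 50
    hi = slot_end - 50 - span
    start = int(lo + rng.integers(0, max(hi - lo, 1)))
    exons = []
    p = start
    for i in range(n_ex):
        exons.append((p, p + int(ex_lens[i])))
        p += int(ex_lens[i])
        if i < n_ex - 1:
            p += int(in_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    coding = idx % 5 != 4  # deterministic 80% coding
    cds: list[tuple[int, int]] = []
    if coding:
        trim_lo = int(rng.integers(20, 60))
        trim_hi = int(rng.integers(20, 60))
        a = exons[0][0] + trim_lo
        b = exons[-1][1] - trim_hi
        cds = [(max(s, a), min(e, b)) for s, e in exons if min(e, b) > max(s, a)]
        extra = sum(e - s for s, e in cds) % 3
        if extra:
            s_last, e_last = cds[-1]
            cds[-1] = (s_last, e_last - extra)
    model = GeneModel(
        gene=f"GENE{idx:03d}",
        transcript=f"TX{idx:03d}",
        contig=contig,
        strand=strand,
        exons=exons,
        cds=cds,
    )
    model.validate()
    return model


class _PositionLedger:
    """Reserved genomic positions, so no two planted events collide."""

    def __init__(self) -> None:
        self._used: dict[str, set[int]] = {}

    def free(self, contig: str, start: int, end: int) -> bool:
        used = self._used.setdefault(contig, set())
        return not any(p in used for p in range(start, end))

    def reserve(self, contig: str, start: int, end: int) -> None:
        self._used.setdefault(contig, set()).update(range(start, end))


def _exon_mask(models: Sequence[GeneModel], margin: int = 2) -> dict[str, list[tuple[int, int]]]:
    """Exon intervals widened by the splice margin, per contig."""
    out: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        for s, e in m.exons:
            out.setdefault(m.contig, []).append((s - margin, e + margin))
    return out


def _in_intervals(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _is_cpg_at(ref: bytearray, p: int) -> bool:
    pair = b"CG"
    if p + 1 < len(ref) and ref[p] == pair[0] and ref[p + 1] == pair[1]:
        return True
    if p >= 1 and ref[p - 1] == pair[0] and ref[p] == pair[1]:
        return True
    return False


def _draw_position(
    rng: np.random.Generator,
    config: SimulationConfig,
    ledger: _PositionLedger,
    width: int,
    avoid_exonic: Optional[dict[str, list[tuple[int, int]]]],
    max_tries: int = 10_000,
) -> tuple[str, int]:
    names = [c for c, _ in config.contigs]
    lengths = np.array([l for _, l in config.contigs], dtype=float)
    weights = lengths / lengths.sum()
    for _ in range(max_tries):
        ci = int(rng.choice(len(names), p=weights))
        contig, length = config.contigs[ci]
        p = int(rng.integers(20, length - 20 - width))
        if not ledger.free(contig, p - 1, p + width + 2):
            continue
        if avoid_exonic is not None and any(
            _in_intervals(q, avoid_exonic.get(contig, []))
            for q in range(p - 1, p + width + 1)
        ):
            continue
        return contig, p
    raise RuntimeError("could not place event; contigs too crowded")


def generate_read_support(
    edge_only: bool,
    read_length: int = 101,
    n_reads: int = 5,
    edge_margin: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> list[tuple[int, int]]:
    """Read placements for an indel as (read_length, offset-in-read) pairs.

    With ``edge_only`` every offset lies within ``edge_margin`` of a read
    end; otherwise at least one read places the indel centrally.
    """
    if read_length <= 20:
        raise ValueError("read_length must exceed 20")
    if rng is None:
        rng = np.random.default_rng(0)
    supports: list[tuple[int, int]] = []
    if edge_only:
        for _ in range(n_reads):
            if rng.random() < 0.5:
                off = int(rng.integers(0, edge_margin + 1))
            else:
                off = int(rng.integers(read_length - 1 - edge_margin, read_length))
            supports.append((read_length, off))
    else:
        central_lo, central_hi = edge_margin + 1, read_length - 1 - edge_margin
        supports.append((read_length, int(rng.integers(central_lo, central_hi))))
        for _ in range(n_reads - 1):
            supports.append((read_length, int(rng.integers(0, read_length))))
    return supports


def _denovo_slots(config: SimulationConfig, rng: np.random.Generator) -> list[dict]:
    """Per-event flag assignment honouring the configured exact counts."""
    n_snv, n_indel = config.n_denovo_snv, config.n_denovo_indel
    n_cpg = int(round(config.cpg_fraction * n_snv))
    n_ts = int(round(config.ts_fraction * n_snv))
    n_ex_snv = min(config.n_denovo_exonic, n_snv)
    n_ex_indel = config.n_denovo_exonic - n_ex_snv
    slots = []
    # exonic SNV slots are taken from the non-CpG pool (CpG plants rewrite
    # reference bases, which must not land inside a CDS)
    if n_ex_snv > n_snv - n_cpg:
        raise ValueError("not enough non-CpG SNV slots for exonic de novos")
    ts_flags = np.zeros(n_snv, dtype=bool)
    ts_flags[:n_ts] = True
    rng.shuffle(ts_flags)
    order = list(range(n_snv))
    for i in order:
        slots.append(
            {
                "kind": "snv",
                "is_ts": bool(ts_flags[i]),
                "is_cpg": False,
                "is_exonic": False,
            }
        )
    for s in slots[:n_ex_snv]:
        s["is_exonic"] = True
    for s in slots[n_ex_snv : n_ex_snv + n_cpg]:
        s["is_cpg"] = True
    for k in range(n_indel):
        slots.append(
            {
                "kind": "indel",
                "is_ts": None,
                "is_cpg": None,
                "is_exonic": k < n_ex_indel,
            }
        )
    return slots


def _plant_denovo(
    config: SimulationConfig,
    reference: dict[str, bytearray],
    models: list[GeneModel],
    ledger: _PositionLedger,
) -> tuple[list[VariantCall], list[DenovoTruth]]:
    rng = _stage_rng(config, _STAGE_DENOVO)
    rng_reads = _stage_rng(config, _STAGE_READS)
    exon_mask = _exon_mask(models)
    coding = [m for m in models if m.is_coding]
    total_cds = sum(e - s for m in coding for s, e in m.cds)
    if config.n_denovo_exonic > 0 and total_cds < config.n_denovo_exonic * 10:
        raise ValueError(
            f"config requests {config.n_denovo_exonic} exonic de novos but only "
            f"{total_cds} exonic bases are available"
        )
    variants: list[VariantCall] = []
    truths: list[DenovoTruth] = []
    tggac_pending = config.plant_tggac_deletion
    for slot in _denovo_slots(config, rng):
        if slot["kind"] == "snv":
            contig, p, ref_b, alt_b = _place_denovo_snv(
                slot, config, reference, models, coding, exon_mask, ledger, rng
            )
            v = _trio_variant(contig, p + 1, ref_b, alt_b, config)
            is_cpg = _is_cpg_at(reference[contig], p)
            variants.append(v)
            truths.append(
                DenovoTruth(
                    contig=contig,
                    pos=p + 1,
                    ref=ref_b,
                    alt=alt_b,
                    is_exonic=slot["is_exonic"],
                    is_cpg=is_cpg,
                    is_transition=slot["is_ts"],
                )
            )
        else:
            if tggac_pending:
                del_seq = "TGGAC"
                tggac_pending = False
            else:
                dlen = int(rng.integers(1, 11))
                del_seq = "".join(
                    _BASES[int(b)] for b in rng.integers(0, 4, size=dlen)
                )
            if slot["is_exonic"]:
                contig, p = _draw_cds_position(coding, ledger, rng, width=len(del_seq) + 1)
            else:
                contig, p = _draw_position(
                    rng, config, ledger, width=len(del_seq) + 1, avoid_exonic=exon_mask
                )
            ref_arr = reference[contig]
            ref_arr[p + 1 : p + 1 + len(del_seq)] = del_seq.encode()
            anchor = chr(ref_arr[p])
            ref_allele = anchor + del_seq
            v = _trio_variant(contig, p + 1, ref_allele, anchor, config)
            v.read_support = generate_read_support(
                edge_only=False, read_length=config.read_length, rng=rng_reads
            )
            ledger.reserve(contig, p - 1, p + len(del_seq) + 2)
            variants.append(v)
            truths.append(
                DenovoTruth(
                    contig=contig,
                    pos=p + 1,
                    ref=ref_allele,
                    alt=anchor,
                    is_exonic=slot["is_exonic"],
                    is_cpg=None,
                    is_transition=None,
                )
            )
    return variants, truths


def _place_denovo_snv(
    slot: dict,
    config: SimulationConfig,
    reference: dict[str, bytearray],
    models: list[GeneModel],
    coding: list[GeneModel],
    exon_mask: dict[str, list[tuple[int, int]]],
    ledger: _PositionLedger,
    rng: np.random.Generator,
) -> tuple[str, int, str, str]:
    if slot["is_exonic"]:
        for _ in range(10_000):
            contig, p = _draw_cds_position(coding, ledger, rng, width=1)
            if not _is_cpg_at(reference[contig], p):
                break
        else:
            raise RuntimeError("could not place exonic de novo SNV")
    elif slot["is_cpg"]:
        contig, p = _draw_position(rng, config, ledger, width=2, avoid_exonic=exon_mask)
        ref_arr = reference[contig]
        ref_arr[p] = ord("C")
        ref_arr[p + 1] = ord("G")
        ledger.reserve(contig, p - 1, p + 3)
    else:
        for _ in range(10_000):
            contig, p = _draw_position(
                rng, config, ledger, width=1, avoid_exonic=exon_mask
            )
            if not _is_cpg_at(reference[contig], p):
                break
        else:
            raise RuntimeError("could not place non-CpG de novo SNV")
    ref_b = chr(reference[contig][p])
    if slot["is_ts"]:
        alt_b = _TS_PARTNER[ref_b]
    else:
        alt_b = _TV_PARTNERS[ref_b][int(rng.integers(0, 2))]
    ledger.reserve(contig, p - 1, p + 2)
    return contig, p, ref_b, alt_b


def _draw_cds_position(
    coding: list[GeneModel],
    ledger: _PositionLedger,
    rng: np.random.Generator,
    width: int,
    max_tries: int = 10_000,
) -> tuple[str, int]:
    if not coding:
        raise ValueError("exonic event requested but no coding genes configured")
    for _ in range(max_tries):
        m = coding[int(rng.integers(0, len(coding)))]
        s, e = m.cds[int(rng.integers(0, len(m.cds)))]
        if e - s < 2 * 3 + width + 2:
            continue
        p = int(rng.integers(s + 3, e - 3 - width + 1))
        if ledger.free(m.contig, p - 1, p + width + 1):
            return m.contig, p
    raise RuntimeError("could not place event inside CDS")


def _trio_variant(
    contig: str, pos: int, ref: str, alt: str, config: SimulationConfig,
    father=(0, 0), mother=(0, 0), proband=(0, 1),
) -> VariantCall:
    dp = int(round(config.depth_mean))
    return VariantCall(
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={"father": father, "mother": mother, "proband": proband},
        depth={s: dp for s in tio.TRIO_SAMPLES},
        gq={s: 99 for s in tio.TRIO_SAMPLES},
    )


def _plant_compound_het(
    config: SimulationConfig,
    reference: dict[str, bytearray],
    models: list[GeneModel],
    ledger: _PositionLedger,
) -> tuple[list[VariantCall], list[CompoundHetTruth]]:
    rng = _stage_rng(config, _STAGE_COMPHET)
    coding = [m for m in models if m.is_coding]
    if config.compound_het_genes > len(coding):
        raise ValueError("more compound-het genes requested than coding genes")
    chosen_idx = rng.choice(len(coding), size=config.compound_het_genes, replace=False)
    variants: list[VariantCall] = []
    truths: list[CompoundHetTruth] = []
    for gi in sorted(int(i) for i in chosen_idx):
        model = coding[gi]
        pair: list[tuple[str, int, str, str, str]] = []
        for origin in ("paternal", "maternal"):
            contig, p, ref_b, alt_b = _missense_site(model, reference, ledger, rng)
            gt_f = (0, 1) if origin == "paternal" else (0, 0)
            gt_m = (0, 1) if origin == "maternal" else (0, 0)
            variants.append(
                _trio_variant(
                    contig, p + 1, ref_b, alt_b, config,
                    father=gt_f, mother=gt_m, proband=(0, 1),
                )
            )
            pair.append((contig, p + 1, ref_b, alt_b, origin))
        truths.append(CompoundHetTruth(gene=model.gene, variants=pair))
    return variants, truths


def _missense_site(
    model: GeneModel,
    reference: dict[str, bytearray],
    ledger: _PositionLedger,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> tuple[str, int, str, str]:
    """A CDS position plus alt base whose codon change is missense."""
    seq = reference[model.contig]
    for _ in range(max_tries):
        contig, p = _draw_cds_position([model], ledger, rng, width=1)
        ref_b = chr(seq[p])
        for alt_b in _BASES:
            if alt_b == ref_b:
                continue
            if _is_missense(model, reference, p, alt_b):
                ledger.reserve(contig, p - 1, p + 2)
                return contig, p, ref_b, alt_b
    raise RuntimeError(f"could not find missense site in {model.gene}")


def _is_missense(
    model: GeneModel, reference: dict[str, bytearray], p: int, alt_b: str
) -> bool:
    cds_seq = "".join(
        reference[model.contig][s:e].decode() for s, e in model.cds
    )
    offset = 0
    idx = None
    for s, e in model.cds:
        if s <= p < e:
            idx = offset + (p - s)
            break
        offset += e - s
    if idx is None:
        return False
    if model.strand == "-":
        cds_seq = revcomp(cds_seq)
        idx = len(cds_seq) - 1 - idx
        alt_b = revcomp(alt_b)
    codon_i = idx // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3].upper()
    if len(codon) < 3:
        return False
    within = idx % 3
    alt_codon = codon[:within] + alt_b.upper() + codon[within + 1 :]
    ref_aa, alt_aa = CODON_TABLE[codon], CODON_TABLE[alt_codon]
    return ref_aa != alt_aa and alt_aa != "*" and ref_aa != "*"


def _plant_inherited(
    config: SimulationConfig,
    reference: dict[str, bytearray],
    ledger: _PositionLedger,
) -> tuple[list[VariantCall], dict, KnownSitesCatalog, KnownSitesCatalog, KnownSitesCatalog]:
    rng = _stage_rng(config, _STAGE_INHERITED)
    variants: list[VariantCall] = []
    af_records: dict[tuple[str, int, str, str], dict[str, float]] = {}
    dbsnp: set = set()
    kg: set = set()
    panel: set = set()
    n = config.n_inherited_variants
    if n == 0:
        return variants, af_records, (
            KnownSitesCatalog("dbsnp", dbsnp)
        ), KnownSitesCatalog("1000g", kg), KnownSitesCatalog("panel", panel)
    for _ in range(n):
        is_indel = rng.random() < config.inherited_indel_fraction
        width = (int(rng.integers(1, 6)) + 1) if is_indel else 1
        contig, p = _draw_position(rng, config, ledger, width=width, avoid_exonic=None)
        seq = reference[contig]
        if not is_indel:
            ref_allele = chr(seq[p])
            others = [b for b in _BASES if b != ref_allele]
            alt_allele = others[int(rng.integers(0, 3))]
            pos = p + 1
        else:
            anchor = chr(seq[p])
            if rng.random() < 0.5:  # deletion
                ref_allele = anchor + seq[p + 1 : p + width].decode()
                alt_allele = anchor
            else:  # insertion
                ref_allele = anchor
                ins = "".join(_BASES[int(b)] for b in rng.integers(0, 4, size=width - 1))
                alt_allele = anchor + ins
            pos = p + 1
        ledger.reserve(contig, p - 1, p + width + 1)
        # condition on the site segregating in the parents, so every emitted
        # row carries at least one alt allele
        af = float(rng.beta(0.5, 0.5))
        while True:
            gt_f = tuple(sorted(int(rng.random() < af) for _ in range(2)))
            gt_m = tuple(sorted(int(rng.random() < af) for _ in range(2)))
            if 1 in gt_f or 1 in gt_m:
                break
            af = float(rng.beta(0.5, 0.5))
        child = tuple(
            sorted(
                (
                    gt_f[int(rng.integers(0, 2))],
                    gt_m[int(rng.integers(0, 2))],
                )
            )
        )
        variants.append(
            _trio_variant(
                contig, pos, ref_allele, alt_allele, config,
                father=gt_f, mother=gt_m, proband=child,
            )
        )
        key = (contig, pos, ref_allele, alt_allele)
        af_records[key] = {"SIM": round(af, 6)}
        panel.add(key)
        if af > 0.05:
            dbsnp.add(key)
            if af > 0.2:
                kg.add(key)
        elif af > 0.01:
            kg.add(key)
    return (
        variants,
        af_records,
        KnownSitesCatalog("dbsnp", dbsnp),
        KnownSitesCatalog("1000g", kg),
        KnownSitesCatalog("panel", panel),
    )


def generate_trio(config: SimulationConfig) -> TrioDataset:
    """Build the full synthetic trio dataset for a validated configuration.

    Proband genotypes are Mendelian-consistent everywhere except at planted
    de novo sites, which are heterozygous in the proband and
    homozygous-reference in both parents.
    """
    config.validate()
    for name, length in config.contigs:
        if length < 10 * config.bin_size:
            raise ValueError(f"contig {name} shorter than 10 bins")
    reference = _make_reference(config)
    models = _make_genes(config)
    ledger = _PositionLedger()
    dn_variants, dn_truth = _plant_denovo(config, reference, models, ledger)
    ch_variants, ch_truth = _plant_compound_het(config, reference, models, ledger)
    inh_variants, af_records, dbsnp, kg, panel = _plant_inherited(
        config, reference, ledger
    )
    truth = TruthTable(
        denovo_events=dn_truth,
        compound_het_events=ch_truth,
        cnv_events=list(config.cnv_events),
    )
    return TrioDataset(
        config=config,
        reference={k: v.decode() for k, v in reference.items()},
        models=models,
        variants=dn_variants + ch_variants + inh_variants,
        truth=truth,
        af_records=af_records,
        dbsnp=dbsnp,
        kg=kg,
        panel=panel,
    )


def generate_depth_profile(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample binned depth with CNV events baked in.

    A bin overlapping a CNV event mixes the event's depth factor with the
    diploid background in proportion to the overlap. Seeded Gaussian noise
    (sd ``depth_noise_sd``) is added and truncated at zero.
    """
    config.validate()
    rng = _stage_rng(config, _STAGE_DEPTH)
    rows = []
    for contig, length in config.contigs:
        starts = np.arange(0, length, config.bin_size)
        ends = np.minimum(starts + config.bin_size, length)
        child_f = np.ones(starts.size)
        parent_f = np.ones(starts.size)
        for ev in config.cnv_events:
            if ev.contig != contig:
                continue
            overlap = np.clip(
                np.minimum(ends, ev.end) - np.maximum(starts, ev.start), 0, None
            ) / (ends - starts)
            child_f += overlap * (_STATE_FACTOR[ev.child_state] - 1.0)
            parent_f += overlap * (_STATE_FACTOR[ev.parent_state] - 1.0)
        depth = {}
        for sample, factor in (
            ("father", parent_f),
            ("mother", parent_f),
            ("proband", child_f),
        ):
            base = config.depth_mean * factor
            if config.depth_noise_sd > 0:
                base = base + rng.normal(0.0, config.depth_noise_sd, starts.size)
            depth[sample] = np.maximum(base, 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "contig": contig,
                    "start": starts,
                    "end": ends,
                    "depth_father": depth["father"],
                    "depth_mother": depth["mother"],
                    "depth_proband": depth["proband"],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
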