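"""Readers and writers for every file format the pipeline touches.

Coordinate conventions are strict and converted only at I/O boundaries:

* point variants are 1-based inclusive (VCF convention);
* intervals are 0-based half-open (BED convention).

All readers reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

TRIO_SAMPLES = ("father", "mother", "proband")

#: FORMAT tag carrying read-support offsets so edge filtering needs no BAM.
#: Value is a comma list of ``<read_length>_<offset>`` pairs, offset being the
#: 0-based start of the variant within the read.
READ_SUPPORT_TAG = "RS"

Genotype = tuple[Optional[int], Optional[int]]

MISSING_GT: Genotype = (None, None)


@dataclass
class VariantCall:
    """One biallelic variant site with per-sample trio genotypes.

    ``genotypes`` maps sample name to an unordered allele pair where
    0 = ref, 1 = alt and ``None`` = missing. Multi-allelic VCF lines are
    decomposed into one ``VariantCall`` per alt allele before reaching here.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    depth: dict[str, Optional[int]] = field(default_factory=dict)
    gq: dict[str, Optional[int]] = field(default_factory=dict)
    read_support: list[tuple[int, int]] = field(default_factory=list)
    annotations: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def is_snv(self) -> bool:
        return self.vtype == "SNV"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    def genotype(self, sample: str) -> Genotype:
        return self.genotypes.get(sample, MISSING_GT)

    def has_alt(self, sample: str) -> bool:
        gt = self.genotype(sample)
        return 1 in gt

    def is_het(self, sample: str) -> bool:
        return sorted(self.genotype(sample), key=lambda a: (a is None, a)) == [0, 1]

    def is_hom_alt(self, sample: str) -> bool:
        return self.genotype(sample) == (1, 1)

    def affected_start(self) -> int:
        """0-based position of the first base changed by this variant.

        For anchored deletions the anchor base itself is unchanged, so the
        first deleted base is one past the VCF position.
        """
        if self.vtype == "deletion":
            return self.pos  # == (pos + 1) - 1
        return self.pos - 1


@dataclass
class GeneModel:
    """One transcript: strand, exon and CDS intervals (0-based half-open)."""

    gene: str
    transcript: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript}: no exons")
        for s, e in self.exons + self.cds:
            if s >= e:
                raise ValueError(f"{self.transcript}: empty interval ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"{self.transcript}: exons not sorted/non-overlapping"
                )
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"{self.transcript}: cds ({s},{e}) outside exons")

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def in_exon(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.exons)

    def in_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds)


@dataclass
class KnownSitesCatalog:
    """Exact-allele site list standing in for a population variant catalog."""

    name: str
    sites: set[tuple[str, int, str, str]]

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.sites


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


def _parse_gt(token: str, line_no: int) -> tuple[Optional[int], ...]:
    m = _GT_RE.match(token)
    if not m:
        raise ValueError(f"line {line_no}: malformed genotype {token!r}")
    alleles = re.split(r"[/|]", token)
    return tuple(None if a == "." else int(a) for a in alleles)


def _parse_info(info: str) -> dict[str, object]:
    ann: dict[str, object] = {}
    if info in (".", ""):
        return ann
    for item in info.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            try:
                ann[k] = float(v) if ("." in v or "e" in v or "E" in v) else int(v)
            except ValueError:
                ann[k] = v
        else:
            ann[item] = True
    return ann


def read_trio_vcf(path: str, samples: Sequence[str] = TRIO_SAMPLES) -> list[VariantCall]:
    """Parse a three-sample VCF 4.2 into decomposed :class:`VariantCall` records.

    Multi-allelic sites yield one record per alt allele; alleles belonging to
    a different alt are recorded as missing in the decomposed record. Errors
    name the offending line number.
    """
    variants: list[VariantCall] = []
    with open(path) as fh:
        header_samples: Optional[list[str]] = None
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                header_samples = cols[9:]
                if list(header_samples) != list(samples):
                    raise ValueError(
                        f"line {line_no}: expected samples {list(samples)}, "
                        f"found {header_samples}"
                    )
                continue
            if header_samples is None:
                raise ValueError(f"line {line_no}: data before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ValueError(
                    f"line {line_no}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            contig, pos_s, _id, ref, alt_s, _qual, _flt, info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"line {line_no}: bad POS {pos_s!r}") from None
            fmt_keys = fmt.split(":")
            if fmt_keys[0] != "GT":
                raise ValueError(f"line {line_no}: FORMAT must start with GT")
            alts = alt_s.split(",")
            sample_fields = [dict(zip(fmt_keys, f.split(":"))) for f in fields[9:]]
            ann = _parse_info(info)
            for alt_idx, alt in enumerate(alts, start=1):
                genotypes: dict[str, Genotype] = {}
                depth: dict[str, Optional[int]] = {}
                gq: dict[str, Optional[int]] = {}
                support: list[tuple[int, int]] = []
                for sample, sf in zip(samples, sample_fields):
                    alleles = _parse_gt(sf["GT"], line_no)
                    if len(alleles) != 2:
                        raise ValueError(
                            f"line {line_no}: non-diploid genotype {sf['GT']!r}"
                        )
                    mapped = tuple(
                        0 if a == 0 else 1 if a == alt_idx else None for a in alleles
                    )
                    genotypes[sample] = mapped  # type: ignore[assignment]
                    depth[sample] = _opt_int(sf.get("DP"), line_no)
                    gq[sample] = _opt_int(sf.get("GQ"), line_no)
                    rs = sf.get(READ_SUPPORT_TAG)
                    if rs and rs != ".":
                        for pair in rs.split(","):
                            rl, off = pair.split("_")
                            support.append((int(rl), int(off)))
                variants.append(
                    VariantCall(
                        contig=contig,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        genotypes=genotypes,
                        depth=depth,
                        gq=gq,
                        read_support=support,
                        annotations=dict(ann),
                    )
                )
    return variants


def _opt_int(token: Optional[str], line_no: int) -> Optional[int]:
    if token is None or token == ".":
        return None
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"line {line_no}: bad integer field {token!r}") from None


def _fmt_info(ann: dict[str, object]) -> str:
    parts = []
    for k, v in ann.items():
        if v is True:
            parts.append(k)
        elif v is False or v is None:
            continue
        else:
            parts.append(f"{k}={v}")
    return ";".join(parts) if parts else "."


def _fmt_gt(gt: Genotype) -> str:
    return "/".join("." if a is None else str(a) for a in gt)


def write_trio_vcf(
    variants: Sequence[VariantCall],
    path: str,
    contigs: Sequence[tuple[str, int]],
    samples: Sequence[str] = TRIO_SAMPLES,
) -> None:
    """Write biallelic records as VCF 4.2, samples in the given order."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=DB,Number=0,Type=Flag,Description="Present in dbSNP-like catalog">',
        '##INFO=<ID=KG,Number=0,Type=Flag,Description="Present in 1000G-like catalog">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=CAT,Number=1,Type=String,Description="Region category">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">',
        '##INFO=<ID=CPG,Number=0,Type=Flag,Description="CpG dinucleotide context">',
        '##INFO=<ID=TS,Number=0,Type=Flag,Description="Transition substitution">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Amino-acid change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        f'##FORMAT=<ID={READ_SUPPORT_TAG},Number=.,Type=String,'
        'Description="Supporting read placements as readlength_offset pairs">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    order = {name: i for i, (name, _) in enumerate(contigs)}
    for v in sorted(variants, key=lambda v: (order.get(v.contig, len(order)), v.pos)):
        fmt = ["GT", "DP", "GQ"]
        has_rs = bool(v.read_support)
        if has_rs:
            fmt.append(READ_SUPPORT_TAG)
        sample_cols = []
        for i, sample in enumerate(samples):
            parts = [
                _fmt_gt(v.genotype(sample)),
                _dot(v.depth.get(sample)),
                _dot(v.gq.get(sample)),
            ]
            if has_rs:
                # read support describes the carrier sample; emit on proband
                if sample == samples[-1]:
                    parts.append(",".join(f"{rl}_{off}" for rl, off in v.read_support))
                else:
                    parts.append(".")
            sample_cols.append(":".join(parts))
        lines.append(
            "\t".join(
                [
                    v.contig,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    _fmt_info(v.annotations),
                    ":".join(fmt),
                ]
                + sample_cols
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _dot(v: Optional[int]) -> str:
    return "." if v is None else str(v)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["gene", "transcript", "contig", "strand", "exons", "cds"]


def _parse_intervals(token: str) -> list[tuple[int, int]]:
    if token in (".", ""):
        return []
    out = []
    for item in token.split(","):
        s, e = item.split("-")
        out.append((int(s), int(e)))
    return out


def read_gene_models(path: str) -> list[GeneModel]:
    """Read the tab-separated gene-model table (0-based half-open intervals)."""
    models: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header and header.split("\t") != _GENE_COLUMNS:
            raise ValueError(f"bad gene-model header: {header!r}")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_GENE_COLUMNS):
                raise ValueError(f"line {line_no}: expected {len(_GENE_COLUMNS)} columns")
            gene, transcript, contig, strand, exons_s, cds_s = fields
            model = GeneModel(
                gene=gene,
                transcript=transcript,
                contig=contig,
                strand=strand,
                exons=_parse_intervals(exons_s),
                cds=_parse_intervals(cds_s),
            )
            model.validate()
            models.append(model)
    return models


def write_gene_models(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for m in models:
            fh.write(
                "\t".join(
                    [
                        m.gene,
                        m.transcript,
                        m.contig,
                        m.strand,
                        ",".join(f"{s}-{e}" for s, e in m.exons) or ".",
                        ",".join(f"{s}-{e}" for s, e in m.cds) or ".",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Known sites
# ---------------------------------------------------------------------------

def read_known_sites(path: str, name: str) -> KnownSitesCatalog:
    """Site list TSV: contig, 1-based pos, ref, alt."""
    sites = set()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path} line {line_no}: expected 4 columns")
            contig, pos_s, ref, alt = fields
            sites.add((contig, int(pos_s), ref, alt))
    return KnownSitesCatalog(name=name, sites=sites)


def write_known_sites(catalog: KnownSitesCatalog, path: str) -> None:
    with open(path, "w") as fh:
        for contig, pos, ref, alt in sorted(catalog.sites):
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA reference fully into memory (contigs are desk-scale)."""
    import pyfaidx

    with pyfaidx.Fasta(path, as_raw=True, rebuild=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Depth bins
# ---------------------------------------------------------------------------

DEPTH_COLUMNS = ["contig", "start", "end", "depth_father", "depth_mother", "depth_proband"]


def read_depth_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != DEPTH_COLUMNS:
        raise ValueError(f"bad depth-table columns: {list(df.columns)}")
    if (df["end"] <= df["start"]).any():
        raise ValueError("depth table has empty or inverted bins")
    if (df[["depth_father", "depth_mother", "depth_proband"]] < 0).any().any():
        raise ValueError("negative depth")
    return df


def write_depth_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Congener measurements
# ---------------------------------------------------------------------------

CONGENER_COLUMNS = ["congener", "family", "concentration", "detected", "detection_limit"]


def read_congener_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != CONGENER_COLUMNS:
        raise ValueError(f"bad congener-table columns: {list(df.columns)}")
    df["detected"] = df["detected"].astype(bool)
    bad = ~df["detected"] & df["detection_limit"].isna()
    if bad.any():
        raise ValueError(
            f"non-detect rows missing detection limit: {df.loc[bad, 'congener'].tolist()}"
        )
    if (df["concentration"].fillna(0) < 0).any():
        raise ValueError("negative concentration")
    return df


def write_congener_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
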