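"""Genomic region classification, coding effect, and sequence-context features."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io import GeneModel, VariantCall

#: Category precedence when a variant touches several transcripts or features.
#: Rarest diagnostic categories win; intergenic is the fallback.
REGION_PRECEDENCE = [
    "splicing",
    "exonic",
    "UTR5",
    "UTR3",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "intergenic",
]

_RANK = {c: i for i, c in enumerate(REGION_PRECEDENCE)}

#: Intronic positions within this many bases of an exon boundary are splicing.
SPLICE_WIDTH = 2

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CodingEffect:
    kind: str  # synonymous|missense|nonsense|frameshift|inframe_indel|splice_site
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    def aa_change(self) -> Optional[str]:
        if self.protein_pos is None:
            return None
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"


def _is_splice(pos0: int, model: GeneModel) -> bool:
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if e1 <= pos0 < min(e1 + SPLICE_WIDTH, s2):
            return True
        if max(s2 - SPLICE_WIDTH, e1) <= pos0 < s2:
            return True
    return False


def _classify_one(pos0: int, model: GeneModel) -> str:
    if not model.contains(pos0):
        return "intergenic"
    if _is_splice(pos0, model):
        return "splicing"
    if not model.is_coding:
        return "ncRNA_exonic" if model.in_exon(pos0) else "ncRNA_intronic"
    if model.in_cds(pos0):
        return "exonic"
    if model.in_exon(pos0):
        cds_start = model.cds[0][0]
        cds_end = model.cds[-1][1]
        if pos0 < cds_start:
            return "UTR5" if model.strand == "+" else "UTR3"
        if pos0 >= cds_end:
            return "UTR3" if model.strand == "+" else "UTR5"
        # exonic position between CDS intervals cannot happen (cds ⊆ exons,
        # contiguity of coding exons); treat defensively as exonic
        return "exonic"
    return "intronic"


def classify_region(v: VariantCall, models: Sequence[GeneModel]) -> str:
    """Assign exactly one region category by precedence across transcripts."""
    pos0 = v.affected_start()
    best = "intergenic"
    for m in models:
        if m.contig != v.contig:
            continue
        cat = _classify_one(pos0, m)
        if _RANK[cat] < _RANK[best]:
            best = cat
    return best


def genes_at(v: VariantCall, models: Sequence[GeneModel]) -> list[str]:
    pos0 = v.affected_start()
    seen: list[str] = []
    for m in models:
        if m.contig == v.contig and m.contains(pos0) and m.gene not in seen:
            seen.append(m.gene)
    return seen


def _cds_sequence(model: GeneModel, reference: dict[str, str]) -> str:
    seq = "".join(reference[model.contig][s:e] for s, e in model.cds)
    return revcomp(seq) if model.strand == "-" else seq


def _cds_index(pos0: int, model: GeneModel) -> Optional[int]:
    """Index of a genomic position within the stranded CDS sequence."""
    offset = 0
    for s, e in model.cds:
        if s <= pos0 < e:
            idx = offset + (pos0 - s)
            if model.strand == "-":
                total = sum(e2 - s2 for s2, e2 in model.cds)
                return total - 1 - idx
            return idx
        offset += e - s
    return None


def coding_effect(
    v: VariantCall, model: GeneModel, reference: dict[str, str]
) -> CodingEffect:
    """Coding consequence of a variant falling in the CDS of ``model``.

    Substitutions are resolved to an amino-acid change via the standard
    genetic code with strand handling; indels are classified by frame.
    """
    ref_seq = reference[v.contig]
    if ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref)].upper() != v.ref.upper():
        raise ValueError(
            f"reference mismatch at {v.contig}:{v.pos}: "
            f"expected {v.ref!r}, found "
            f"{ref_seq[v.pos - 1 : v.pos - 1 + len(v.ref)]!r}"
        )
    pos0 = v.affected_start()
    if _is_splice(pos0, model):
        return CodingEffect(kind="splice_site")
    if not v.is_snv:
        delta = len(v.alt) - len(v.ref)
        kind = "inframe_indel" if delta % 3 == 0 else "frameshift"
        return CodingEffect(kind=kind)
    idx = _cds_index(pos0, model)
    if idx is None:
        raise ValueError(f"{v.contig}:{v.pos} not in CDS of {model.transcript}")
    cds = _cds_sequence(model, reference).upper()
    codon_idx = idx // 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:  # trailing partial codon
        return CodingEffect(kind="synonymous", protein_pos=codon_idx + 1)
    alt_base = v.alt.upper() if model.strand == "+" else revcomp(v.alt.upper())
    within = idx % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = CODON_TABLE[codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        kind = "synonymous"
    elif alt_aa == "*":
        kind = "nonsense"
    else:
        kind = "missense"
    return CodingEffect(kind=kind, protein_pos=codon_idx + 1, ref_aa=ref_aa, alt_aa=alt_aa)


def cpg_context(v: VariantCall, reference: dict[str, str]) -> bool:
    """True iff the reference dinucleotide on either side of the site is CG."""
    if not v.is_snv:
        raise ValueError("CpG context is defined for SNVs only")
    seq = reference[v.contig].upper()
    p = v.pos - 1
    right = seq[p : p + 2] == "CG" if p + 1 < len(seq) else False
    left = seq[p - 1 : p + 1] == "CG" if p >= 1 else False
    return right or left


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def transition_flag(v: VariantCall) -> bool:
    """True for purine↔purine or pyrimidine↔pyrimidine substitutions."""
    if not v.is_snv:
        raise ValueError("transition/transversion is defined for SNVs only")
    pair = {v.ref.upper(), v.alt.upper()}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def most_severe_effect(
    v: VariantCall, models: Sequence[GeneModel], reference: dict[str, str]
) -> Optional[tuple[str, CodingEffect]]:
    """(gene, effect) with the most severe consequence across transcripts.

    Severity order: frameshift/nonsense > missense > inframe/splice >
    synonymous. Ties break deterministically by transcript name.
    """
    severity = {
        "nonsense": 0,
        "frameshift": 0,
        "missense": 1,
        "inframe_indel": 2,
        "splice_site": 2,
        "synonymous": 3,
    }
    pos0 = v.affected_start()
    best: Optional[tuple[int, str, str, CodingEffect]] = None
    for m in sorted(models, key=lambda m: m.transcript):
        if m.contig != v.contig or not m.is_coding:
            continue
        in_cds = m.in_cds(pos0)
        splice = m.contains(pos0) and _is_splice(pos0, m)
        if not (in_cds or splice):
            continue
        eff = coding_effect(v, m, reference)
        rank = severity[eff.kind]
        if best is None or rank < best[0]:
            best = (rank, m.gene, m.transcript, eff)
    if best is None:
        return None
    return best[1], best[3]
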