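"""Recessive-model filtering: compound heterozygotes and homozygous calls.

A compound-het call requires two proband-heterozygous variants in the same
gene in trans — one transmitted by the father only, one by the mother only —
with both variants passing the coding-effect filter and the population
frequency filter. Pairs whose parental origin is ambiguous (an allele seen
in both parents) are excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotate import CodingEffect
from .io import KnownSitesCatalog, VariantCall

log = logging.getLogger(__name__)

DEFAULT_MAX_AF = 0.01

#: Effects retained by the recessive-model search: non-synonymous SNVs,
#: coding indels, and splice-site variants.
DAMAGING_EFFECTS = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice_site"}
)


@dataclass
class AnnotatedVariant:
    """A variant with its gene assignment and coding effect, ready for the
    recessive-model filters."""

    variant: VariantCall
    gene: str
    effect: CodingEffect


@dataclass
class CompoundHetCall:
    gene: str
    paternal: AnnotatedVariant
    maternal: AnnotatedVariant


@dataclass
class HomRecessiveCall:
    gene: str
    variant: AnnotatedVariant


def effect_filter(effect: CodingEffect) -> bool:
    return effect.kind in DAMAGING_EFFECTS


def frequency_filter(
    v: VariantCall,
    af_records: Optional[dict[tuple[str, int, str, str], dict[str, float]]] = None,
    threshold: float = DEFAULT_MAX_AF,
    panel: Optional[KnownSitesCatalog] = None,
) -> bool:
    """Pass iff the max allele frequency across populations is ≤ threshold.

    A variant with no frequency record is treated as AF 0. Presence in the
    optional local cohort panel excludes the variant at any frequency.
    """
    if panel is not None and v.key in panel:
        return False
    if af_records is None:
        return True
    by_pop = af_records.get(v.key)
    if not by_pop:
        return True
    return max(by_pop.values()) <= threshold


def _origin(
    v: VariantCall, father: str, mother: str, proband: str
) -> Optional[str]:
    """Parental origin of the proband's het alt allele, or None if ambiguous."""
    in_father = v.has_alt(father)
    in_mother = v.has_alt(mother)
    if in_father and not in_mother:
        return "paternal"
    if in_mother and not in_father:
        return "maternal"
    return None


def find_compound_het(
    annotated: Sequence[AnnotatedVariant],
    af_records: Optional[dict] = None,
    max_af: float = DEFAULT_MAX_AF,
    panel: Optional[KnownSitesCatalog] = None,
    father: str = "father",
    mother: str = "mother",
    proband: str = "proband",
) -> list[CompoundHetCall]:
    """All trans-configured variant pairs per gene passing every filter."""
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for av in annotated:
        by_gene.setdefault(av.gene, []).append(av)
    calls: list[CompoundHetCall] = []
    for gene in sorted(by_gene):
        usable: list[tuple[AnnotatedVariant, str]] = []
        for av in by_gene[gene]:
            v = av.variant
            if not v.is_het(proband):
                continue
            if not effect_filter(av.effect):
                continue
            if not frequency_filter(v, af_records, max_af, panel):
                continue
            origin = _origin(v, father, mother, proband)
            if origin is None:
                log.info(
                    "ambiguous parental origin at %s:%d in %s; pair excluded",
                    v.contig,
                    v.pos,
                    gene,
                )
                continue
            usable.append((av, origin))
        paternal = [av for av, o in usable if o == "paternal"]
        maternal = [av for av, o in usable if o == "maternal"]
        for p in paternal:
            for m in maternal:
                calls.append(CompoundHetCall(gene=gene, paternal=p, maternal=m))
    return calls


def find_homozygous_recessive(
    annotated: Sequence[AnnotatedVariant],
    af_records: Optional[dict] = None,
    max_af: float = DEFAULT_MAX_AF,
    panel: Optional[KnownSitesCatalog] = None,
    father: str = "father",
    mother: str = "mother",
    proband: str = "proband",
) -> list[HomRecessiveCall]:
    """Proband homozygous-alt with both parents heterozygous, filters passing."""
    calls: list[HomRecessiveCall] = []
    for av in annotated:
        v = av.variant
        if not v.is_hom_alt(proband):
            continue
        if not (v.is_het(father) and v.is_het(mother)):
            continue
        if not effect_filter(av.effect):
            continue
        if not frequency_filter(v, af_records, max_af, panel):
            continue
        calls.append(HomRecessiveCall(gene=av.gene, variant=av))
    return calls


def read_af_table(path: str) -> dict[tuple[str, int, str, str], dict[str, float]]:
    """AF TSV: contig, pos, ref, alt, population, allele_frequency."""
    records: dict[tuple[str, int, str, str], dict[str, float]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path} line {line_no}: expected 6 columns")
            contig, pos_s, ref, alt, pop, af_s = fields
            af = float(af_s)
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{path} line {line_no}: AF {af} outside [0,1]")
            records.setdefault((contig, int(pos_s), ref, alt), {})[pop] = af
    return records
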