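"""De novo candidate detection, edge-read indel filtering, mutation spectrum.

Detection is deterministic set logic: the proband is compared against each
parent separately and a site is a candidate only when the proband's alt
allele is absent from *both* parents' called genotypes. Sites with missing or
low-quality genotypes are unevaluable and never counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotate import classify_region, cpg_context, transition_flag
from .io import GeneModel, VariantCall

log = logging.getLogger(__name__)

#: hg19 total assembled length, used when no callable-genome length is given.
DEFAULT_GENOME_LENGTH = 3_137_161_264

DEFAULT_MIN_DP = 10
DEFAULT_MIN_GQ = 20
DEFAULT_EDGE_MARGIN = 10


@dataclass(frozen=True)
class QcThresholds:
    min_dp: int = DEFAULT_MIN_DP
    min_gq: int = DEFAULT_MIN_GQ


@dataclass
class DeNovoCandidate:
    variant: VariantCall
    region: str
    is_cpg: Optional[bool]  # None for indels
    is_transition: Optional[bool]  # None for indels


@dataclass
class MutationSpectrum:
    n_total: int
    n_snv: int
    n_cpg: int
    n_transition: int
    n_transversion: int
    titv: Optional[float]
    cpg_proportion: Optional[float]
    rate: float
    genome_length: int

    def report(self) -> dict:
        """Rounded presentation: Ts/Tv to 1 d.p., CpG proportion to 2 d.p."""
        return {
            "n_total": self.n_total,
            "n_snv": self.n_snv,
            "n_cpg": self.n_cpg,
            "n_transition": self.n_transition,
            "n_transversion": self.n_transversion,
            "titv": None if self.titv is None else round(self.titv, 1),
            "cpg_proportion": (
                None if self.cpg_proportion is None else round(self.cpg_proportion, 2)
            ),
            "rate": self.rate,
            "genome_length": self.genome_length,
        }


def _passes_qc(v: VariantCall, sample: str, qc: QcThresholds) -> bool:
    dp = v.depth.get(sample)
    gq = v.gq.get(sample)
    if dp is not None and dp < qc.min_dp:
        return False
    if gq is not None and gq < qc.min_gq:
        return False
    return True


def pairwise_absent(
    parent_gt: tuple[Optional[int], Optional[int]],
    proband_gt: tuple[Optional[int], Optional[int]],
) -> Optional[bool]:
    """Does the proband carry an alt allele absent from this parent?

    Returns ``None`` (unevaluable) when either genotype has a missing allele.
    """
    if None in parent_gt or None in proband_gt:
        return None
    return 1 in proband_gt and 1 not in parent_gt


def filter_edge_indels(
    indel: VariantCall, edge_margin: int = DEFAULT_EDGE_MARGIN
) -> bool:
    """Keep an indel only if some supporting read places it away from both
    read ends (strictly more than ``edge_margin`` bases from each end).

    Without read-support metadata the indel is kept, with a warning — the
    filter can only remove what it can measure.
    """
    if not indel.read_support:
        log.warning(
            "no read support at %s:%d; keeping indel unfiltered",
            indel.contig,
            indel.pos,
        )
        return True
    for read_length, offset in indel.read_support:
        if offset > edge_margin and (read_length - 1 - offset) > edge_margin:
            return True
    return False


def detect_denovo(
    variants: Sequence[VariantCall],
    qc: QcThresholds = QcThresholds(),
    edge_margin: int = DEFAULT_EDGE_MARGIN,
    models: Sequence[GeneModel] = (),
    reference: Optional[dict[str, str]] = None,
    father: str = "father",
    mother: str = "mother",
    proband: str = "proband",
) -> list[DeNovoCandidate]:
    """Dual-comparison de novo detection over a decomposed trio variant list.

    A candidate must be absent from the father AND absent from the mother
    (each comparison evaluable and QC-passing), and indels must additionally
    survive the edge-read filter.
    """
    candidates: list[DeNovoCandidate] = []
    for v in variants:
        if not all(_passes_qc(v, s, qc) for s in (father, mother, proband)):
            continue
        vs_father = pairwise_absent(v.genotype(father), v.genotype(proband))
        vs_mother = pairwise_absent(v.genotype(mother), v.genotype(proband))
        if vs_father is None or vs_mother is None:
            continue
        if not (vs_father and vs_mother):
            continue
        if not v.is_snv and not filter_edge_indels(v, edge_margin):
            continue
        region = classify_region(v, models) if models else "intergenic"
        is_cpg = cpg_context(v, reference) if (v.is_snv and reference) else None
        is_ts = transition_flag(v) if v.is_snv else None
        candidates.append(
            DeNovoCandidate(variant=v, region=region, is_cpg=is_cpg, is_transition=is_ts)
        )
    return candidates


def spectrum(
    candidates: Sequence[DeNovoCandidate],
    genome_length: int = DEFAULT_GENOME_LENGTH,
) -> MutationSpectrum:
    """Summary statistics of a de novo candidate set.

    The per-generation rate divides the candidate count by the diploid
    genome length (2·L). Ts/Tv and the CpG proportion are computed over SNV
    candidates and are absent (not zero) when undefined.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    snvs = [c for c in candidates if c.variant.is_snv]
    n_ts = sum(1 for c in snvs if c.is_transition)
    n_tv = sum(1 for c in snvs if c.is_transition is False)
    n_cpg = sum(1 for c in snvs if c.is_cpg)
    titv = (n_ts / n_tv) if n_tv > 0 else None
    cpg_prop = (n_cpg / len(snvs)) if snvs else None
    return MutationSpectrum(
        n_total=len(candidates),
        n_snv=len(snvs),
        n_cpg=n_cpg,
        n_transition=n_ts,
        n_transversion=n_tv,
        titv=titv,
        cpg_proportion=cpg_prop,
        rate=len(candidates) / (2 * genome_length),
        genome_length=genome_length,
    )
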