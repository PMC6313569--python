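import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from trioscan import annotate as ann
from trioscan.io import GeneModel

from conftest import make_gene, make_variant

# ---------------------------------------------------------------------------
# region classification
# ---------------------------------------------------------------------------


def _ref(seq, contig="c1"):
    return {contig: seq}


def test_cds_exon_is_exonic():
    gene = make_gene()
    assert ann.classify_region(make_variant(pos=151), [gene]) == "exonic"


def test_splicing_positions_enumerated_around_boundary():
    # exon1 ends at 200 (0-based half-open), exon2 starts at 300; enumerate
    # every intronic position and check only those within 2 bp of a boundary
    # are splicing
    gene = make_gene()
    for pos0 in range(200, 300):
        v = make_variant(pos=pos0 + 1)
        cat = ann.classify_region(v, [gene])
        if pos0 in (200, 201, 298, 299):
            assert cat == "splicing", pos0
        else:
            assert cat == "intronic", pos0


def test_noncoding_exon_is_ncrna_exonic():
    gene = make_gene(cds=())
    assert ann.classify_region(make_variant(pos=151), [gene]) == "ncRNA_exonic"
    assert ann.classify_region(make_variant(pos=251), [gene]) == "ncRNA_intronic"


def test_no_gene_is_intergenic():
    gene = make_gene()
    assert ann.classify_region(make_variant(pos=5000), [gene]) == "intergenic"
    assert ann.classify_region(make_variant(pos=151), []) == "intergenic"


def test_utr_categories_respect_strand():
    plus = make_gene(exons=((100, 200),), cds=((130, 190),), strand="+")
    assert ann.classify_region(make_variant(pos=110), [plus]) == "UTR5"
    assert ann.classify_region(make_variant(pos=195), [plus]) == "UTR3"
    minus = make_gene(exons=((100, 200),), cds=((130, 190),), strand="-")
    assert ann.classify_region(make_variant(pos=110), [minus]) == "UTR3"
    assert ann.classify_region(make_variant(pos=195), [minus]) == "UTR5"


def test_precedence_coding_wins_over_noncoding():
    coding = make_gene(gene="A")
    noncoding = make_gene(gene="B", cds=())
    v = make_variant(pos=151)
    assert ann.classify_region(v, [coding, noncoding]) == "exonic"
    assert ann.classify_region(v, [noncoding, coding]) == "exonic"


def test_classification_is_a_partition(paper_trio):
    cats = [ann.classify_region(v, paper_trio.models) for v in paper_trio.variants]
    counts = {c: cats.count(c) for c in set(cats)}
    assert sum(counts.values()) == len(paper_trio.variants)
    assert set(counts) <= set(ann.REGION_PRECEDENCE)


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------


def _single_exon_gene(n_codons, strand="+", start=10, contig="c1"):
    cds = [(start, start + 3 * n_codons)]
    return GeneModel(
        gene="G", transcript="T", contig=contig, strand=strand, exons=cds, cds=cds
    )


def test_codon_502_arginine_to_tryptophan():
    # codon 502 is CGG (R); a C>T at its first base gives TGG (W)
    n = 502
    cds = "ATG" + "GCT" * (n - 2) + "CGG" + "TAA"
    gene = _single_exon_gene(len(cds) // 3, start=0)
    ref = _ref(cds)
    pos = 3 * (n - 1) + 1  # 1-based genomic = CDS coordinate here
    assert pos == 1504
    eff = ann.coding_effect(make_variant(pos=pos, ref="C", alt="T"), gene, ref)
    assert eff.kind == "missense"
    assert eff.aa_change() == "R502W"


def test_synonymous_substitution():
    cds = "ATGCTTTAA"  # M L *
    gene = _single_exon_gene(3, start=0)
    # CTT -> CTC is still Leucine
    eff = ann.coding_effect(make_variant(pos=6, ref="T", alt="C"), gene, _ref(cds))
    assert eff.kind == "synonymous"


def test_nonsense_substitution():
    cds = "ATGTACTAA"  # M Y *
    gene = _single_exon_gene(3, start=0)
    # TAC -> TAA stop
    eff = ann.coding_effect(make_variant(pos=6, ref="C", alt="A"), gene, _ref(cds))
    assert eff.kind == "nonsense"


def test_indel_frame_classification():
    cds = "ATG" + "GCT" * 30 + "TAA"
    gene = _single_exon_gene(len(cds) // 3, start=0)
    ref = _ref(cds)
    del4 = make_variant(pos=6, ref=cds[5:10], alt=cds[5])
    assert ann.coding_effect(del4, gene, ref).kind == "frameshift"
    del3 = make_variant(pos=6, ref=cds[5:9], alt=cds[5])
    assert ann.coding_effect(del3, gene, ref).kind == "inframe_indel"


def test_reference_mismatch_raises():
    cds = "ATGCTTTAA"
    gene = _single_exon_gene(3, start=0)
    with pytest.raises(ValueError, match="mismatch"):
        ann.coding_effect(make_variant(pos=6, ref="G", alt="C"), gene, _ref(cds))


def _oracle_effect(v, model, reference):
    """Independent oracle: rebuild the whole CDS through an explicit genomic
    coordinate list, apply the substitution, translate both with Biopython,
    and diff the protein sequences."""
    coords = [g for s, e in model.cds for g in range(s, e)]
    bases = [reference[model.contig][g] for g in coords]
    mutated = list(bases)
    mutated[coords.index(v.pos - 1)] = v.alt
    ref_nt, alt_nt = "".join(bases), "".join(mutated)
    if model.strand == "-":
        ref_nt = str(Seq(ref_nt).reverse_complement())
        alt_nt = str(Seq(alt_nt).reverse_complement())
    ref_aa = str(Seq(ref_nt).translate())
    alt_aa = str(Seq(alt_nt).translate())
    if ref_aa == alt_aa:
        return ("synonymous", None)
    diffs = [i for i, (a, b) in enumerate(zip(ref_aa, alt_aa)) if a != b]
    (i,) = diffs
    kind = "nonsense" if alt_aa[i] == "*" else "missense"
    return (kind, f"{ref_aa[i]}{i + 1}{alt_aa[i]}")


@pytest.mark.parametrize("strand", ["+", "-"])
def test_coding_effect_matches_full_retranslation_oracle(strand):
    # every substitution at every position of a 200-codon toy gene
    rng = np.random.default_rng(11)
    n_codons = 200
    seq = "".join(rng.choice(list("ACGT"), size=3 * n_codons + 40))
    gene = GeneModel(
        gene="G",
        transcript="T",
        contig="c1",
        strand=strand,
        exons=[(20, 20 + 3 * n_codons)],
        cds=[(20, 20 + 3 * n_codons)],
    )
    reference = {"c1": seq}
    for pos0 in range(20, 20 + 3 * n_codons):
        ref_b = seq[pos0]
        for alt_b in "ACGT":
            if alt_b == ref_b:
                continue
            v = make_variant(pos=pos0 + 1, ref=ref_b, alt=alt_b)
            eff = ann.coding_effect(v, gene, reference)
            kind, aa = _oracle_effect(v, gene, reference)
            assert eff.kind == kind, (pos0, alt_b, strand)
            if kind != "synonymous":
                assert eff.aa_change() == aa, (pos0, alt_b, strand)


def test_split_cds_minus_strand_effect():
    # CDS split across two exons on the minus strand
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    gene = GeneModel(
        gene="G",
        transcript="T",
        contig="c1",
        strand="-",
        exons=[(50, 110), (200, 260)],
        cds=[(50, 110), (200, 260)],
    )
    reference = {"c1": seq}
    for pos0 in list(range(50, 110)) + list(range(200, 260)):
        ref_b = seq[pos0]
        alt_b = "A" if ref_b != "A" else "C"
        v = make_variant(pos=pos0 + 1, ref=ref_b, alt=alt_b)
        eff = ann.coding_effect(v, gene, reference)
        kind, aa = _oracle_effect(v, gene, reference)
        assert eff.kind == kind
        if kind != "synonymous":
            assert eff.aa_change() == aa


# ---------------------------------------------------------------------------
# CpG context & transitions
# ---------------------------------------------------------------------------


def test_cpg_context_at_c_and_g():
    ref = _ref("AACGTT")
    assert ann.cpg_context(make_variant(pos=3, ref="C", alt="T"), ref)
    assert ann.cpg_context(make_variant(pos=4, ref="G", alt="A"), ref)
    assert not ann.cpg_context(make_variant(pos=2, ref="A", alt="G"), ref)


def test_cpg_context_all_false_without_cg():
    ref = _ref("ATTA")
    for pos in range(1, 5):
        base = ref["c1"][pos - 1]
        v = make_variant(pos=pos, ref=base, alt="G" if base != "G" else "C")
        assert not ann.cpg_context(v, ref)


def test_cpg_context_contig_edges():
    assert ann.cpg_context(make_variant(pos=1, ref="C", alt="T"), _ref("CG"))
    assert ann.cpg_context(make_variant(pos=2, ref="G", alt="A"), _ref("CG"))
    assert not ann.cpg_context(make_variant(pos=1, ref="C", alt="T"), _ref("CT"))


@given(st.text(alphabet="ACGT", min_size=3, max_size=30), st.integers(1, 28))
@settings(max_examples=200, deadline=None)
def test_cpg_context_strand_symmetric(seq, pos):
    # reverse-complementing the contig and mirroring the position preserves
    # CpG context
    if pos > len(seq):
        pos = len(seq)
    fwd = ann.cpg_context(make_variant(pos=pos, ref=seq[pos - 1], alt="A"), _ref(seq))
    rc = str(Seq(seq).reverse_complement())
    mirrored = len(seq) - pos + 1
    rev = ann.cpg_context(
        make_variant(pos=mirrored, ref=rc[mirrored - 1], alt="A"), _ref(rc)
    )
    assert fwd == rev


def test_transition_examples():
    assert ann.transition_flag(make_variant(ref="C", alt="T"))
    assert not ann.transition_flag(make_variant(ref="C", alt="A"))


def test_exactly_4_of_12_substitutions_are_transitions():
    flags = [
        ann.transition_flag(make_variant(ref=r, alt=a))
        for r in "ACGT"
        for a in "ACGT"
        if r != a
    ]
    assert len(flags) == 12
    assert sum(flags) == 4


def test_transition_rejects_indel():
    with pytest.raises(ValueError):
        ann.transition_flag(make_variant(ref="AT", alt="A"))
    with pytest.raises(ValueError):
        ann.cpg_context(make_variant(ref="AT", alt="A"), _ref("AATT"))
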