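import pytest

from trioscan.io import GeneModel, VariantCall
from trioscan.simulate import SimulationConfig, generate_trio, preset


def make_variant(
    contig="c1",
    pos=100,
    ref="A",
    alt="G",
    father=(0, 0),
    mother=(0, 0),
    proband=(0, 1),
    dp=30,
    gq=99,
    **kwargs,
):
    return VariantCall(
        contig=contig,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes={"father": father, "mother": mother, "proband": proband},
        depth={s: dp for s in ("father", "mother", "proband")},
        gq={s: gq for s in ("father", "mother", "proband")},
        **kwargs,
    )


def make_gene(
    gene="G1",
    transcript="T1",
    contig="c1",
    strand="+",
    exons=((100, 200), (300, 400)),
    cds=((130, 200), (300, 370)),
):
    model = GeneModel(
        gene=gene,
        transcript=transcript,
        contig=contig,
        strand=strand,
        exons=[tuple(e) for e in exons],
        cds=[tuple(c) for c in cds],
    )
    model.validate()
    return model


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7,
        contigs=[("t1", 60_000)],
        n_genes=8,
        n_inherited_variants=300,
        n_denovo_snv=10,
        n_denovo_indel=2,
        n_denovo_exonic=1,
        cpg_fraction=0.2,
        ts_fraction=0.6,
        compound_het_genes=1,
        bin_size=1000,
        depth_mean=30.0,
        depth_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_trio():
    config = SimulationConfig(
        seed=7,
        contigs=[("t1", 60_000)],
        n_genes=8,
        n_inherited_variants=300,
        n_denovo_snv=10,
        n_denovo_indel=2,
        n_denovo_exonic=1,
        cpg_fraction=0.2,
        ts_fraction=0.6,
        compound_het_genes=1,
    )
    return generate_trio(config)


@pytest.fixture(scope="session")
def paper_trio():
    return generate_trio(preset("paper_trio", seed=42))
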