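import filecmp
import os

import numpy as np
import pytest

from trioscan import io as tio
from trioscan import simulate as tsim
from trioscan.annotate import cpg_context, transition_flag
from trioscan.simulate import CnvEvent, SimulationConfig, TruthTable


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_same_seed_byte_identical_outputs(tmp_path, small_config):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    tsim.generate_trio(small_config).write(str(d1))
    tsim.generate_trio(small_config).write(str(d2))
    files = sorted(os.listdir(d1))
    assert files == sorted(os.listdir(d2))
    for name in files:
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_different_seed_changes_output(small_config):
    import dataclasses

    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    a = tsim.generate_trio(small_config)
    b = tsim.generate_trio(other)
    assert {v.key for v in a.variants} != {v.key for v in b.variants}


# ---------------------------------------------------------------------------
# preset content
# ---------------------------------------------------------------------------


def test_paper_trio_truth_counts(paper_trio):
    truth = paper_trio.truth
    assert len(truth.denovo_events) == 93
    assert sum(1 for d in truth.denovo_events if d.is_exonic) == 3
    snvs = [d for d in truth.denovo_events if len(d.ref) == len(d.alt) == 1]
    assert len(snvs) == 92
    assert sum(1 for d in snvs if d.is_cpg) == 18
    assert sum(1 for d in snvs if d.is_transition) == 62
    assert len(truth.compound_het_events) == 2
    assert len(paper_trio.variants) >= 10_000


def test_paper_trio_plants_tggac_deletion(paper_trio):
    deletions = [
        d
        for d in paper_trio.truth.denovo_events
        if len(d.ref) > 1 and d.ref[1:] == "TGGAC"
    ]
    assert len(deletions) == 1
    assert not deletions[0].is_exonic


def test_truth_flags_match_reference_annotations(paper_trio):
    by_key = {v.key: v for v in paper_trio.variants}
    for d in paper_trio.truth.denovo_events:
        v = by_key[(d.contig, d.pos, d.ref, d.alt)]
        if v.is_snv:
            assert cpg_context(v, paper_trio.reference) == d.is_cpg
            assert transition_flag(v) == d.is_transition


def test_truth_events_appear_exactly_once_in_vcf(paper_trio):
    keys = [v.key for v in paper_trio.variants]
    assert len(keys) == len(set(keys))
    key_set = set(keys)
    for d in paper_trio.truth.denovo_events:
        assert (d.contig, d.pos, d.ref, d.alt) in key_set
    for c in paper_trio.truth.compound_het_events:
        for contig, pos, ref, alt, _origin in c.variants:
            assert (contig, pos, ref, alt) in key_set


def test_mendelian_consistency_outside_denovo_sites(paper_trio):
    denovo_keys = {
        (d.contig, d.pos, d.ref, d.alt) for d in paper_trio.truth.denovo_events
    }
    for v in paper_trio.variants:
        if v.key in denovo_keys:
            assert v.genotypes["proband"] == (0, 1)
            assert v.genotypes["father"] == (0, 0)
            assert v.genotypes["mother"] == (0, 0)
        else:
            gf, gm, gp = (v.genotypes[s] for s in ("father", "mother", "proband"))
            combos = {tuple(sorted((a, b))) for a in gf for b in gm}
            assert tuple(sorted(gp)) in combos, v.key


def test_compound_het_truth_is_trans(paper_trio):
    by_key = {v.key: v for v in paper_trio.variants}
    for event in paper_trio.truth.compound_het_events:
        origins = set()
        for contig, pos, ref, alt, origin in event.variants:
            v = by_key[(contig, pos, ref, alt)]
            origins.add(origin)
            carrier = "father" if origin == "paternal" else "mother"
            other = "mother" if origin == "paternal" else "father"
            assert v.is_het(carrier)
            assert not v.has_alt(other)
            assert v.is_het("proband")
        assert origins == {"paternal", "maternal"}


def test_truth_table_json_round_trip(paper_trio):
    text = paper_trio.truth.to_json()
    back = TruthTable.from_json(text)
    assert back.denovo_events == paper_trio.truth.denovo_events
    assert back.cnv_events == paper_trio.truth.cnv_events
    assert [c.gene for c in back.compound_het_events] == [
        c.gene for c in paper_trio.truth.compound_het_events
    ]


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


def test_exonic_exceeding_total_denovo_rejected():
    config = SimulationConfig(
        seed=1, contigs=[("t1", 50_000)], n_denovo_snv=2, n_denovo_exonic=5
    )
    with pytest.raises(ValueError, match="exonic"):
        config.validate()


def test_exonic_without_coding_space_rejected():
    config = SimulationConfig(
        seed=1,
        contigs=[("t1", 50_000)],
        n_genes=0,
        n_denovo_snv=3,
        n_denovo_exonic=1,
    )
    with pytest.raises((ValueError, RuntimeError)):
        tsim.generate_trio(config)


def test_overlapping_cnv_events_rejected():
    config = SimulationConfig(
        seed=1,
        contigs=[("t1", 100_000)],
        cnv_events=[
            CnvEvent("t1", 10_000, 30_000, "hom_del", "hemi"),
            CnvEvent("t1", 25_000, 40_000, "hom_del", "hemi"),
        ],
    )
    with pytest.raises(ValueError, match="overlap"):
        config.validate()


def test_cnv_outside_contig_rejected():
    config = SimulationConfig(
        seed=1,
        contigs=[("t1", 100_000)],
        cnv_events=[CnvEvent("t1", 90_000, 200_000, "hom_del", "hemi")],
    )
    with pytest.raises(ValueError, match="range"):
        config.validate()


def test_bad_fraction_rejected():
    config = SimulationConfig(seed=1, contigs=[("t1", 50_000)], cpg_fraction=1.5)
    with pytest.raises(ValueError, match="fraction"):
        config.validate()


def test_contig_shorter_than_ten_bins_rejected():
    config = SimulationConfig(seed=1, contigs=[("t1", 5_000)], bin_size=1000)
    with pytest.raises(ValueError, match="10 bins"):
        tsim.generate_trio(config)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------


def test_no_cnv_no_noise_all_bins_at_mean():
    config = SimulationConfig(
        seed=1, contigs=[("t1", 20_000)], bin_size=1000, depth_mean=30.0,
        depth_noise_sd=0.0,
    )
    df = tsim.generate_depth_profile(config)
    assert len(df) == 20
    for col in ("depth_father", "depth_mother", "depth_proband"):
        assert (df[col] == 30.0).all()


def test_paper_cnv_child_depth_collapses_in_deletion():
    config = tsim.preset("paper_cnv", seed=9)
    df = tsim.generate_depth_profile(config)
    ev = config.cnv_events[0]
    inside = df[(df["start"] >= ev.start) & (df["end"] <= ev.end)]
    assert inside["depth_proband"].mean() < 0.05 * config.depth_mean
    assert inside["depth_father"].mean() == pytest.approx(
        config.depth_mean / 2, rel=0.1
    )


def test_single_bin_deletion_yields_exactly_one_low_bin():
    config = SimulationConfig(
        seed=1,
        contigs=[("t1", 20_000)],
        bin_size=1000,
        depth_mean=30.0,
        depth_noise_sd=0.0,
        cnv_events=[CnvEvent("t1", 5_000, 6_000, "hom_del", "hemi")],
    )
    df = tsim.generate_depth_profile(config)
    low = df[df["depth_proband"] < 1.0]
    assert len(low) == 1
    assert int(low["start"].iloc[0]) == 5_000


def test_depth_noise_is_seeded_and_truncated():
    config = SimulationConfig(
        seed=1, contigs=[("t1", 50_000)], bin_size=1000, depth_mean=1.0,
        depth_noise_sd=5.0,
    )
    a = tsim.generate_depth_profile(config)
    b = tsim.generate_depth_profile(config)
    assert a.equals(b)
    assert (a["depth_proband"] >= 0).all()
    assert a["depth_proband"].nunique() > 1


# ---------------------------------------------------------------------------
# read support
# ---------------------------------------------------------------------------


def test_edge_only_read_support_is_edge_confined():
    rng = np.random.default_rng(1)
    supports = tsim.generate_read_support(edge_only=True, read_length=101, rng=rng)
    assert supports
    for read_length, off in supports:
        assert off <= 10 or (read_length - 1 - off) <= 10


def test_non_edge_support_has_central_read():
    rng = np.random.default_rng(1)
    supports = tsim.generate_read_support(edge_only=False, read_length=101, rng=rng)
    assert any(off > 10 and (rl - 1 - off) > 10 for rl, off in supports)


def test_read_offsets_within_101bp_read():
    rng = np.random.default_rng(2)
    for edge_only in (True, False):
        for rl, off in tsim.generate_read_support(
            edge_only=edge_only, read_length=101, n_reads=50, rng=rng
        ):
            assert rl == 101
            assert 0 <= off <= 100


def test_edge_only_interacts_with_filter():
    from trioscan.denovo import filter_edge_indels
    from conftest import make_variant

    rng = np.random.default_rng(3)
    edge = make_variant(
        ref="ATG",
        alt="A",
        read_support=tsim.generate_read_support(True, 101, rng=rng),
    )
    central = make_variant(
        ref="ATG",
        alt="A",
        read_support=tsim.generate_read_support(False, 101, rng=rng),
    )
    assert not filter_edge_indels(edge)
    assert filter_edge_indels(central)


def test_short_read_length_rejected():
    with pytest.raises(ValueError, match="read_length"):
        tsim.generate_read_support(edge_only=False, read_length=15)


# ---------------------------------------------------------------------------
# emitted files
# ---------------------------------------------------------------------------


def test_written_dataset_reads_back(tmp_path, small_trio):
    out = tmp_path / "sim"
    small_trio.write(str(out))
    variants = tio.read_trio_vcf(str(out / "trio.vcf"))
    assert len(variants) == len(small_trio.variants)
    ref = tio.read_fasta(str(out / "reference.fa"))
    assert ref == small_trio.reference
    models = tio.read_gene_models(str(out / "genes.tsv"))
    assert models == small_trio.models
    truth = TruthTable.from_json((out / "truth.json").read_text())
    assert len(truth.denovo_events) == len(small_trio.truth.denovo_events)
    depth = tio.read_depth_table(str(out / "depth.tsv"))
    assert len(depth) == 60
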