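import edlib
import numpy as np
import pytest

from crossmeta.io_ace import build_inventory, parse_ace
from crossmeta.kmer_profile import revcomp
from crossmeta.profile import build_profile
from crossmeta.synthetic import (
    CommunitySpec,
    InputError,
    experiment_abundance,
    experiment_noise,
    experiment_overlap,
    logarithmic_abundances,
    make_genome_pool,
    sample_reads,
    toy_cross_assemble,
    uniform_abundances,
)


# ---------------------------------------------------------------------------
# genome pools


def test_genome_pool_is_deterministic_given_seed():
    a = make_genome_pool(3, (20000, 20000), (0.4, 0.6), seed=99)
    b = make_genome_pool(3, (20000, 20000), (0.4, 0.6), seed=99)
    assert [g.sequence for g in a] == [g.sequence for g in b]


def test_realized_gc_tracks_target_range():
    pool = make_genome_pool(5, (20000, 20000), (0.60, 0.65), seed=1)
    for g in pool:
        gc = (g.sequence.count("G") + g.sequence.count("C")) / len(g.sequence)
        assert 0.58 <= gc <= 0.67


def test_fixed_length_range_gives_exact_lengths():
    pool = make_genome_pool(4, (20000, 20000), (0.3, 0.7), seed=2)
    assert all(len(g) == 20000 for g in pool)


def test_divergent_pool_members_are_homologous():
    pool = make_genome_pool(3, (20000, 20000), (0.4, 0.5), seed=3, divergence=0.03)
    a, b = pool[0].sequence, pool[1].sequence
    mismatches = sum(x != y for x, y in zip(a, b))
    # two genomes each 3% diverged from one ancestor: ~6% apart
    assert 0.03 < mismatches / len(a) < 0.09


def test_invalid_pool_parameters_rejected():
    with pytest.raises(InputError):
        make_genome_pool(0)
    with pytest.raises(InputError):
        make_genome_pool(1, (500, 400))
    with pytest.raises(InputError):
        make_genome_pool(1, (2000, 2000), (0.9, 0.2))


def test_abundance_helpers():
    log = logarithmic_abundances(5, 0.5)
    assert log.sum() == pytest.approx(1.0)
    assert np.allclose(log[:-1] / log[1:], 2.0)
    assert uniform_abundances(4).tolist() == [0.25] * 4
    with pytest.raises(InputError):
        logarithmic_abundances(0)


# ---------------------------------------------------------------------------
# read simulation


def _one_genome_spec(label, gid, n_reads, noise=0.0, contaminants=()):
    return CommunitySpec(
        label=label,
        members=((gid, 1.0),),
        n_reads=n_reads,
        noise_fraction=noise,
        contaminants=tuple(contaminants),
    )


def test_error_free_reads_are_exact_substrings():
    pool = make_genome_pool(1, (20000, 20000), (0.4, 0.6), seed=4)
    genome = pool[0]
    rs = sample_reads(
        _one_genome_spec("s", genome.id, 50), pool, seed=5, error_rate=0.0
    )
    for read in rs.reads:
        seq = read.sequence if read.strand == "+" else revcomp(read.sequence)
        assert genome.sequence[read.start : read.start + len(seq)] == seq


def test_observed_error_rate_matches_the_2_percent_model():
    """Edit distance to the true source fragment reflects the error rate."""
    pool = make_genome_pool(1, (50000, 50000), (0.4, 0.6), seed=6)
    genome = pool[0]
    rs = sample_reads(_one_genome_spec("s", genome.id, 10_000), pool, seed=7)
    errors = bases = 0
    for read in rs.reads:
        seq = read.sequence if read.strand == "+" else revcomp(read.sequence)
        ref = genome.sequence[read.start : read.start + len(seq) + 30]
        res = edlib.align(seq, ref, mode="HW", task="distance")
        errors += res["editDistance"]
        bases += len(seq)
    # homopolymer inflation pushes the realized rate slightly above 2%
    assert 0.015 <= errors / bases <= 0.032


def test_read_lengths_truncated_to_bounds():
    pool = make_genome_pool(1, (20000, 20000), (0.4, 0.6), seed=8)
    rs = sample_reads(
        _one_genome_spec("s", pool[0].id, 2000), pool, seed=9, error_rate=0.0
    )
    lengths = [len(r.sequence) for r in rs.reads]
    assert min(lengths) >= 50
    assert max(lengths) <= 20000
    assert 400 < np.mean(lengths) < 500


def test_noise_fraction_controls_contaminant_reads():
    pool = make_genome_pool(2, (20000, 20000), (0.4, 0.6), seed=10)
    spec = _one_genome_spec("s", pool[0].id, 10_000, noise=0.3,
                            contaminants=[pool[1].id])
    rs = sample_reads(spec, pool, seed=11)
    n_noise = sum(r.genome_id == pool[1].id for r in rs.reads)
    assert 2800 <= n_noise <= 3200


def test_read_ids_unique_and_provenance_recorded(tmp_path):
    pool = make_genome_pool(1, (20000, 20000), (0.4, 0.6), seed=12)
    rs = sample_reads(_one_genome_spec("s", pool[0].id, 100), pool, seed=13)
    assert len(rs.read_ids()) == 100
    prov = rs.write_provenance(tmp_path / "p.tsv").read_text().splitlines()
    assert prov[0].split("\t") == ["read_id", "sample", "genome_id", "start", "strand"]
    assert len(prov) == 101


# ---------------------------------------------------------------------------
# toy cross-assembler


def _two_sample_readsets(shared=True, n_reads=150, seed=14):
    rng = np.random.default_rng(seed)
    if shared:
        pool = make_genome_pool(1, (20000, 20000), (0.4, 0.6), rng)
        g1 = g2 = pool[0]
        genomes = {g1.id: g1}
    else:
        pool = make_genome_pool(2, (20000, 20000), (0.4, 0.6), rng)
        g1, g2 = pool
        genomes = {g.id: g for g in pool}
    rs1 = sample_reads(_one_genome_spec("s1", g1.id, n_reads), genomes, rng,
                       error_rate=0.0)
    rs2 = sample_reads(_one_genome_spec("s2", g2.id, n_reads), genomes, rng,
                       error_rate=0.0)
    return rs1, rs2


def test_shared_genome_produces_cross_contigs():
    rs1, rs2 = _two_sample_readsets(shared=True)
    asm = toy_cross_assemble([rs1, rs2])
    cross = [
        cid for cid, comp in asm.sample_composition.items()
        if comp.get("s1") and comp.get("s2")
    ]
    assert cross


def test_disjoint_genomes_produce_no_cross_contigs():
    rs1, rs2 = _two_sample_readsets(shared=False)
    asm = toy_cross_assemble([rs1, rs2])
    for comp in asm.sample_composition.values():
        assert not (comp.get("s1") and comp.get("s2"))


def test_emitted_ace_reparses_to_identical_membership(tmp_path):
    rs1, rs2 = _two_sample_readsets(shared=True)
    asm = toy_cross_assemble([rs1, rs2])
    ace = asm.write_ace(tmp_path / "toy.ace")
    parsed = parse_ace(ace)
    assert [c.contig_id for c in parsed.contigs] == [
        c.contig_id for c in asm.membership.contigs
    ]
    for a, b in zip(parsed.contigs, asm.membership.contigs):
        assert a.read_ids == b.read_ids

    # and the resulting profile equals the assembler's ground truth
    inv = build_inventory(
        [("s1", rs1.read_ids(), None), ("s2", rs2.read_ids(), None)]
    )
    profile = build_profile(inv, parsed)
    for k, cid in enumerate(profile.contig_ids):
        comp = asm.sample_composition[cid]
        assert profile.counts[k].tolist() == [comp.get("s1", 0), comp.get("s2", 0)]
    assert profile.singletons == {
        s: sorted(ids) for s, ids in asm.singletons.items()
    }


def test_assembler_rejects_bad_parameters():
    rs1, rs2 = _two_sample_readsets(shared=True, n_reads=5)
    with pytest.raises(InputError):
        toy_cross_assemble([rs1, rs2], k=10)
    with pytest.raises(InputError):
        toy_cross_assemble([], k=21)


# ---------------------------------------------------------------------------
# experiment fixtures


def test_overlap_series_construction():
    fx = experiment_overlap(n_steps=5, species_per_sample=3, seed=15,
                            n_reads=20, genome_length=20000)
    overlaps = [o for o, _ in fx.steps]
    assert overlaps[0] == 1.0
    assert overlaps[-1] == 0.0
    assert overlaps == sorted(overlaps, reverse=True)
    with pytest.raises(InputError):
        experiment_overlap(n_steps=6, species_per_sample=3, seed=15)


def test_abundance_pairs_share_and_permute_profiles():
    fx = experiment_abundance(n_pairs=3, species=6, seed=16, n_reads=20,
                              genome_length=20000)
    for a, b in fx.pairs:
        assert np.allclose(fx.abundances[a], fx.abundances[b])
    base = np.sort(fx.abundances[fx.pairs[0][0]])
    for a, _ in fx.pairs[1:]:
        assert np.allclose(np.sort(fx.abundances[a]), base)
        assert not np.allclose(fx.abundances[a], fx.abundances[fx.pairs[0][0]])


def test_noise_extremes():
    fx = experiment_noise(noise_levels=(0.0, 1.0), seed=17, n_reads=30,
                          species_per_sample=2, genome_length=20000,
                          n_contaminants=4, contaminant_length=20000)
    contam = {g.id for g in fx.pools["contam"]}
    for rs in fx.readsets_by_level[0.0]:
        assert not any(r.genome_id in contam for r in rs.reads)
    for rs in fx.readsets_by_level[1.0]:
        assert all(r.genome_id in contam for r in rs.reads)


def test_generators_are_bit_reproducible():
    a = experiment_overlap(n_steps=3, species_per_sample=2, seed=18,
                           n_reads=10, genome_length=20000)
    b = experiment_overlap(n_steps=3, species_per_sample=2, seed=18,
                           n_reads=10, genome_length=20000)
    assert [r.sequence for r in a.reference.reads] == [
        r.sequence for r in b.reference.reads
    ]
    for (o1, r1), (o2, r2) in zip(a.steps, b.steps):
        assert o1 == o2
        assert [x.sequence for x in r1.reads] == [x.sequence for x in r2.reads]
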