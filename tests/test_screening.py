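import numpy as np
import pytest

from mgbssr.align import ParameterError, search_genome
from mgbssr.screening import ScreenParams, extract_flanked, screen_polymorphic
from mgbssr.sequence_io import GenomeSequence, reverse_complement
from mgbssr.ssr_detection import SSRLocus, detect_ssrs
from mgbssr.synthetic import PlantSpec, generate_genomes

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate_fraction(rng, seq, frac):
    n_mut = int(round(frac * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = [b for b in "ACGT" if b != out[p]][rng.integers(0, 3)]
    return "".join(out)


# --- flank extraction ----------------------------------------------------
def test_extract_flanked_interior_locus():
    rng = np.random.default_rng(0)
    seq = rand_seq(rng, 2000)
    core = "GCA" * 5
    seq = seq[:500] + core + seq[500:]
    locus = SSRLocus("g", "s", 500, 515, "GCA", 5)
    g = GenomeSequence("g", {"s": seq})
    [fl] = extract_flanked([locus], g, 300)
    assert len(fl.left_flank) == len(fl.right_flank) == 300
    assert not fl.truncated
    assert fl.full_seq == seq[200:815]


def test_extract_flanked_truncates_at_contig_edge():
    g = GenomeSequence("g", {"s": "ACGTACGTAC" + "GCA" * 4 + "TT"})
    locus = SSRLocus("g", "s", 10, 22, "GCA", 4)
    [fl] = extract_flanked([locus], g, 300)
    assert len(fl.left_flank) == 10
    assert len(fl.right_flank) == 2
    assert fl.truncated


def test_extract_flanked_zero_flank_is_core_only():
    g = GenomeSequence("g", {"s": "TT" + "GCA" * 4 + "TT"})
    locus = SSRLocus("g", "s", 2, 14, "GCA", 4)
    [fl] = extract_flanked([locus], g, 0)
    assert fl.full_seq == locus.core_seq


def test_extract_flanked_rejects_foreign_locus():
    g = GenomeSequence("g", {"s": "ACGT" * 10})
    with pytest.raises(KeyError):
        extract_flanked([SSRLocus("g", "other", 0, 12, "GCA", 4)], g)


# --- search_genome -------------------------------------------------------
def test_search_finds_exact_substring_on_plus_strand():
    rng = np.random.default_rng(1)
    target = GenomeSequence("t", {"c": rand_seq(rng, 5000)})
    query = target["c"][1000:1400]
    hits = search_genome(query, target)
    assert hits[0].strand == "+"
    assert hits[0].interval == (1000, 1400)
    assert hits[0].flank_identity == pytest.approx(1.0)


def test_search_finds_reverse_complement_on_minus_strand():
    rng = np.random.default_rng(2)
    target = GenomeSequence("t", {"c": rand_seq(rng, 5000)})
    query = reverse_complement(target["c"][2000:2300])
    hits = search_genome(query, target)
    assert hits[0].strand == "-"
    assert hits[0].interval == (2000, 2300)


@pytest.mark.parametrize("frac,expect_hit", [(0.05, True), (0.15, False)])
def test_identity_threshold_separates_divergence_levels(frac, expect_hit):
    rng = np.random.default_rng(3)
    target = GenomeSequence("t", {"c": rand_seq(rng, 5000)})
    query = mutate_fraction(rng, target["c"][1500:1800], frac)
    hits = search_genome(query, target, min_identity=0.90)
    assert bool(hits) == expect_hit


def test_query_shorter_than_seed_is_a_parameter_error():
    target = GenomeSequence("t", {"c": "ACGT" * 100})
    with pytest.raises(ParameterError):
        search_genome("ACGTACGT", target, seed_len=15)


def test_hits_sorted_by_descending_identity():
    rng = np.random.default_rng(4)
    block = rand_seq(rng, 200)
    far = mutate_fraction(rng, block, 0.05)
    target = GenomeSequence(
        "t", {"c": rand_seq(rng, 500) + block + rand_seq(rng, 500) + far + rand_seq(rng, 300)}
    )
    hits = search_genome(block, target, min_identity=0.8)
    assert len(hits) == 2
    assert hits[0].flank_identity >= hits[1].flank_identity
    assert hits[0].interval == (500, 700)


# --- the five-step screen ------------------------------------------------
def test_screen_recovers_planted_truth_exactly(small_trio):
    genomes, truth = small_trio
    res = screen_polymorphic(genomes, ScreenParams())
    by_iv = {t.anchor_interval: t for t in truth}
    assert len(res.loci) == len(truth)
    for pl in res.loci:
        t = by_iv[(pl.anchor.locus.start, pl.anchor.locus.end)]
        assert pl.status == t.expected_status, t.cls
        if pl.status == "retained":
            assert pl.repeat_counts == t.repeat_counts


def test_screen_funnel_is_a_non_increasing_candidate_count(small_trio):
    genomes, _ = small_trio
    f = screen_polymorphic(genomes, ScreenParams()).funnel
    stages = [f["detected"], f["self_unique"], f["cross_matched"],
              f["polymorphic"], f["clean_flanks"], f["retained"]]
    assert stages == sorted(stages, reverse=True)


def test_retained_loci_have_pairwise_distinct_counts_and_good_identity(small_trio):
    genomes, _ = small_trio
    res = screen_polymorphic(genomes, ScreenParams())
    for pl in res.retained:
        counts = list(pl.repeat_counts.values())
        assert len(set(counts)) == len(counts)
        assert all(h.flank_identity >= 0.90 for h in pl.hits.values())


def test_raising_min_identity_never_grows_the_retained_set(small_trio):
    genomes, _ = small_trio
    lo = {pl.marker_id for pl in screen_polymorphic(
        genomes, ScreenParams(min_identity=0.85)).retained}
    hi = {pl.marker_id for pl in screen_polymorphic(
        genomes, ScreenParams(min_identity=0.95)).retained}
    assert hi <= lo


def test_adding_a_genome_only_adds_constraints():
    spec = PlantSpec(
        n_per_class={"three_way_polymorphic": 4, "monomorphic": 2},
        genome_length=15_000,
        seed=21,
    )
    g4, truth4 = generate_genomes(spec, 4)
    res3 = screen_polymorphic(g4[:3], ScreenParams())
    res4 = screen_polymorphic(g4, ScreenParams())
    ret3 = {pl.marker_id for pl in res3.retained}
    ret4 = {pl.marker_id for pl in res4.retained}
    assert ret4 <= ret3


def test_two_genome_screen_degenerates_to_pairwise_difference():
    spec = PlantSpec(
        n_per_class={"two_way_only": 3, "monomorphic": 3},
        genome_length=12_000,
        seed=33,
    )
    genomes, truth = generate_genomes(spec, 2)
    res = screen_polymorphic(genomes, ScreenParams())
    by_iv = {t.anchor_interval: t for t in truth}
    for pl in res.loci:
        t = by_iv[(pl.anchor.locus.start, pl.anchor.locus.end)]
        expected = "retained" if t.cls == "two_way_only" else "dropped_monomorphic"
        assert pl.status == expected


def test_screen_requires_two_genomes_and_known_anchor(small_trio):
    genomes, _ = small_trio
    with pytest.raises(ValueError):
        screen_polymorphic(genomes[:1])
    with pytest.raises(ValueError):
        screen_polymorphic(genomes, anchor="nope")


def test_minus_strand_ortholog_is_matched():
    """A locus whose block is reverse-complemented in the other genome is
    still matched, and its repeat count read off the reverse complement."""
    rng = np.random.default_rng(8)
    left, right = rand_seq(rng, 300), rand_seq(rng, 300)
    motif = "GAT"
    blockA = left + motif * 5 + right
    blockB = left + motif * 7 + right
    gA = GenomeSequence("A", {"c": rand_seq(rng, 800) + blockA + rand_seq(rng, 800)})
    gB = GenomeSequence(
        "B", {"c": rand_seq(rng, 700) + reverse_complement(blockB) + rand_seq(rng, 900)}
    )
    loci = [l for l in detect_ssrs(gA) if l.motif in ("GAT", "ATG", "TGA")]
    assert len(loci) == 1
    res = screen_polymorphic([gA, gB], ScreenParams(), loci=loci)
    [pl] = res.loci
    assert pl.status == "retained"
    assert pl.hits["B"].strand == "-"
    assert pl.repeat_counts == {"A": 5, "B": 7}
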