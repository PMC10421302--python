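import math

import numpy as np
import pytest

from mgbssr.data import jujube_panel_primers
from mgbssr.primers import (
    DYES,
    M13_TAIL,
    EvaluationThresholds,
    PanelPackingError,
    PrimerPair,
    assign_panels,
    complementarity_runs,
    evaluate_primer_pair,
    melting_temperature,
)
from mgbssr.screening import FlankedSSR
from mgbssr.sequence_io import GenomeSequence, reverse_complement
from mgbssr.ssr_detection import SSRLocus

BASES = np.array(list("ACGT"))


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="module")
def planted_locus():
    """A flanked locus plus three genomes each containing it exactly once,
    and a primer pair designed inside the flanks."""
    rng = np.random.default_rng(42)
    left, right = rand_seq(rng, 300), rand_seq(rng, 300)
    core = "GCA" * 5
    fl = FlankedSSR(
        locus=SSRLocus("G1", "c", 1300, 1315, "GCA", 5),
        left_flank=left,
        right_flank=right,
    )
    genomes = []
    for i, count in enumerate((5, 6, 7)):
        block = left + "GCA" * count + right
        seq = rand_seq(rng, 1000) + block + rand_seq(rng, 1000)
        genomes.append(GenomeSequence(f"G{i + 1}", {"c": seq}))
    forward = left[250:272]
    reverse = reverse_complement(right[30:52])
    amplicon = 50 + 15 + 52  # forward start .. reverse 3' end on the anchor
    pair = PrimerPair("mk1", forward, reverse, amplicon)
    return fl, genomes, pair


def test_all_six_criteria_pass_for_a_well_designed_pair(planted_locus):
    fl, genomes, pair = planted_locus
    rep = evaluate_primer_pair(pair, fl, genomes)
    assert rep.overall, rep
    assert rep.details["sites_per_genome"] == {"G1": 1, "G2": 1, "G3": 1}


def test_primer_outside_flanks_fails_only_that_criterion(planted_locus):
    fl, genomes, pair = planted_locus
    # forward spanning into the core is no longer wholly within the flank
    bad = PrimerPair(
        "mk1", fl.left_flank[-10:] + fl.locus.core_seq[:12], pair.reverse_seq,
        pair.expected_amplicon_len,
    )
    rep = evaluate_primer_pair(bad, fl, genomes=None)
    assert not rep.in_flanks
    assert rep.amplicon_in_range and rep.m13_tagged


@pytest.mark.parametrize("amplicon,ok", [(50, True), (209, True), (300, True),
                                         (49, False), (320, False)])
def test_amplicon_size_window(planted_locus, amplicon, ok):
    fl, _, pair = planted_locus
    p = PrimerPair("x", pair.forward_seq, pair.reverse_seq, amplicon)
    assert evaluate_primer_pair(p, fl).amplicon_in_range == ok


def test_self_complementary_pair_is_a_full_length_dimer(planted_locus):
    fl, _, pair = planted_locus
    worst = PrimerPair(
        "x", pair.forward_seq, reverse_complement(pair.forward_seq),
        pair.expected_amplicon_len,
    )
    run, _ = complementarity_runs(worst.forward_seq, worst.reverse_seq)
    assert run == len(pair.forward_seq)
    assert not evaluate_primer_pair(worst, fl).no_dimer


def test_three_prime_anchored_short_run_fails():
    # forward 3' end "GGCCG" pairs with reverse 3' end "CGGCC"
    f = "ATTCAGATTACAGTAGGCCG"
    r = "TTAGACTTGGATTACGGCC"
    run, run3p = complementarity_runs(f, r)
    assert run3p >= 5
    fl = FlankedSSR(SSRLocus("g", "s", 0, 12, "GCA", 4), f, reverse_complement(r))
    assert not evaluate_primer_pair(
        PrimerPair("x", f, r, 100), fl
    ).no_dimer


def test_duplicated_site_breaks_specificity(planted_locus):
    fl, genomes, pair = planted_locus
    g = genomes[0]
    dup = GenomeSequence("dup", {"c": g["c"] + g["c"]})
    rep = evaluate_primer_pair(pair, fl, [dup])
    assert not rep.specific
    assert rep.details["sites_per_genome"]["dup"] == 2


def test_tm_tolerance_is_applied(planted_locus):
    fl, _, pair = planted_locus
    strict = EvaluationThresholds(tm_tolerance=0.0)
    rep = evaluate_primer_pair(pair, fl, thresholds=strict)
    assert rep.tm_compatible == (rep.details["delta_tm"] == 0.0)


def test_m13_tail_constant_and_tagging(planted_locus):
    fl, _, pair = planted_locus
    assert len(M13_TAIL) == 18
    assert pair.m13_tagged_forward == M13_TAIL + pair.forward_seq
    rep = evaluate_primer_pair(
        pair, fl, m13_tagged_forward="AAAA" + pair.forward_seq
    )
    assert not rep.m13_tagged


def test_rejects_empty_or_non_acgt_primers(planted_locus):
    fl, _, pair = planted_locus
    with pytest.raises(ValueError):
        evaluate_primer_pair(PrimerPair("x", "", pair.reverse_seq, 100), fl)
    with pytest.raises(ValueError):
        evaluate_primer_pair(PrimerPair("x", "ACGN", pair.reverse_seq, 100), fl)


# --- melting temperature -------------------------------------------------
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def _oracle_tm(seq, na_mM=50.0, c_nM=250.0):
    """Independent nearest-neighbor sum over the unified duplex parameters."""
    dh = ds = 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = _NN[a + b]
        dh += h
        ds += s
    for term in (seq[0], seq[-1]):
        if term in "GC":
            dh += 0.1
            ds += -2.8
        else:
            dh += 2.3
            ds += 4.1
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    return 1000 * dh / (ds + 1.987 * math.log(c_nM * 1e-9)) - 273.15


def test_tm_agrees_with_independent_nearest_neighbor_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(18, 26))
        s = rand_seq(rng, n)
        assert melting_temperature(s) == pytest.approx(_oracle_tm(s), abs=1.0)


# --- panel assembly ------------------------------------------------------
def test_twelve_pair_panel_packs_into_four_dyes_of_three():
    pairs = jujube_panel_primers()
    assert len(pairs) == 12
    panels = assign_panels(pairs, DYES, per_panel=3, min_separation=20)
    assert sorted(len(v) for v in panels.values()) == [3, 3, 3, 3]
    for members in panels.values():
        lens = sorted(m.expected_amplicon_len for m in members)
        assert all(b - a >= 20 for a, b in zip(lens, lens[1:]))


def test_single_pair_lands_on_first_dye():
    p = PrimerPair("x", "ACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG", 150)
    panels = assign_panels([p])
    assert panels["FAM"] == [p]


def test_identical_lengths_on_one_dye_is_a_packing_error():
    a = PrimerPair("a", "ACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG", 150)
    b = PrimerPair("b", "ACCTACGTACGTACGTAC", "TGCATGCATGCATGCATG", 150)
    with pytest.raises(PanelPackingError, match="conflicts"):
        assign_panels([a, b], dyes=("FAM",), per_panel=2)


def test_published_panel_amplicon_criterion():
    """All published amplicons sit in the 50-300 bp window except one
    309 bp outlier, which the size criterion flags."""
    pairs = jujube_panel_primers()
    out_of_range = [
        p.marker_id
        for p in pairs
        if not 50 <= p.expected_amplicon_len <= 300
    ]
    assert out_of_range == ["LSSR-6"]
    lssr4 = next(p for p in pairs if p.marker_id == "LSSR-4")
    assert lssr4.expected_amplicon_len == 209
    fl = FlankedSSR(SSRLocus("g", "s", 0, 21, "GCA", 7), "A" * 30, "C" * 30)
    assert evaluate_primer_pair(lssr4, fl).amplicon_in_range
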