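"""Motif machinery: parsing, scanning, exact p-values, discovery, enrichment."""

import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from facreg import motifs, synthgen
from facreg.motifs import (
    PWM,
    ScoreDistribution,
    MotifParseError,
    consensus_distance,
    enrichment_from_counts,
    fisher_exact_p,
    motif_enrichment,
    parse_iupac,
    pwm_scan,
    reverse_complement,
    scan_iupac,
    zoops_discover,
)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pattern, width",
    [("TG[CAG][GTA]GGG", 7), ("CC[ACTG]CCAA", 7), ("CCCC[atcg]CC", 7), ("ACGTN", 5), ("RYK", 3)],
)
def test_parse_iupac_widths(pattern, width):
    assert parse_iupac(pattern).width == width


def test_parse_iupac_case_insensitive():
    a = parse_iupac("cc[acTG]ccaa")
    b = parse_iupac("CC[ACTG]CCAA")
    assert a.position_sets == b.position_sets


def test_parse_errors_carry_position():
    with pytest.raises(MotifParseError) as e:
        parse_iupac("CC[]AA")
    assert e.value.position == 3
    with pytest.raises(MotifParseError):
        parse_iupac("AC!GT")
    with pytest.raises(MotifParseError):
        parse_iupac("")


# ---------------------------------------------------------------------------
# IUPAC scanning
# ---------------------------------------------------------------------------


def test_scan_plus_strand_hit_and_position_convention():
    """GARE in 'AAACCGCCAATTT' (L=13): leftmost base 4 -> upstream 10."""
    hits = scan_iupac({"s": "AAACCGCCAATTT"}, parse_iupac("CC[ACTG]CCAA"))
    assert len(hits) == 1
    h = hits.iloc[0]
    assert (h["strand"], h["start"], h["upstream_position"], h["match"]) == (
        "+", 4, 10, "CCGCCAA",
    )


def test_scan_minus_strand_reports_pattern_orientation():
    """CCCCTCA embeds rc(TGAGGGG): one minus-strand hit of the RhaR element."""
    hits = scan_iupac({"s": "AAAACCCCTCAAAAA"}, parse_iupac("TG[CAG][GTA]GGG"))
    assert len(hits) == 1
    assert hits.iloc[0]["strand"] == "-"
    assert hits.iloc[0]["match"] == "TGAGGGG"


def test_scan_reports_overlapping_hits():
    hits = scan_iupac({"s": "AAAAA"}, parse_iupac("AA"))
    assert len(hits[hits["strand"] == "+"]) == 4


def test_n_never_matches():
    hits = scan_iupac({"s": "CCNCCAA"}, parse_iupac("CC[ACTG]CCAA"))
    assert hits.empty


def _regex_oracle(seq, motif):
    """Brute-force regex scan of both strands, forward coordinates."""
    def clsre(m):
        return "".join(f"[{''.join(sorted(s))}]" for s in m.position_sets)

    out = set()
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        for i in range(len(seq) - motif.width + 1):
            if re.fullmatch(clsre(m), seq[i : i + motif.width]):
                out.add((strand, i + 1))
    return out


def test_scan_matches_regex_oracle_on_random_sequences():
    rng = np.random.default_rng(123)
    motif = parse_iupac("TG[CAG][GTA]GGG")
    for i in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        hits = scan_iupac({"s": seq}, motif)
        got = {(r["strand"], r["start"]) for _, r in hits.iterrows()}
        assert got == _regex_oracle(seq, motif)


@given(st.text(alphabet="ACGT", min_size=12, max_size=60))
@settings(max_examples=60, deadline=None)
def test_strand_symmetry_under_reverse_complement(seq):
    """Scanning rc(seq) swaps strands and maps pos' = L - (pos + w - 1) + 1."""
    motif = parse_iupac("GG[AT]C")
    w = motif.width
    L = len(seq)
    fwd = scan_iupac({"s": seq}, motif)
    rev = scan_iupac({"s": reverse_complement(seq)}, motif)
    mapped = {
        ("-" if r["strand"] == "+" else "+", L - (r["start"] + w - 1) + 1)
        for _, r in rev.iterrows()
    }
    assert {(r["strand"], r["start"]) for _, r in fwd.iterrows()} == mapped


# ---------------------------------------------------------------------------
# PWM scanning with exact p-values
# ---------------------------------------------------------------------------


def test_width1_pwm_tail_probability():
    """Best letter prob 0.97, uniform background: p(max score) = 0.25."""
    pwm = PWM(np.array([[0.97, 0.01, 0.01, 0.01]]))
    d = ScoreDistribution.from_pwm(pwm)
    assert d.pvalue_of_int(int(d.int_scores.max())) == pytest.approx(0.25)


@pytest.mark.parametrize("width", [2, 7])
def test_dp_pvalues_equal_enumeration(width):
    """DP tail equals exhaustive enumeration over all 4^w windows."""
    rng = np.random.default_rng(width)
    probs = rng.dirichlet([1.0, 1.0, 1.0, 1.0], size=width)
    bg = np.array([0.3, 0.2, 0.3, 0.2])
    pwm = PWM(probs, bg)
    d = ScoreDistribution.from_pwm(pwm)
    scores = {}
    for window in itertools.product(range(4), repeat=width):
        s = int(sum(d.int_scores[k, b] for k, b in enumerate(window)))
        prob = float(np.prod([bg[b] for b in window]))
        scores[s] = scores.get(s, 0.0) + prob
    for s in sorted(scores):
        tail = sum(p for t, p in scores.items() if t >= s)
        assert d.pvalue_of_int(s) == pytest.approx(tail, abs=1e-12)


def test_pwm_scan_threshold_is_strict():
    """Hits require p strictly below the threshold."""
    sites = ["ACGT", "ACGT", "ACGA", "ACGT"]
    pwm = PWM.from_sites(sites, motif_id="m")
    d = ScoreDistribution.from_pwm(pwm)
    best = int(d.int_scores.max(axis=1).sum())
    p_best = d.pvalue_of_int(best)
    hits = pwm_scan({"s": "AAACGTAAA"}, pwm, p_threshold=p_best * 2)
    assert not hits.empty
    assert (hits["p"] < p_best * 2).all()
    assert pwm_scan({"s": "AAACGTAAA"}, pwm, p_threshold=p_best / 2).empty


def test_pwm_scan_finds_planted_site_on_both_strands():
    pwm = PWM.from_sites(["TGAGGGG"] * 10, motif_id="rha")
    seq = "A" * 20 + "TGAGGGG" + "A" * 20 + reverse_complement("TGAGGGG") + "A" * 10
    hits = pwm_scan({"s": seq}, pwm, p_threshold=1e-3)
    assert set(hits["strand"]) == {"+", "-"}
    assert (hits["match"] == "TGAGGGG").all()


def test_pwm_scan_zero_background_letter_rejected():
    pwm = PWM(np.full((2, 4), 0.25), np.array([0.5, 0.5, 0.0, 0.0]))
    with pytest.raises(ValueError):
        pwm_scan({"s": "ACGT"}, pwm)


def test_pwm_from_sites_rows_normalised():
    pwm = PWM.from_sites(["ACGT", "ACGG"])
    assert np.allclose(pwm.probs.sum(axis=1), 1.0)
    # tied final position: argmax breaks ties toward the earlier letter
    assert pwm.consensus == "ACGG"


def test_meme_text_round_trippable_numbers():
    pwm = PWM.from_sites(["ACGT"] * 5, motif_id="x")
    text = pwm.to_meme_text(nsites=5)
    assert "MOTIF x" in text and "w= 4" in text


# ---------------------------------------------------------------------------
# ZOOPS discovery
# ---------------------------------------------------------------------------


def test_zoops_recovers_exact_planted_word():
    """20 sequences each containing TGAGGGG: top width-7 consensus is it."""
    rng = np.random.default_rng(3)
    seqs = {}
    for i in range(20):
        s = list("".join(rng.choice(list("ACGT"), size=200)))
        pos = rng.integers(200 - 7)
        s[pos : pos + 7] = list("TGAGGGG")
        seqs[f"s{i}"] = "".join(s)
    found = zoops_discover(seqs, width_range=(7, 7), seed=0)
    top = found[0]
    assert top.consensus in ("TGAGGGG", reverse_complement("TGAGGGG"))
    assert all(
        b >= a - 1e-9
        for a, b in zip(top.objective_trace, top.objective_trace[1:])
    )


def test_zoops_input_validation():
    with pytest.raises(ValueError):
        zoops_discover({"a": "ACGTACGTACGT"}, width_range=(6, 10))
    with pytest.raises(ValueError):
        zoops_discover({f"s{i}": "AAAAAAAAAAAA" for i in range(6)})
    with pytest.raises(ValueError):
        zoops_discover({f"s{i}": "ACGTA" for i in range(6)}, width_range=(6, 10))


# ---------------------------------------------------------------------------
# enrichment / conservation
# ---------------------------------------------------------------------------


def test_enrichment_printed_proportions_and_odds_ratio():
    """28/34 targets vs 3688/11717 genome-wide: 82.35% vs 31.47%, OR ~ 10.16."""
    enr = enrichment_from_counts(28, 34, 3688, 11717)
    assert enr.proportion_target * 100 == pytest.approx(82.35, abs=0.01)
    assert enr.proportion_background * 100 == pytest.approx(31.47, abs=0.01)
    assert enr.odds_ratio == pytest.approx((28 / 6) / (3688 / 8029), rel=1e-12)
    assert enr.odds_ratio == pytest.approx(10.16, abs=0.01)
    assert enr.p < 1e-8


def test_enrichment_degenerate_table():
    """All-zero presence: Haldane-corrected OR, p = 1."""
    enr = enrichment_from_counts(0, 10, 0, 100)
    assert enr.p == pytest.approx(1.0)
    assert enr.odds_ratio == pytest.approx((0.5 * 100.5) / (10.5 * 0.5))


def test_enrichment_empty_target_rejected():
    with pytest.raises(ValueError):
        enrichment_from_counts(0, 0, 5, 10)


def test_motif_enrichment_from_indicators():
    enr = motif_enrichment([True, True, False], [True] + [False] * 9)
    assert enr.target_with == 2 and enr.background_with == 1


@pytest.mark.parametrize("seed", range(20))
def test_fisher_p_matches_scipy_oracle(seed):
    rng = np.random.default_rng(seed)
    a, b, c, d = rng.integers(0, 120, size=4)
    if a + b == 0 or c + d == 0:
        a, b = 1, 1
    ours = fisher_exact_p(int(a), int(b), int(c), int(d))
    oracle = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    assert ours == pytest.approx(oracle, rel=1e-7, abs=1e-12)


def test_conservation_fractions_and_majority_flag():
    motif = parse_iupac("TGAGGGG")
    with_site = "A" * 30 + "TGAGGGG" + "A" * 30
    without = "C" * 67
    species = {
        "A_niger": {f"g{i}": with_site for i in range(4)} | {"g4": without},
        "A_oryzae": {"g0": without, "g1": without},
        "empty": {},
    }
    table = motifs.conservation_scan(species, motif).set_index("species")
    assert table.loc["A_niger", "fraction"] == pytest.approx(0.8)
    assert bool(table.loc["A_niger", "majority"])
    assert table.loc["A_oryzae", "fraction"] == 0.0
    assert not bool(table.loc["A_oryzae", "majority"])
    assert "empty" not in table.index


def test_conservation_agrees_with_scan_iupac_composition():
    seqs, planted = synthgen.planted_motif_fixture(n_seqs=10, n_planted=6, seed=5)
    motif = parse_iupac("TG[CAG][GTA]GGG")
    table = motifs.conservation_scan({"sp": seqs}, motif).iloc[0]
    ind = motifs.hit_indicator(seqs, motif)
    assert table["n_with_motif"] == sum(ind.values())


def test_consensus_distance_counts_disallowed_positions():
    motif = parse_iupac("TG[CAG][GTA]GGG")
    assert consensus_distance("TGCGGGG", motif) == 0
    assert consensus_distance("TGCCGGG", motif) == 1
    assert consensus_distance(reverse_complement("TGAGGGG"), motif) == 0
    # wider consensus containing the pattern exactly aligns with distance 0
    assert consensus_distance("TGCGGGGT", motif) == 0
    # a short fragment pays one per unaligned pattern position
    assert consensus_distance("GGG", motif) == 4
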