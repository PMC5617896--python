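"""Synthetic generator: class mix, determinism, NB means, planting."""

import numpy as np
import pytest

from facreg import motifs, synthgen
from facreg.core import MUTANT_ORDER, genotype_set


def test_class_counts_are_rounded_proportions():
    m = synthgen.build_model(
        100, {"none": 0.5, "single": 0.3, "and": 0.1, "or": 0.1}, seed=1
    )
    assert m.class_counts() == {
        "none": 50, "single": 30, "and": 10, "or": 10, "mixed": 0
    }


def test_largest_remainder_handles_non_exact_mixes():
    m = synthgen.build_model(
        10, {"none": 0.34, "single": 0.33, "and": 0.33}, seed=1, include_tf_genes=False
    )
    counts = m.class_counts()
    assert sum(counts.values()) == 10


def test_same_seed_gives_byte_identical_serialization():
    a = synthgen.build_model(50, seed=42).to_json()
    b = synthgen.build_model(50, seed=42).to_json()
    assert a == b
    assert synthgen.build_model(50, seed=43).to_json() != a


def test_model_json_round_trip(tmp_path):
    m = synthgen.build_model(20, seed=5)
    path = tmp_path / "model.json"
    m.to_json(path)
    m2 = synthgen.RegulatoryModel.from_json(path)
    assert m2.to_json() == m.to_json()


def test_all_dependencies_are_monotone():
    """Satisfied deletion sets of every gene's DNF are upward-closed."""
    m = synthgen.build_model(
        200, {"single": 0.25, "and": 0.25, "or": 0.25, "mixed": 0.25}, seed=3
    )
    subsets = [genotype_set(g) for g in ("ref",) + MUTANT_ORDER]
    for gene in m.genes:
        clauses = [set(c) for c in gene.clauses]
        sat = {
            frozenset(s)
            for s in subsets
            if any(c <= s for c in clauses)
        }
        for s in sat:
            for t in subsets:
                if s < t:
                    assert frozenset(t) in sat, (gene.gene_id, s, t)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        synthgen.build_model(10, {"none": 1.2, "single": -0.2}, seed=0)
    with pytest.raises(ValueError):
        synthgen.build_model(10, effect_range=(-1.0, 2.0), seed=0)
    with pytest.raises(ValueError):
        synthgen.build_model(10, {"none": 0.6, "single": 0.6}, seed=0)


def test_deletion_effect_halves_mean_per_log2_unit():
    """A gene depending on G with effect 2.0 has mean/4 in any gaaR deletant."""
    g = synthgen.GeneSpec(
        "x", 1000, baseline_log2=8.0, clauses=(("G",),), clause_effects=(2.0,),
        dispersion=0.0,
    )
    assert 2 ** g.mean_log2("ref") == pytest.approx(256.0)
    assert 2 ** g.mean_log2("G") == pytest.approx(64.0)
    assert 2 ** g.mean_log2("GA") == pytest.approx(64.0)


def test_satisfied_clause_effects_add_on_log2_scale():
    g = synthgen.GeneSpec(
        "x", 1000, baseline_log2=10.0, clauses=(("G",), ("A",)),
        clause_effects=(1.0, 2.0), dispersion=0.0,
    )
    assert g.mean_log2("G") == pytest.approx(9.0)
    assert g.mean_log2("A") == pytest.approx(8.0)
    assert g.mean_log2("GA") == pytest.approx(7.0)


def test_tf_gene_counts_are_zero_in_own_deletion_strains():
    model = synthgen.build_model(20, seed=2)
    design = synthgen.factorial_design(seed=2)
    cm = synthgen.simulate_counts(model, design, seed=2)
    for tf, gene in (("G", "gaaR"), ("A", "araR"), ("R", "rhaR")):
        for _, row in design.table.iterrows():
            if tf in genotype_set(row["genotype"]):
                assert cm.counts.loc[gene, row["sample_id"]] == 0
            elif row["genotype"] == "ref":
                assert cm.counts.loc[gene, row["sample_id"]] > 0


def test_simulation_is_deterministic_given_seed():
    model = synthgen.build_model(30, seed=9)
    design = synthgen.factorial_design(seed=9)
    a = synthgen.simulate_counts(model, design, seed=4)
    b = synthgen.simulate_counts(model, design, seed=4)
    assert a.counts.equals(b.counts)


def test_zero_dispersion_means_match_poisson_limit():
    """10,000 Poisson replicates of one gene: empirical mean within 1%."""
    gene = synthgen.GeneSpec(
        "x", 1000, baseline_log2=7.0, clauses=(), clause_effects=(),
        dispersion=0.0,
    )
    model = synthgen.RegulatoryModel([gene])
    import pandas as pd

    rows = [
        {
            "sample_id": f"ref_2h_r{i}",
            "genotype": "ref",
            "timepoint": "2h",
            "replicate": i,
            "library_size": model.reference_library_size,
        }
        for i in range(1, 10001)
    ]
    from facreg.core import Design

    design = Design(pd.DataFrame(rows))
    cm = synthgen.simulate_counts(model, design, seed=1)
    assert cm.counts.loc["x"].mean() == pytest.approx(128.0, rel=0.01)


def test_factorial_design_invariants():
    d = synthgen.factorial_design(replicates=2, seed=0)
    assert len(d.sample_ids) == 8 * 2 * 2
    assert "ref" in set(d.table["genotype"])
    lo, hi = d.table["library_size"].min(), d.table["library_size"].max()
    assert 0.8 * 5e6 <= lo <= hi <= 1.25 * 5e6


def test_promoters_carry_planted_motifs_for_every_mentioned_tf():
    model = synthgen.build_model(
        40, {"single": 0.4, "and": 0.3, "or": 0.3}, seed=6
    )
    promoters, truth = synthgen.generate_promoters(model, seed=6)
    for gene in model.genes:
        mentioned = {t for c in gene.clauses for t in c}
        planted = set(truth.sites_for(gene.gene_id)["tf"])
        assert planted == mentioned


def test_planted_sites_recoverable_by_exact_scanning():
    """Every truth-table site is found by the IUPAC scanner at its position."""
    model = synthgen.build_model(30, {"single": 0.5, "and": 0.5}, seed=8)
    promoters, truth = synthgen.generate_promoters(model, seed=8)
    motif_objs = {
        tf: motifs.parse_iupac(p, motif_id=f"{tf}") for tf, p in
        synthgen.DEFAULT_MOTIF_MAP.items()
    }
    for _, site in truth.table.iterrows():
        hits = motifs.scan_iupac(
            {site["gene_id"]: promoters[site["gene_id"]]}, motif_objs[site["tf"]]
        )
        found = hits[
            (hits["upstream_position"] == site["upstream_position"])
            & (hits["strand"] == site["strand"])
        ]
        assert len(found) == 1, site.to_dict()
        assert found.iloc[0]["match"] == site["site"]


def test_planting_error_when_promoter_too_short():
    model = synthgen.build_model(5, {"and": 1.0}, seed=0, include_tf_genes=False)
    with pytest.raises(ValueError):
        synthgen.generate_promoters(model, promoter_len=10, seed=0)


def test_background_match_rate_follows_product_formula():
    """Hits per strand per position on background ~ product of set probabilities."""
    rng = np.random.default_rng(0)
    motif = motifs.parse_iupac("TG[CAG][GTA]GGG")
    n, L = 400, 1000
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=L)) for i in range(n)
    }
    hits = motifs.scan_iupac(seqs, motif)
    positions = n * (L - motif.width + 1) * 2  # both strands
    expected = (1 / 4) ** 5 * (3 / 4) ** 2  # ~5.49e-4
    assert motif.match_probability() == pytest.approx(expected)
    assert len(hits) / positions == pytest.approx(expected, rel=0.15)
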