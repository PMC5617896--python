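"""Dependency classification: patterns, minimal monotone DNF, Venn, switches."""

from itertools import combinations, product

import pandas as pd
import pytest

from facreg import depclass
from facreg.core import MUTANT_ORDER, TF_ORDER, eval_dnf, genotype_set, parse_dnf
from facreg.depclass import (
    DependencyCall,
    DownPattern,
    down_pattern,
    infer_dependency,
    predominant_tf,
    temporal_switches,
    venn_partition,
)


def _pattern(true_genotypes, direction="down"):
    bits = tuple(g in true_genotypes for g in MUTANT_ORDER)
    return DownPattern("g", "2h", direction, bits)


def _calls_table(down_genotypes, timepoint="2h", direction="down"):
    calls = {}
    for g in MUTANT_ORDER:
        call = direction if g in down_genotypes else "ns"
        calls[(g, timepoint)] = pd.DataFrame(
            {"call": [call], "log2FC": [-2.0 if call == direction else 0.0]},
            index=["g"],
        )
    return calls


def test_down_pattern_gaaR_dependent_bits():
    """Down in all gaaR-deleted strains -> bits (1,0,0,1,0,1,1)."""
    calls = _calls_table({"G", "GA", "GR", "GAR"})
    pat = down_pattern(calls, "g", "2h", "down")
    assert pat.bits == (True, False, False, True, False, True, True)


def test_down_pattern_no_regulation_is_all_false():
    pat = down_pattern(_calls_table(set()), "g", "2h", "down")
    assert pat.bits == (False,) * 7


def test_down_pattern_up_direction_same_machinery():
    calls = _calls_table({"G", "GA", "GR", "GAR"}, direction="up")
    pat = down_pattern(calls, "g", "2h", "up")
    assert pat.bits == (True, False, False, True, False, True, True)


def test_down_pattern_missing_contrast_lists_it():
    calls = _calls_table({"G"})
    del calls[("AR", "2h")]
    with pytest.raises(ValueError, match="AR"):
        down_pattern(calls, "g", "2h", "down")


@pytest.mark.parametrize(
    "true_genotypes, expression, cls",
    [
        ({"G", "GA", "GR", "GAR"}, "G", "single"),
        ({"GA", "GAR"}, "G∧A", "and"),
        ({"GA", "GR", "GAR"}, "(G∧A)∨(G∧R)", "mixed"),
        ({"G", "A", "GA", "AR", "GR", "GAR"}, "G∨A", "or"),
        ({"G"}, "complex", "complex"),
        (set(), "none", "none"),
        ({"G", "A", "R", "GA", "AR", "GR", "GAR"}, "G∨A∨R", "or"),
    ],
)
def test_infer_dependency_named_patterns(true_genotypes, expression, cls):
    call = infer_dependency(_pattern(true_genotypes))
    assert call.expression == expression
    assert call.dependency_class == cls


def _all_monotone_true_sets():
    """All upward-closed families over the 7 nonempty deletion sets."""
    subsets = [frozenset(s) for r in (1, 2, 3) for s in combinations(TF_ORDER, r)]
    families = []
    for bits in product([False, True], repeat=7):
        fam = {s for s, b in zip(subsets, bits) if b}
        if all(t in fam for s in fam for t in subsets if s < t):
            families.append(fam)
    return subsets, families


def test_soundness_over_all_monotone_patterns():
    """Evaluating the inferred DNF reproduces every monotone pattern exactly."""
    subsets, families = _all_monotone_true_sets()
    assert len(families) == 19  # Dedekind count with f(empty)=false
    for fam in families:
        call = infer_dependency(_pattern({g for g in MUTANT_ORDER if genotype_set(g) in fam}))
        assert call.expression != "complex"
        if not fam:
            assert call.expression == "none"
            continue
        clauses = parse_dnf(call.expression)
        recovered = {s for s in subsets if eval_dnf(clauses, s)}
        assert recovered == fam


def test_minimality_against_brute_force_clause_search():
    """The returned DNF has the fewest clauses, then fewest literals, among
    all clause sets reproducing the pattern (exhaustive search)."""
    subsets, families = _all_monotone_true_sets()
    all_clause_sets = []
    for r in range(1, 8):
        all_clause_sets.extend(combinations(subsets, r))
    for fam in families:
        if not fam:
            continue
        call = infer_dependency(
            _pattern({g for g in MUTANT_ORDER if genotype_set(g) in fam})
        )
        ours = parse_dnf(call.expression)
        matching = [
            cs
            for cs in all_clause_sets
            if {s for s in subsets if eval_dnf(cs, s)} == fam
        ]
        best = min(
            (len(cs), sum(len(c) for c in cs)) for cs in matching
        )
        assert (len(ours), sum(len(c) for c in ours)) == best


def test_non_monotone_patterns_are_complex():
    """A regulated set with an unregulated superset forces 'complex'."""
    assert infer_dependency(_pattern({"G"})).dependency_class == "complex"
    assert infer_dependency(_pattern({"GA"})).dependency_class == "complex"
    assert infer_dependency(_pattern({"G", "A"})).dependency_class == "complex"
    # the triple deletion alone is monotone-consistent (top of the lattice)
    call = infer_dependency(_pattern({"GAR"}))
    assert call.dependency_class == "and" and call.expression == "G∧A∧R"


def _call(expr, direction="down"):
    return DependencyCall("g", "2h", direction, expr, "or")


def test_predominant_tf_argmax_and_tie():
    tfs, status = predominant_tf(_call("G∨A"), {"G": -3.2, "A": -1.1})
    assert tfs == {"G"} and status == "determined"
    tfs, status = predominant_tf(_call("G∨A"), {"G": -2.0, "A": -2.05})
    assert tfs == {"G", "A"} and status == "tie"


def test_predominant_tf_weak_and_gene_documented_behaviour():
    """AND genes with ns single mutants: rule still applies to the values."""
    tfs, status = predominant_tf(_call("G∧A"), {"G": -0.2, "A": -0.1})
    assert tfs == {"G", "A"} and status == "tie"  # within the 0.1 margin
    tfs, status = predominant_tf(_call("G∧A"), {"G": -0.3, "A": -0.1})
    assert tfs == {"G"} and status == "determined"


def test_predominant_tf_missing_value_undetermined():
    tfs, status = predominant_tf(_call("G∨A"), {"G": -3.0})
    assert tfs == frozenset() and status == "undetermined"


def test_predominant_tf_up_direction_uses_maximum():
    tfs, status = predominant_tf(_call("G∨A", "up"), {"G": 2.5, "A": 0.4})
    assert tfs == {"G"} and status == "determined"


def test_venn_membership_rule():
    calls = [_call("G"), _call("G∨A"), _call("G∧A")]
    venn = venn_partition(calls)
    assert venn["G"] == 1 and venn["GA"] == 2
    assert sum(v for k, v in venn.items() if k != "none") == 3


def test_venn_all_none():
    calls = [_call("none"), _call("complex")]
    venn = venn_partition(calls)
    assert venn["none"] == 2
    assert sum(v for k, v in venn.items() if k != "none") == 0


def test_temporal_switches_and_canonicalization():
    early = [
        DependencyCall("pmeA", "2h", "down", "G∨A", "or"),
        DependencyCall("same", "2h", "down", "A∨G", "or"),
        DependencyCall("only2h", "2h", "down", "G", "single"),
    ]
    late = [
        DependencyCall("pmeA", "8h", "down", "G∧R", "and"),
        DependencyCall("same", "8h", "down", "G∨A", "or"),
    ]
    sw = temporal_switches(early, late).set_index("gene_id")
    assert bool(sw.loc["pmeA", "switched"])
    assert not bool(sw.loc["same", "switched"])  # canonical forms equal
    assert bool(sw.loc["only2h", "one_sided"])


def test_classify_all_attributes_predominant(synthetic_run=None):
    calls = _calls_table({"G", "A", "GA", "AR", "GR", "GAR"})
    # give G a stronger single-deletion effect than A
    calls[("G", "2h")].loc["g", "log2FC"] = -3.0
    calls[("A", "2h")].loc["g", "log2FC"] = -1.0
    out = depclass.classify_all(calls, "2h", "down")
    assert out[0].expression == "G∨A"
    assert out[0].predominant == {"G"}
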