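"""Combinatorial TF-dependency classification from per-genotype DE calls.

The core inference of the factorial deletion design: a gene's pattern of
significant down- (or up-) regulation across the seven deletion genotypes is
interpreted as a Boolean function of the three deleted activators.  Because
deleting additional TFs cannot restore expression that an earlier deletion
removed, biologically interpretable patterns are *monotone*: the set of
deletion sets that regulate the gene is upward-closed under inclusion.  For
such patterns the unique minimal monotone DNF (clauses = minimal regulating
deletion sets) is returned, e.g.

* down in every strain lacking gaaR -> ``"G"`` (class ``single``),
* down only when both gaaR and araR are gone -> ``"G∧A"`` (class ``and``),
* down whenever gaaR and/or araR is gone -> ``"G∨A"`` (class ``or``),
* down in the GA and GR doubles and the triple -> ``"(G∧A)∨(G∧R)"``
  (class ``mixed``).

Patterns that are not upward-closed are labelled ``complex`` and never
forced into a DNF.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    MUTANT_ORDER,
    TF_ORDER,
    canonical_expression,
    clause_string,
    dnf_string,
    eval_dnf,
    genotype_set,
    genotype_string,
    parse_dnf,
)

#: All eight deletion sets, reference first.
ALL_DELETION_SETS: tuple[frozenset[str], ...] = tuple(
    frozenset(s)
    for r in range(4)
    for s in combinations(TF_ORDER, r)
)


@dataclass(frozen=True)
class DownPattern:
    """Regulation bits over the seven mutant genotypes, in ``MUTANT_ORDER``."""

    gene_id: str
    timepoint: str
    direction: str  # "down" or "up"
    bits: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != 7:
            raise ValueError("pattern must have exactly 7 bits")
        if self.direction not in ("down", "up"):
            raise ValueError("direction must be 'down' or 'up'")

    def true_sets(self) -> set[frozenset[str]]:
        return {
            genotype_set(g) for g, b in zip(MUTANT_ORDER, self.bits) if b
        }


@dataclass
class DependencyCall:
    """Inferred dependency of one gene at one timepoint."""

    gene_id: str
    timepoint: str
    direction: str
    expression: str  # minimal monotone DNF, "none", or "complex"
    dependency_class: str  # none/single/and/or/mixed/complex
    predominant: frozenset[str] = frozenset()
    predominant_status: str = "n/a"  # n/a | determined | tie | undetermined

    @property
    def mentioned_tfs(self) -> frozenset[str]:
        if self.expression in ("none", "complex"):
            return frozenset()
        return frozenset(t for c in parse_dnf(self.expression) for t in c)


def down_pattern(
    calls: Mapping[tuple[str, str], pd.DataFrame],
    gene_id: str,
    timepoint: str,
    direction: str = "down",
) -> DownPattern:
    """Build the 7-bit regulation pattern of a gene from per-contrast calls.

    ``calls`` maps (genotype, timepoint) to a contrast table indexed by gene
    with a ``call`` column.  All seven mutant contrasts must be present.
    """
    missing = [g for g in MUTANT_ORDER if (g, timepoint) not in calls]
    if missing:
        raise ValueError(
            f"missing contrasts at {timepoint!r}: {missing}"
        )
    bits = []
    for g in MUTANT_ORDER:
        df = calls[(g, timepoint)]
        if gene_id not in df.index:
            raise KeyError(f"gene {gene_id!r} absent from contrast {(g, timepoint)}")
        bits.append(str(df.loc[gene_id, "call"]) == direction)
    return DownPattern(gene_id, timepoint, direction, tuple(bits))


def infer_dependency(pattern: DownPattern) -> DependencyCall:
    """Minimal monotone DNF consistent with a regulation pattern.

    The 7-bit pattern is extended to the full 8-genotype truth table with the
    reference fixed to false.  If the regulating deletion sets are
    upward-closed under inclusion, the minimal sets form the clauses of the
    unique minimal DNF; otherwise the call is ``complex``.
    """
    true_sets = pattern.true_sets()
    if not true_sets:
        return DependencyCall(
            pattern.gene_id, pattern.timepoint, pattern.direction, "none", "none"
        )
    # upward closure over all supersets (reference = empty set is false)
    for s in true_sets:
        for t in ALL_DELETION_SETS:
            if s < t and t not in true_sets:
                return DependencyCall(
                    pattern.gene_id,
                    pattern.timepoint,
                    pattern.direction,
                    "complex",
                    "complex",
                )
    minimal = {
        s for s in true_sets if not any(t < s for t in true_sets)
    }
    expression = dnf_string(minimal)
    sizes = [len(c) for c in minimal]
    if len(minimal) == 1:
        cls = "single" if sizes[0] == 1 else "and"
    elif all(x == 1 for x in sizes):
        cls = "or"
    else:
        cls = "mixed"
    return DependencyCall(
        pattern.gene_id, pattern.timepoint, pattern.direction, expression, cls
    )


def predominant_tf(
    call: DependencyCall,
    single_mutant_log2fc: Mapping[str, float],
    tie_margin: float = 0.1,
) -> tuple[frozenset[str], str]:
    """TF(s) with the strongest single-deletion effect among those in the call.

    For ``down`` calls the extreme is the most negative single-mutant log2
    fold change; TFs within ``tie_margin`` log2 units of the extreme are
    returned (ties possible).  Returns ``(tfs, status)`` with status one of
    ``determined``, ``tie``, ``undetermined`` (a mentioned TF lacks a value)
    or ``n/a`` (fewer than two TFs mentioned).
    """
    tfs = call.mentioned_tfs
    if len(tfs) == 0:
        return frozenset(), "n/a"
    if len(tfs) == 1:
        return tfs, "n/a"
    if any(t not in single_mutant_log2fc or pd.isna(single_mutant_log2fc[t]) for t in tfs):
        return frozenset(), "undetermined"
    values = {t: float(single_mutant_log2fc[t]) for t in tfs}
    if call.direction == "down":
        extreme = min(values.values())
        chosen = frozenset(t for t, v in values.items() if v <= extreme + tie_margin)
    else:
        extreme = max(values.values())
        chosen = frozenset(t for t, v in values.items() if v >= extreme - tie_margin)
    return chosen, ("determined" if len(chosen) == 1 else "tie")


VENN_REGIONS: tuple[str, ...] = ("G", "A", "R", "GA", "GR", "AR", "GAR")


def venn_partition(calls: Iterable[DependencyCall]) -> dict[str, int]:
    """Counts for the 7 regions of the three-TF Venn diagram plus ``none``.

    A gene sits in circle X iff literal X appears in its dependency
    expression; its region is the exact set of such circles.  ``none`` and
    ``complex`` calls fall into the ``none`` bucket.
    """
    out = {region: 0 for region in VENN_REGIONS}
    out["none"] = 0
    for call in calls:
        tfs = call.mentioned_tfs
        if not tfs:
            out["none"] += 1
        else:
            out[genotype_string(tfs)] += 1
    return out


@dataclass
class TemporalSwitch:
    gene_id: str
    expression_early: str
    expression_late: str
    switched: bool


def temporal_switches(
    calls_early: Iterable[DependencyCall], calls_late: Iterable[DependencyCall]
) -> pd.DataFrame:
    """Genes whose dependency expression differs between the two timepoints.

    Expressions are canonicalised (clauses and literals sorted) before
    comparison, so ``"A∨G"`` equals ``"G∨A"``.  Genes present at only one
    timepoint are reported with a ``one_sided`` flag and no switch call.
    """
    early = {c.gene_id: canonical_expression(c.expression) for c in calls_early}
    late = {c.gene_id: canonical_expression(c.expression) for c in calls_late}
    rows = []
    for gene in sorted(set(early) | set(late)):
        e, l = early.get(gene), late.get(gene)
        one_sided = e is None or l is None
        rows.append(
            {
                "gene_id": gene,
                "expression_early": e if e is not None else ".",
                "expression_late": l if l is not None else ".",
                "one_sided": one_sided,
                "switched": (not one_sided) and e != l,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "expression_early", "expression_late", "one_sided", "switched"],
    )


def classify_all(
    calls: Mapping[tuple[str, str], pd.DataFrame],
    timepoint: str,
    direction: str = "down",
    genes: Sequence[str] | None = None,
    tie_margin: float = 0.1,
) -> list[DependencyCall]:
    """Dependency calls for every gene at one timepoint and direction.

    The predominant TF of multi-TF calls is attributed from the single-mutant
    log2 fold changes at the same timepoint.
    """
    ref_df = calls[(MUTANT_ORDER[0], timepoint)]
    if genes is None:
        genes = list(ref_df.index)
    singles = {
        t: calls[(t, timepoint)]["log2FC"] for t in TF_ORDER if (t, timepoint) in calls
    }
    out = []
    for gene in genes:
        call = infer_dependency(down_pattern(calls, gene, timepoint, direction))
        if len(call.mentioned_tfs) >= 2:
            lfcs = {
                t: singles[t].loc[gene]
                for t in call.mentioned_tfs
                if t in singles and gene in singles[t].index
            }
            call.predominant, call.predominant_status = predominant_tf(
                call, lfcs, tie_margin
            )
        elif len(call.mentioned_tfs) == 1:
            call.predominant, call.predominant_status = call.mentioned_tfs, "n/a"
        out.append(call)
    return out


def calls_to_frame(calls: Iterable[DependencyCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "timepoint": c.timepoint,
            "direction": c.direction,
            "expression": c.expression,
            "class": c.dependency_class,
            "predominant": genotype_string(c.predominant) if c.predominant else ".",
            "predominant_status": c.predominant_status,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "timepoint",
            "direction",
            "expression",
            "class",
            "predominant",
            "predominant_status",
        ],
    )
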