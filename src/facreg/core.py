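"""Shared containers and conventions for the factorial TF-deletion pipeline.

The study design deletes up to three transcriptional activators —
GaaR (``G``), AraR (``A``) and RhaR (``R``) — in all eight combinations.
Throughout the package a *genotype* is the set of deleted TFs, written as a
string of single-letter TF codes in the fixed order ``G < A < R``
(e.g. ``"GA"`` for the double deletant lacking both GaaR and AraR); the
reference (no deletion) genotype is written ``"ref"``.

Dependency expressions are monotone DNF formulas over the same literals,
rendered with ``∧`` / ``∨`` (e.g. ``"G∧A"``, ``"(G∧A)∨(G∧R)"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Fixed transcription-factor order used for genotype strings and DNF literals.
TF_ORDER: tuple[str, ...] = ("G", "A", "R")

#: Full TF gene names keyed by their single-letter code.
TF_GENES: dict[str, str] = {"G": "gaaR", "A": "araR", "R": "rhaR"}

#: The seven deletion genotypes in canonical reporting order
#: (singles, doubles, triple).
MUTANT_ORDER: tuple[str, ...] = ("G", "A", "R", "GA", "AR", "GR", "GAR")

#: All eight genotypes including the reference strain.
GENOTYPE_ORDER: tuple[str, ...] = ("ref",) + MUTANT_ORDER

REFERENCE = "ref"


def genotype_set(genotype: str) -> frozenset[str]:
    """Deleted-TF set of a genotype string (``"ref"`` -> empty set)."""
    if genotype == REFERENCE:
        return frozenset()
    letters = set(genotype)
    if not letters <= set(TF_ORDER) or len(letters) != len(genotype):
        raise ValueError(f"invalid genotype string: {genotype!r}")
    return frozenset(letters)


def genotype_string(deleted: Iterable[str]) -> str:
    """Canonical genotype string for a set of deleted TFs."""
    deleted = set(deleted)
    if not deleted:
        return REFERENCE
    if not deleted <= set(TF_ORDER):
        raise ValueError(f"unknown TF letters: {deleted - set(TF_ORDER)}")
    return "".join(t for t in TF_ORDER if t in deleted)


def clause_string(clause: Iterable[str]) -> str:
    """Render an AND-clause (set of TF literals) as e.g. ``"G∧A"``."""
    letters = [t for t in TF_ORDER if t in set(clause)]
    if not letters:
        raise ValueError("empty clause")
    return "∧".join(letters)


def dnf_string(clauses: Iterable[frozenset[str]]) -> str:
    """Canonical string for a monotone DNF given as a set of clauses.

    Clauses are sorted by their literal indices in ``TF_ORDER``; multi-literal
    clauses are parenthesised when the formula has more than one clause.
    Returns ``"none"`` for the empty clause set.
    """
    cl = sorted(
        {frozenset(c) for c in clauses},
        key=lambda c: tuple(TF_ORDER.index(t) for t in sorted(c, key=TF_ORDER.index)),
    )
    if not cl:
        return "none"
    if len(cl) == 1:
        return clause_string(cl[0])
    parts = [
        f"({clause_string(c)})" if len(c) > 1 else clause_string(c) for c in cl
    ]
    return "∨".join(parts)


def parse_dnf(expression: str) -> frozenset[frozenset[str]]:
    """Parse a DNF string back to its clause set.

    Accepts the output of :func:`dnf_string` plus the special values
    ``"none"`` (no dependency; empty clause set) — ``"complex"`` is rejected
    because it has no Boolean semantics.
    """
    expression = expression.strip()
    if expression == "none":
        return frozenset()
    if expression == "complex":
        raise ValueError("'complex' calls have no DNF representation")
    clauses = set()
    for part in expression.split("∨"):
        part = part.strip().strip("()")
        literals = frozenset(x.strip() for x in part.split("∧"))
        if not literals or not literals <= set(TF_ORDER):
            raise ValueError(f"cannot parse clause {part!r} in {expression!r}")
        clauses.add(literals)
    return frozenset(clauses)


def canonical_expression(expression: str) -> str:
    """Canonical form of a DNF string (clauses and literals sorted)."""
    if expression.strip() in ("none", "complex"):
        return expression.strip()
    return dnf_string(parse_dnf(expression))


def eval_dnf(clauses: Iterable[frozenset[str]], deleted: Iterable[str]) -> bool:
    """Evaluate a DNF on a deletion set: true iff some clause is fully deleted."""
    deleted = set(deleted)
    return any(set(c) <= deleted for c in clauses)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ("sample_id", "genotype", "timepoint", "replicate", "library_size")


@dataclass
class Design:
    """Sample sheet of a factorial deletion experiment.

    ``table`` has one row per sample with columns ``sample_id``, ``genotype``
    (canonical string), ``timepoint``, ``replicate`` and ``library_size``
    (expected total mapped fragments).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(DESIGN_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        for g in self.table["genotype"]:
            genotype_set(g)  # validates
        if REFERENCE not in set(self.table["genotype"]):
            raise ValueError("design must contain the reference genotype")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def timepoints(self) -> list[str]:
        return sorted(set(self.table["timepoint"]))

    def samples_for(self, genotype: str, timepoint: str | None = None) -> list[str]:
        t = self.table
        mask = t["genotype"] == genotype
        if timepoint is not None:
            mask &= t["timepoint"] == timepoint
        return list(t.loc[mask, "sample_id"])

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Sample ids per (genotype, timepoint) group."""
        out: dict[tuple[str, str], list[str]] = {}
        for (g, tp), sub in self.table.groupby(["genotype", "timepoint"], sort=False):
            out[(g, tp)] = list(sub["sample_id"])
        return out

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Design":
        t = pd.read_csv(path, sep="\t", dtype={"genotype": str, "timepoint": str})
        return cls(t)


# ---------------------------------------------------------------------------
# Count / expression matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer fragment counts (genes x samples) with gene lengths and design."""

    counts: pd.DataFrame  # genes x samples
    lengths: pd.Series  # bp per gene
    design: Design

    def __post_init__(self) -> None:
        c = self.counts
        if (c.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c.values, np.round(c.values)):
            raise ValueError("counts must be integral")
        if list(c.columns) != self.design.sample_ids:
            # allow reordering if the sets match
            if set(c.columns) == set(self.design.sample_ids):
                self.counts = c = c[self.design.sample_ids]
            else:
                raise ValueError("count columns do not match design sample ids")
        self.lengths = self.lengths.reindex(c.index)
        if self.lengths.isna().any():
            raise ValueError("missing gene lengths")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def write_tsv(self, counts_path: str | Path, lengths_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": self.lengths.index, "length_bp": self.lengths.values}
        ).to_csv(lengths_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, counts_path: str | Path, lengths_path: str | Path, design: Design
    ) -> "CountMatrix":
        c = pd.read_csv(counts_path, sep="\t").set_index("gene_id")
        ln = pd.read_csv(lengths_path, sep="\t").set_index("gene_id")["length_bp"]
        return cls(c, ln, design)


@dataclass
class ExpressionMatrix:
    """FPKM values on the same axes as the source :class:`CountMatrix`."""

    fpkm: pd.DataFrame
    lengths: pd.Series
    design: Design

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    def write_tsv(self, path: str | Path) -> None:
        out = self.fpkm.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
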