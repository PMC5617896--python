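"""Synthetic factorial-deletion transcriptomes and promoters with known truth.

The generator emulates the study conditions of a three-activator deletion
panel: 8 genotypes x 2 timepoints x 2 replicates of negative-binomial RNA-seq
counts whose gene-wise means follow monotone regulatory logic over the
activators GaaR, AraR and RhaR, TF genes with hard-zero expression in their
own deletion strains, and 1-kb promoters carrying planted degenerate binding
motifs for every activator a gene depends on.

Counts are parameterised as NB(mean mu, dispersion alpha) with
Var = mu + alpha * mu**2; alpha = 0 degenerates to Poisson.  A DNF clause
contributes its full log2 effect when all of its TFs are deleted, and the
effects of multiple satisfied clauses add on the log2 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    TF_ORDER,
    TF_GENES,
    GENOTYPE_ORDER,
    REFERENCE,
    CountMatrix,
    Design,
    dnf_string,
    eval_dnf,
    genotype_set,
    parse_dnf,
)
from .motifs import IUPACMotif, parse_iupac, reverse_complement

#: Default binding motifs planted for each activator: the GaaR-responsive
#: element (GARE), a published AraR element, and the RhaR-associated element.
DEFAULT_MOTIF_MAP: dict[str, str] = {
    "G": "CC[ACTG]CCAA",
    "A": "CCCC[ATCG]CC",
    "R": "TG[CAG][GTA]GGG",
}

DEPENDENCY_CLASSES = ("none", "single", "and", "or", "mixed")

#: Candidate clause sets per dependency class (clauses as TF-letter tuples).
_CLASS_POOLS: dict[str, list[tuple[tuple[str, ...], ...]]] = {
    "single": [(("G",),), (("A",),), (("R",),)],
    "and": [(("G", "A"),), (("G", "R"),), (("A", "R"),), (("G", "A", "R"),)],
    "or": [
        (("G",), ("A",)),
        (("G",), ("R",)),
        (("A",), ("R",)),
        (("G",), ("A",), ("R",)),
    ],
    "mixed": [
        (("G", "A"), ("G", "R")),
        (("G", "A"), ("A", "R")),
        (("G", "R"), ("A", "R")),
        (("G", "A"), ("G", "R"), ("A", "R")),
        (("G",), ("A", "R")),
        (("A",), ("G", "R")),
        (("R",), ("G", "A")),
    ],
}


@dataclass
class GeneSpec:
    """Ground-truth regulatory parameters of one simulated gene."""

    gene_id: str
    length_bp: int
    baseline_log2: float
    clauses: tuple[tuple[str, ...], ...]  # monotone DNF; () = no dependency
    clause_effects: tuple[float, ...]  # log2 reduction per satisfied clause
    dispersion: float
    timepoint_shift_log2: float = 0.0  # applied at the later timepoint
    is_tf_gene: str | None = None  # TF letter if this gene encodes a TF

    @property
    def dependency(self) -> str:
        return dnf_string(frozenset(c) for c in self.clauses)

    def mean_log2(self, genotype: str, timepoint_index: int = 0) -> float:
        """log2 expected reference-scale count for a genotype."""
        deleted = genotype_set(genotype)
        drop = sum(
            eff
            for cl, eff in zip(self.clauses, self.clause_effects)
            if set(cl) <= deleted
        )
        shift = self.timepoint_shift_log2 if timepoint_index > 0 else 0.0
        return self.baseline_log2 + shift - drop


@dataclass
class RegulatoryModel:
    """Per-gene monotone regulatory logic plus NB simulation parameters."""

    genes: list[GeneSpec]
    reference_library_size: float = 5e6

    def __post_init__(self) -> None:
        tf_flags: dict[str, int] = {}
        for g in self.genes:
            if any(e < 0 for e in g.clause_effects):
                raise ValueError(f"{g.gene_id}: clause effects must be >= 0")
            if g.dispersion < 0:
                raise ValueError(f"{g.gene_id}: dispersion must be >= 0")
            if len(g.clauses) != len(g.clause_effects):
                raise ValueError(f"{g.gene_id}: one effect per clause required")
            if g.is_tf_gene is not None:
                tf_flags[g.is_tf_gene] = tf_flags.get(g.is_tf_gene, 0) + 1
        if any(v > 1 for v in tf_flags.values()):
            raise ValueError("at most one gene may be flagged per TF")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def class_counts(self, include_tf_genes: bool = False) -> dict[str, int]:
        out = {c: 0 for c in DEPENDENCY_CLASSES}
        for g in self.genes:
            if g.is_tf_gene and not include_tf_genes:
                continue
            out[classify_clauses(g.clauses)] += 1
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "reference_library_size": self.reference_library_size,
            "genes": [asdict(g) for g in self.genes],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RegulatoryModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        genes = []
        for g in payload["genes"]:
            g["clauses"] = tuple(tuple(c) for c in g["clauses"])
            g["clause_effects"] = tuple(g["clause_effects"])
            genes.append(GeneSpec(**g))
        return cls(genes, payload["reference_library_size"])

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g.gene_id,
                "dependency": g.dependency,
                "class": classify_clauses(g.clauses),
                "is_tf_gene": g.is_tf_gene or ".",
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows)


def classify_clauses(clauses: Sequence[tuple[str, ...]]) -> str:
    """Dependency class of a clause set: none/single/and/or/mixed."""
    if not clauses:
        return "none"
    sizes = [len(c) for c in clauses]
    if len(clauses) == 1:
        return "single" if sizes[0] == 1 else "and"
    return "or" if all(s == 1 for s in sizes) else "mixed"


def _rounded_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over the class mix."""
    bad = set(mix) - set(DEPENDENCY_CLASSES)
    if bad:
        raise ValueError(f"unknown dependency classes: {sorted(bad)}")
    if any(p < 0 for p in mix.values()):
        raise ValueError("class proportions must be non-negative")
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1 (got {total})")
    raw = {c: n * p for c, p in mix.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(mix, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    return counts


def build_model(
    n_genes: int,
    class_mix: Mapping[str, float] | None = None,
    effect_range: tuple[float, float] = (2.0, 4.0),
    dispersion: float | tuple[float, float] = 0.05,
    seed: int | None = None,
    baseline_range: tuple[float, float] = (5.0, 11.0),
    length_range: tuple[int, int] = (600, 4000),
    timepoint_shift_sd: float = 0.25,
    include_tf_genes: bool = True,
) -> RegulatoryModel:
    """Draw a ground-truth regulatory model.

    Parameters
    ----------
    n_genes
        Number of regular (non-TF) genes.  Class counts are the rounded
        proportions of ``class_mix`` (largest-remainder rule).
    class_mix
        Proportions over dependency classes {none, single, and, or, mixed};
        defaults to ``{none: .5, single: .3, and: .1, or: .1}``.
    effect_range
        Log2 interval from which each clause's expression drop is drawn.
    dispersion
        NB dispersion alpha, either a constant or a uniform range.
    timepoint_shift_sd
        SD of the per-gene log2 baseline shift at the later timepoint
        (regulatory logic itself is time-invariant in the generator).
    include_tf_genes
        Append one gene per TF (gaaR/araR/rhaR) whose expression is
        abolished in its own deletion strains.
    """
    if class_mix is None:
        class_mix = {"none": 0.5, "single": 0.3, "and": 0.1, "or": 0.1}
    if effect_range[0] < 0 or effect_range[1] < effect_range[0]:
        raise ValueError("effect_range must be a non-negative interval")
    rng = np.random.default_rng(seed)
    counts = _rounded_counts(n_genes, class_mix)

    genes: list[GeneSpec] = []
    idx = 0
    for cls in DEPENDENCY_CLASSES:
        for _ in range(counts.get(cls, 0)):
            if cls == "none":
                clauses: tuple[tuple[str, ...], ...] = ()
            else:
                pool = _CLASS_POOLS[cls]
                clauses = pool[rng.integers(len(pool))]
            effects = tuple(
                float(rng.uniform(*effect_range)) for _ in clauses
            )
            if isinstance(dispersion, (tuple, list)):
                disp = float(rng.uniform(*dispersion))
            else:
                disp = float(dispersion)
            genes.append(
                GeneSpec(
                    gene_id=f"gene{idx:04d}",
                    length_bp=int(rng.integers(*length_range)),
                    baseline_log2=float(rng.uniform(*baseline_range)),
                    clauses=clauses,
                    clause_effects=effects,
                    dispersion=disp,
                    timepoint_shift_log2=float(rng.normal(0.0, timepoint_shift_sd)),
                )
            )
            idx += 1
    if include_tf_genes:
        for tf in TF_ORDER:
            disp = (
                float(rng.uniform(*dispersion))
                if isinstance(dispersion, (tuple, list))
                else float(dispersion)
            )
            genes.append(
                GeneSpec(
                    gene_id=TF_GENES[tf],
                    length_bp=int(rng.integers(*length_range)),
                    baseline_log2=float(rng.uniform(7.0, 9.0)),
                    clauses=((tf,),),
                    clause_effects=(float(rng.uniform(*effect_range)),),
                    dispersion=disp,
                    timepoint_shift_log2=float(rng.normal(0.0, timepoint_shift_sd)),
                    is_tf_gene=tf,
                )
            )
    return RegulatoryModel(genes)


def factorial_design(
    timepoints: Sequence[str] = ("2h", "8h"),
    replicates: int = 2,
    library_size: float = 5e6,
    libsize_variation: tuple[float, float] = (0.8, 1.25),
    seed: int | None = None,
) -> Design:
    """Full-factorial sample sheet: 8 genotypes x timepoints x replicates.

    Expected library sizes vary per sample by a log-uniform factor drawn
    from ``libsize_variation`` so that size-factor normalisation is exercised.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    rows = []
    for g in GENOTYPE_ORDER:
        for tp in timepoints:
            for r in range(1, replicates + 1):
                lo, hi = libsize_variation
                factor = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                rows.append(
                    {
                        "sample_id": f"{g}_{tp}_r{r}",
                        "genotype": g,
                        "timepoint": tp,
                        "replicate": r,
                        "library_size": library_size * factor,
                    }
                )
    return Design(pd.DataFrame(rows))


def simulate_counts(
    model: RegulatoryModel, design: Design, seed: int | None = None
) -> CountMatrix:
    """Draw an NB count matrix from the model under the given design.

    Gene g in sample s has mean ``(library_size_s / reference_library_size)
    * 2**mean_log2(genotype_s)``; TF genes emit hard zeros in every genotype
    deleting that TF (their expression is abolished, not merely reduced).
    """
    rng = np.random.default_rng(seed)
    timepoints = sorted(set(design.table["timepoint"]))
    tp_index = {tp: i for i, tp in enumerate(timepoints)}
    n_g, n_s = len(model.genes), len(design.sample_ids)
    counts = np.zeros((n_g, n_s), dtype=np.int64)
    for j, (_, srow) in enumerate(design.table.iterrows()):
        scale = srow["library_size"] / model.reference_library_size
        for i, g in enumerate(model.genes):
            if g.is_tf_gene and g.is_tf_gene in genotype_set(srow["genotype"]):
                counts[i, j] = 0
                continue
            mu = scale * 2.0 ** g.mean_log2(srow["genotype"], tp_index[srow["timepoint"]])
            if mu <= 0:
                counts[i, j] = 0
            elif g.dispersion <= 0:
                counts[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / g.dispersion
                p = r / (r + mu)
                counts[i, j] = rng.negative_binomial(r, p)
    frame = pd.DataFrame(counts, index=model.gene_ids, columns=design.sample_ids)
    lengths = pd.Series(
        [g.length_bp for g in model.genes], index=model.gene_ids, name="length_bp"
    )
    return CountMatrix(frame, lengths, design)


# ---------------------------------------------------------------------------
# Promoters with planted motifs
# ---------------------------------------------------------------------------

_LETTERS = np.array(list("ACGT"))


@dataclass
class PlantedMotifTruth:
    """Where each motif instance was planted: one row per planted site."""

    table: pd.DataFrame  # gene_id, motif_id, tf, strand, upstream_position, site

    def sites_for(self, gene_id: str) -> pd.DataFrame:
        return self.table[self.table["gene_id"] == gene_id]

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PlantedMotifTruth":
        return cls(pd.read_csv(path, sep="\t"))


def _sample_instance(
    motif: IUPACMotif, rng: np.random.Generator, letter_bias: float = 0.35
) -> str:
    """Sample one site from a degenerate motif.

    At degenerate positions the allowed letters (listed order of the
    pattern, falling back to alphabetical) are drawn with geometrically
    decaying weights ``1, b, b^2, ...`` (``b = letter_bias``); 1 gives
    uniform sampling.  Real binding sites are sharper than their IUPAC
    summary — a site model flat over the allowed letters could never reach
    the stringent scan p-values used for site calling — so the generator
    defaults to a biased draw.
    """
    out = []
    for k, pos in enumerate(motif.position_sets):
        letters = _ordered_letters(motif, k)
        if len(letters) == 1:
            out.append(letters[0])
            continue
        w = letter_bias ** np.arange(len(letters))
        out.append(letters[rng.choice(len(letters), p=w / w.sum())])
    return "".join(out)


def _ordered_letters(motif: IUPACMotif, k: int) -> list[str]:
    """Allowed letters at position k in the pattern's listed order."""
    # recover bracket order from the original pattern when possible
    spans = []
    i = 0
    pat = motif.pattern.upper()
    while i < len(pat):
        if pat[i] == "[":
            j = pat.index("]", i)
            spans.append(pat[i + 1 : j].replace("U", "T"))
            i = j + 1
        else:
            spans.append(pat[i])
            i += 1
    if k < len(spans) and set(spans[k]) == set(motif.position_sets[k]):
        return list(spans[k])
    return sorted(motif.position_sets[k])


def planted_motif_fixture(
    pattern: str = "TG[CAG][GTA]GGG",
    n_seqs: int = 34,
    n_planted: int = 28,
    instances_per_seq: int = 2,
    promoter_len: int = 1000,
    letter_bias: float = 0.35,
    seed: int | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Promoter set for motif-discovery tests: some carry planted sites.

    Mirrors the RhaR-target search setting: 34 1-kb promoters of which 28
    contain instances of the degenerate element (by default two instances
    each, at random positions and strands — target promoters typically carry
    more than one occurrence).  Returns the sequence dict and the ids of the
    planted sequences.
    """
    rng = np.random.default_rng(seed)
    motif = parse_iupac(pattern)
    w = motif.width
    seqs: dict[str, str] = {}
    planted_ids: list[str] = []
    for i in range(n_seqs):
        seq = list(_LETTERS[rng.integers(4, size=promoter_len)])
        if i < n_planted:
            occupied: list[tuple[int, int]] = []
            for _ in range(instances_per_seq):
                for _try in range(1000):
                    start = int(rng.integers(promoter_len - w + 1))
                    if all(start + w <= a or start >= b for a, b in occupied):
                        break
                occupied.append((start, start + w))
                site = _sample_instance(motif, rng, letter_bias)
                if rng.integers(2):
                    site = reverse_complement(site)
                seq[start : start + w] = list(site)
            planted_ids.append(f"prom{i:02d}")
        seqs[f"prom{i:02d}"] = "".join(seq)
    return seqs, planted_ids


def generate_promoters(
    model: RegulatoryModel,
    motif_map: Mapping[str, IUPACMotif | str] | None = None,
    promoter_len: int = 1000,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
    max_tries: int = 1000,
    letter_bias: float = 0.35,
) -> tuple[dict[str, str], PlantedMotifTruth]:
    """Generate one promoter per gene with planted TF binding motifs.

    Every gene whose dependency mentions TF X receives at least one planted,
    non-overlapping instance of ``motif_map[X]`` at a uniformly random
    position and strand; all other sequence is i.i.d. from ``background``
    (order A, C, G, T).  Returns the promoter dict (gene_id -> sequence) and
    the planted-site truth table.  Positions follow the upstream convention:
    distance from the start codon to the leftmost base of the site.
    """
    if motif_map is None:
        motif_map = DEFAULT_MOTIF_MAP
    motifs = {
        tf: (m if isinstance(m, IUPACMotif) else parse_iupac(m, motif_id=f"{TF_GENES[tf]}_motif"))
        for tf, m in motif_map.items()
    }
    bg = np.asarray(background, dtype=float)
    if abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
        raise ValueError("background frequencies must be a distribution")
    rng = np.random.default_rng(seed)

    promoters: dict[str, str] = {}
    truth_rows = []
    for g in model.genes:
        mentioned = sorted(
            {t for cl in g.clauses for t in cl if t in motifs}, key=TF_ORDER.index
        )
        widths = [motifs[t].width for t in mentioned]
        if promoter_len < (max(widths) if widths else 0):
            raise ValueError("promoter shorter than motif width")
        if sum(widths) > promoter_len:
            raise ValueError(
                f"{g.gene_id}: cannot plant {len(widths)} motifs in {promoter_len} bp"
            )
        seq = _LETTERS[rng.choice(4, size=promoter_len, p=bg)]
        occupied: list[tuple[int, int]] = []
        for tf in mentioned:
            motif = motifs[tf]
            w = motif.width
            for attempt in range(max_tries):
                start = int(rng.integers(promoter_len - w + 1))  # 0-based
                if all(start + w <= a or start >= b for a, b in occupied):
                    break
            else:
                raise ValueError(
                    f"{g.gene_id}: could not place motif {motif.motif_id} "
                    f"without overlap after {max_tries} tries"
                )
            occupied.append((start, start + w))
            site = _sample_instance(motif, rng, letter_bias)
            # '+' when the pattern reads on the forward (upstream) strand
            strand = "+" if rng.integers(2) == 0 else "-"
            planted = site if strand == "+" else reverse_complement(site)
            seq[start : start + w] = list(planted)
            truth_rows.append(
                {
                    "gene_id": g.gene_id,
                    "motif_id": motif.motif_id,
                    "tf": tf,
                    "strand": strand,
                    "upstream_position": promoter_len - start,  # leftmost base
                    "site": site,
                }
            )
        promoters[g.gene_id] = "".join(seq)
    truth = PlantedMotifTruth(
        pd.DataFrame(
            truth_rows,
            columns=["gene_id", "motif_id", "tf", "strand", "upstream_position", "site"],
        )
    )
    return promoters, truth


def write_promoters_fasta(promoters: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoters_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
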