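"""End-to-end orchestration: counts + promoters -> dependency calls, Venn,
clusters, motif report, and a machine-readable JSON summary.

Stages run in order quantify -> differential expression -> dependency
classification -> clustering -> motifs.  When the inputs come from the
synthetic generator (a truth table is available) the pipeline additionally
scores recovery of the ground-truth dependency expressions and of the
hard-zero behaviour of the TF genes.  Given a seed, the whole run is
deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, depclass, diffexp, motifs, quantify, synthgen
from .core import (
    CountMatrix,
    Design,
    MUTANT_ORDER,
    REFERENCE,
    TF_GENES,
    canonical_expression,
    genotype_set,
)

log = logging.getLogger("facreg")


@dataclass
class PipelineConfig:
    """Paths and thresholds of one pipeline run.

    Thresholds default to the study cut-offs: fold change > 1.5 with
    BH-adjusted p <= 0.05 for regulation calls, FPKM < 1 for "not expressed"
    and FPKM in [1, 20] for "lowly expressed", PWM site p < 1e-4, motif
    widths 6-10 and a 0.1 log2 tie margin for predominant-TF attribution.
    """

    counts: str | None = None
    lengths: str | None = None
    design: str | None = None
    promoters: str | None = None
    gene_panel: str | None = None  # optional file with one gene id per line
    truth: str | None = None  # synthetic dependency truth table
    outdir: str = "facreg_out"
    seed: int = 0
    fc: float = 1.5
    alpha: float = 0.05
    fpkm_not_expressed: float = 1.0
    fpkm_low_max: float = 20.0
    scan_p: float = 1e-4
    motif_widths: tuple[int, int] = (6, 10)
    tie_margin: float = 0.1
    log_base: float = 2.0
    cluster_k: int | None = None
    discover_motifs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motif_widths" in data:
            data["motif_widths"] = tuple(data["motif_widths"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("fc", "alpha", "fpkm_not_expressed", "fpkm_low_max", "scan_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        lo, hi = self.motif_widths
        if not (4 <= lo <= hi <= 20):
            raise ValueError("motif widths must lie within [4, 20]")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def simulate_inputs(
    outdir: str | Path,
    n_genes: int = 300,
    seed: int = 0,
    replicates: int = 2,
    dispersion: float | tuple[float, float] = 0.05,
    effect_range: tuple[float, float] = (2.0, 4.0),
    class_mix: Mapping[str, float] | None = None,
) -> PipelineConfig:
    """Generate a synthetic dataset on disk and a config pointing at it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    model = synthgen.build_model(
        n_genes,
        class_mix=class_mix,
        effect_range=effect_range,
        dispersion=dispersion,
        seed=int(rng.integers(2**31)),
    )
    design = synthgen.factorial_design(
        replicates=replicates, seed=int(rng.integers(2**31))
    )
    counts = synthgen.simulate_counts(model, design, seed=int(rng.integers(2**31)))
    promoters, planted = synthgen.generate_promoters(
        model, seed=int(rng.integers(2**31))
    )
    counts.write_tsv(outdir / "counts.tsv", outdir / "lengths.tsv")
    design.write_tsv(outdir / "design.tsv")
    synthgen.write_promoters_fasta(promoters, outdir / "promoters.fa")
    model.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    planted.write_tsv(outdir / "planted_sites.tsv")
    model.to_json(outdir / "model.json")
    return PipelineConfig(
        counts=str(outdir / "counts.tsv"),
        lengths=str(outdir / "lengths.tsv"),
        design=str(outdir / "design.tsv"),
        promoters=str(outdir / "promoters.fa"),
        truth=str(outdir / "truth.tsv"),
        outdir=str(outdir / "results"),
        seed=seed,
    )


@_stage("load")
def _load(config: PipelineConfig) -> CountMatrix:
    design = Design.read_tsv(config.design)
    return CountMatrix.read_tsv(config.counts, config.lengths, design)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full inference chain and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = _load(config)
    design = counts.design
    panel = None
    if config.gene_panel:
        panel = [
            line.strip()
            for line in Path(config.gene_panel).read_text().splitlines()
            if line.strip()
        ]

    summary: dict = {"n_genes": len(counts.gene_ids), "timepoints": design.timepoints}

    # ---- quantify -------------------------------------------------------
    @_stage("quantify")
    def _quantify():
        expr = quantify.compute_fpkm(counts)
        status = quantify.expression_status(
            expr, (config.fpkm_not_expressed, config.fpkm_low_max)
        )
        expr.write_tsv(outdir / "fpkm.tsv")
        status.to_csv(outdir / "expression_status.tsv", sep="\t")
        return expr, status

    expr, status = _quantify()

    # ---- differential expression ---------------------------------------
    @_stage("diffexp")
    def _de():
        res = diffexp.run_contrasts(counts, config.fc, config.alpha)
        diffexp.write_contrasts(res, outdir / "de")
        return res

    de_results = _de()

    # ---- dependency classification --------------------------------------
    @_stage("depclass")
    def _classify():
        per_tp: dict[str, dict] = {}
        for tp in design.timepoints:
            calls_down = depclass.classify_all(
                de_results, tp, "down", genes=panel, tie_margin=config.tie_margin
            )
            calls_up = depclass.classify_all(
                de_results, tp, "up", genes=panel, tie_margin=config.tie_margin
            )
            depclass.calls_to_frame(calls_down).to_csv(
                outdir / f"dependency_down_{tp}.tsv", sep="\t", index=False
            )
            depclass.calls_to_frame(calls_up).to_csv(
                outdir / f"dependency_up_{tp}.tsv", sep="\t", index=False
            )
            venn = depclass.venn_partition(calls_down)
            per_tp[tp] = {"down": calls_down, "up": calls_up, "venn": venn}
        pd.DataFrame(
            {tp: d["venn"] for tp, d in per_tp.items()}
        ).to_csv(outdir / "venn.tsv", sep="\t")
        return per_tp

    classified = _classify()

    # ---- temporal switches ----------------------------------------------
    @_stage("switches")
    def _switches():
        tps = design.timepoints
        if len(tps) < 2:
            return pd.DataFrame()
        sw = depclass.temporal_switches(
            classified[tps[0]]["down"], classified[tps[1]]["down"]
        )
        sw.to_csv(outdir / "temporal_switches.tsv", sep="\t", index=False)
        return sw

    switches = _switches()

    # ---- clustering ------------------------------------------------------
    @_stage("clustering")
    def _cluster():
        mat = quantify.mean_log_matrix(expr, base=config.log_base)
        if panel:
            mat = mat.loc[[g for g in panel if g in mat.index]]
        dendro = clustering.hclust_complete(mat)
        clustering.write_dendrogram_tsv(dendro, outdir / "dendrogram.tsv")
        if config.cluster_k:
            dendro.cut(config.cluster_k).to_csv(
                outdir / "clusters.tsv", sep="\t", header=True
            )
        return dendro

    dendro = _cluster()

    # ---- motifs ----------------------------------------------------------
    motif_report: dict = {}
    if config.promoters:

        @_stage("motifs")
        def _motifs():
            promoters = synthgen.read_promoters_fasta(config.promoters)
            report = {}
            tps = design.timepoints
            calls_down = classified[tps[0]]["down"]
            by_tf: dict[str, list[str]] = {}
            for call in calls_down:
                for tf in call.mentioned_tfs:
                    by_tf.setdefault(tf, []).append(call.gene_id)
            all_hits = []
            for tf, pattern in synthgen.DEFAULT_MOTIF_MAP.items():
                motif = motifs.parse_iupac(pattern, motif_id=f"{TF_GENES[tf]}_motif")
                targets = by_tf.get(tf, [])
                target_seqs = {g: promoters[g] for g in targets if g in promoters}
                hits = motifs.scan_iupac(promoters, motif)
                all_hits.append(hits)
                if target_seqs:
                    enr = motifs.motif_enrichment(
                        motifs.hit_indicator(target_seqs, motif),
                        motifs.hit_indicator(promoters, motif),
                    )
                    report[tf] = enr.as_dict()
            if all_hits:
                pd.concat(all_hits, ignore_index=True).to_csv(
                    outdir / "motif_hits.tsv", sep="\t", index=False,
                    float_format="%.4g",
                )
            if config.discover_motifs:
                tf = "R"
                targets = by_tf.get(tf, [])
                seqs = {g: promoters[g] for g in targets if g in promoters}
                if len(seqs) >= 5:
                    found = motifs.zoops_discover(
                        seqs, width_range=config.motif_widths, seed=config.seed
                    )
                    if found:
                        best = found[0]
                        (outdir / "discovered_motif.meme.txt").write_text(
                            best.pwm.to_meme_text(nsites=int(round(best.nsites)))
                        )
                        # discover-then-rescan: call sites genome-wide with
                        # the discovered matrix at the configured p cut-off
                        pwm_hits = motifs.pwm_scan(
                            promoters, best.pwm, p_threshold=config.scan_p
                        )
                        pwm_hits.to_csv(
                            outdir / "pwm_hits.tsv", sep="\t", index=False,
                            float_format="%.4g",
                        )
                        report["discovered"] = {
                            "consensus": best.consensus,
                            "width": best.width,
                            "llr": best.llr,
                            "score": best.score,
                            "pwm_hit_promoters": int(pwm_hits["seq_id"].nunique()),
                        }
            return report

        motif_report = _motifs()

    # ---- bookkeeping summary --------------------------------------------
    @_stage("summary")
    def _summary():
        for tp in design.timepoints:
            calls_down = classified[tp]["down"]
            genes = [c.gene_id for c in calls_down]
            st = status[tp].reindex(genes)
            not_expressed = set(st[st == "not_expressed"].index)
            regulated = {
                c.gene_id
                for c in calls_down
                if c.expression not in ("none",) and c.gene_id not in not_expressed
            }
            not_regulated = set(genes) - regulated - not_expressed
            summary[tp] = {
                "panel_size": len(genes),
                "regulated": len(regulated),
                "not_regulated": len(not_regulated),
                "not_expressed": len(not_expressed),
                "venn": classified[tp]["venn"],
            }
        summary["n_switched"] = (
            int(switches["switched"].sum()) if len(switches) else 0
        )
        summary["cluster_merge_count"] = int(dendro.merges.shape[0])
        if motif_report:
            summary["motifs"] = motif_report
        if config.truth:
            summary["recovery"] = recovery_metrics(
                pd.read_csv(config.truth, sep="\t"), classified, expr, design
            )
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
        return summary

    return _summary()


def recovery_metrics(
    truth: pd.DataFrame,
    classified: Mapping[str, Mapping],
    expr,
    design: Design,
) -> dict:
    """Score inferred dependencies against the generator's ground truth.

    Reports, per timepoint, the fraction of genes with a true dependency
    whose inferred down-direction expression equals the truth, and the
    fraction of TF genes whose expression is abolished (mutant FPKM < 1)
    in every genotype deleting them.
    """
    truth = truth.set_index("gene_id")
    out: dict = {}
    for tp, d in classified.items():
        calls = {c.gene_id: canonical_expression(c.expression) for c in d["down"]}
        dep_genes = [
            g
            for g in truth.index
            if truth.loc[g, "dependency"] != "none" and g in calls
        ]
        correct = sum(
            calls[g] == canonical_expression(truth.loc[g, "dependency"])
            for g in dep_genes
        )
        out[tp] = {
            "dependency_genes": len(dep_genes),
            "correct_expressions": int(correct),
            "accuracy": correct / len(dep_genes) if dep_genes else float("nan"),
        }
    # TF genes: hard-zero behaviour in their own deletion strains
    tf_rows = truth[truth["is_tf_gene"] != "."]
    checks = ok = 0
    for gene, row in tf_rows.iterrows():
        tf = row["is_tf_gene"]
        for (genotype, tp), samples in design.groups().items():
            if tf in genotype_set(genotype):
                checks += 1
                if float(expr.fpkm.loc[gene, samples].mean()) < 1.0:
                    ok += 1
    out["tf_abolished_checks"] = checks
    out["tf_abolished_ok"] = ok
    out["tf_abolished_fraction"] = ok / checks if checks else float("nan")
    return out
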