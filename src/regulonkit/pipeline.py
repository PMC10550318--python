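"""End-to-end orchestration: simulate -> call regulon -> meiotic response.

``run_all`` executes the full study on synthetic data and writes a
machine-readable report recording the set size at every filtering step
(time-series hits -> baseline filter -> acute filter -> +rescue -> composite
-> ChIP-curated direct list), the timing classification, the motif-fraction
summary and the meiotic grouping.  All randomness flows from the config seed;
re-running with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, gsea, meiotic, motif, targets
from .quantio import (CountMatrix, SampleSheet, compute_tpm, size_factors,
                      write_chip_table, write_counts, write_fasta_regions,
                      write_gene_table, write_sample_sheet)
from .synthetic import (SimConfig, generate_chip_scores,
                        generate_depletion_experiment, generate_meiosis_experiment,
                        generate_promoters, generate_stage_atlas)

logger = logging.getLogger(__name__)

#: default thresholds of the composite procedure
THRESHOLDS = {
    "padj": 0.05,
    "baseline_lfc": 1.0,
    "acute_lfc": 0.3,
    "ratio_up": 1.4,
    "ratio_down": 0.6,
    "chip": 0.5,
    "emg_lfc": 1.0,
}


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str | None = None
    sim: SimConfig | None = None
    thresholds: dict = dataclasses.field(default_factory=lambda: dict(THRESHOLDS))
    run_meiosis: bool = True
    run_motif: bool = True
    kmax: int = 8

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        unknown = set(self.thresholds) - set(THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold(s): {sorted(unknown)}")
        merged = dict(THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, val in self.thresholds.items():
            if not (0 < val if key != "ratio_down" else 0 <= val <= 1):
                raise ValueError(f"threshold {key}={val} outside its valid range")


def call_depletion_regulon(counts: CountMatrix, sheet: SampleSheet,
                           gene_table: pd.DataFrame, chip, atlas,
                           thresholds: dict | None = None) -> dict:
    """The composite target-calling procedure on one depletion experiment.

    Returns a dict with the step-by-step gene lists, the evidence table and
    the bookkeeping sizes.
    """
    th = dict(THRESHOLDS)
    th.update(thresholds or {})
    sf = size_factors(counts)
    disp = diffexpr.estimate_dispersions(counts, sheet, sf)
    series = diffexpr.lrt_timeseries(counts, sheet, sf, disp,
                                     timepoints=[0, 15, 30, 60, 120])
    candidates = list(series.loc[series["padj"] < th["padj"], "gene_id"])

    pw = {t: diffexpr.wald_pairwise(counts, sheet, sf, disp, t)
          for t in (-30, 0, 15)}
    after_baseline = targets.filter_baseline_de(
        candidates, pw[-30], pw[0], th["padj"], th["baseline_lfc"])
    after_acute = targets.filter_acute_response(
        after_baseline, pw[15], th["padj"], th["acute_lfc"])

    tpm = compute_tpm(counts, gene_table["length_bp"])
    ratios = targets.tpm_ratio_rescue(tpm, sheet, up=th["ratio_up"],
                                      down=th["ratio_down"])
    rescued = list(ratios.index[ratios["rescued"]])
    composite = targets.build_composite(after_acute, rescued)
    curated = targets.chip_curation(composite, chip, th["chip"])
    direct = list(curated.index[curated["direct"]])
    stages, stage_counts = targets.classify_timing(direct, atlas)
    calls = targets.call_regulon(curated, pw[15], ratios, atlas)

    return {
        "series": series,
        "pairwise": pw,
        "ratios": ratios,
        "calls": calls,
        "direct": direct,
        "stage_counts": stage_counts,
        "sizes": {
            "lrt_hits": len(candidates),
            "after_baseline_filter": len(after_baseline),
            "after_acute_filter": len(after_acute),
            "tpm_rescued": len(rescued),
            "rescue_overlap": len(set(rescued) & set(after_acute)),
            "composite": len(composite),
            "direct": len(direct),
        },
    }


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order; return the report dict.

    When ``config.outdir`` is set, inputs and outputs are also written there
    (counts/sheets/annotation TSVs, FASTA, regulon calls, grouping, report
    JSON).
    """
    sim = config.sim
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    logger.info("[simulate] depletion experiment (seed=%d)", sim.seed)
    counts, sheet, gene_table, truth = generate_depletion_experiment(sim)
    chip = generate_chip_scores(truth, sim)
    atlas = generate_stage_atlas(truth, sim)

    logger.info("[targets] composite regulon calling")
    res = call_depletion_regulon(counts, sheet, gene_table, chip, atlas,
                                 config.thresholds)

    report = {
        "seed": config.seed,
        "n_genes": sim.n_genes,
        "thresholds": config.thresholds,
        "sizes": res["sizes"],
        "stage_counts": res["stage_counts"],
    }

    if config.run_motif:
        logger.info("[motif] URS1 core scan over direct-target regions")
        regions = generate_promoters(truth, sim)
        table, fraction = motif.motif_fraction(res["direct"], regions)
        report["motif"] = {
            "genes_with_hit": int((table["total"] > 0).sum()),
            "n_targets": len(res["direct"]),
            "fraction": fraction,
        }
        if outdir:
            write_fasta_regions(regions, outdir / "regions.fasta")
            table.to_csv(outdir / "motif_hits.tsv", sep="\t")

    if config.run_meiosis:
        logger.info("[meiotic] induction course, clustering and summaries")
        m_counts, m_sheet, m_truth = generate_meiosis_experiment(sim)
        lengths = pd.Series(1000, index=m_counts.genes)
        m_tpm = compute_tpm(m_counts, lengths)
        target_mask = m_truth["class"] != "null"
        response = meiotic.response_vs_baseline(m_tpm, m_sheet)
        grouping = meiotic.kmeans_elbow(response.loc[target_mask], kmax=config.kmax,
                                        seed=config.seed)
        summary = meiotic.group_summary(grouping, m_tpm, m_sheet)
        report["meiosis"] = {
            "k": grouping.k,
            "wss": {int(k): float(w) for k, w in grouping.wss.items()},
            "cluster_sizes": summary["n"].to_dict(),
            "pct_decrease": summary["pct_decrease"].round(2).to_dict(),
        }
        if outdir:
            response.to_csv(outdir / "response.tsv", sep="\t")
            grouping.labels.rename_axis("gene_id").to_csv(outdir / "grouping.tsv", sep="\t")
            write_counts(m_counts, outdir / "meiosis_counts.tsv")
            write_sample_sheet(m_sheet, outdir / "meiosis_samples.csv")

    # internal consistency of the bookkeeping arithmetic
    s = report["sizes"]
    assert s["composite"] == s["after_acute_filter"] + s["tpm_rescued"] - s["rescue_overlap"]
    assert s["direct"] <= s["composite"]

    if outdir:
        write_counts(counts, outdir / "counts.tsv")
        write_sample_sheet(sheet, outdir / "samples.csv")
        write_gene_table(gene_table, outdir / "genes.tsv")
        write_chip_table(chip, outdir / "chip.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        res["calls"].to_csv(outdir / "regulon_calls.tsv", sep="\t")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    return report
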