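"""Composite regulon identification.

The composite procedure turns the time-series test hits into a curated direct
target list in five steps:

1. :func:`filter_baseline_de` removes candidates already differentially
   expressed before the protein was depleted (pairwise contrasts at -30 and
   0 min; padj < 0.05 and \\|log2FC\\| > 1 at either timepoint removes a gene).
2. :func:`filter_acute_response` keeps candidates with an acute response at
   15 min (padj < 0.05 and \\|log2FC\\| > 0.3), as expected of direct
   derepression.
3. :func:`tpm_ratio_rescue` adds back genes the count-based test missed: the
   per-timepoint depletion/control TPM ratio (15, 30, 60, 120 min) is
   averaged, and genes with average ratio >= 1.4 or <= 0.6 are rescued.
4. :func:`build_composite` takes the union, labelling each gene's source.
5. :func:`chip_curation` keeps genes whose mean ChIP peak score is at least
   half that of the reference bound gene (ratio >= 0.5), marking them direct.

:func:`classify_timing` then assigns each direct target the meiotic stage
where its atlas expression peaks.

Boundary semantics follow the printed comparators exactly: strict ``>`` for
log2FC cuts, inclusive ``>=`` / ``<=`` for the ratio and ChIP thresholds.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quantio import ChipScoreTable, SampleSheet
from .synthetic import EARLY_STAGES, STAGES

#: TPM-ratio pseudocount (TPM units), guarding zero denominators
RATIO_EPS = 1.0


class LookupError_(KeyError):
    """A gene required by a step is missing from one of its inputs."""


def _indexed(de: pd.DataFrame) -> pd.DataFrame:
    return de.set_index("gene_id") if "gene_id" in de.columns else de


def _require(candidates: Sequence[str], table: pd.DataFrame, what: str) -> None:
    missing = [g for g in candidates if g not in table.index]
    if missing:
        raise LookupError_(f"{len(missing)} candidate(s) missing from {what}: {missing[:5]}")


def filter_baseline_de(candidates: Sequence[str], pairwise_neg30: pd.DataFrame,
                       pairwise_0: pd.DataFrame, padj_cut: float = 0.05,
                       lfc_cut: float = 1.0) -> list[str]:
    """Drop candidates significantly DE before depletion (at -30 OR 0 min)."""
    tables = [_indexed(pairwise_neg30), _indexed(pairwise_0)]
    for t, name in zip(tables, ("t=-30 contrast", "t=0 contrast")):
        _require(candidates, t, name)
    kept = []
    for gene in candidates:
        flagged = any(
            (t.loc[gene, "padj"] < padj_cut) and (abs(t.loc[gene, "log2FC"]) > lfc_cut)
            for t in tables
        )
        if not flagged:
            kept.append(gene)
    return kept


def filter_acute_response(candidates: Sequence[str], pairwise_15: pd.DataFrame,
                          padj_cut: float = 0.05, lfc_cut: float = 0.3) -> list[str]:
    """Keep candidates with an acute 15-min response (padj < 0.05, |lfc| > 0.3)."""
    t = _indexed(pairwise_15)
    _require(candidates, t, "t=15 contrast")
    return [g for g in candidates
            if (t.loc[g, "padj"] < padj_cut) and (abs(t.loc[g, "log2FC"]) > lfc_cut)]


def tpm_ratio_rescue(tpm: pd.DataFrame, sheet: SampleSheet,
                     timepoints: Sequence[float] = (15, 30, 60, 120),
                     up: float = 1.4, down: float = 0.6,
                     cond_a: str = "control", cond_b: str = "depletion") -> pd.DataFrame:
    """Average depletion/control TPM ratio across post-depletion timepoints.

    Per gene and timepoint, ratio_t = (mean TPM_B + eps) / (mean TPM_A + eps)
    with eps = 1 TPM; the average over the listed timepoints flags a gene when
    it is >= ``up`` or <= ``down`` (both inclusive).  Returns a frame with
    columns ``avg_ratio`` and ``rescued`` for all genes.
    """
    ratios = []
    for t in timepoints:
        ids_a = sheet.samples_for(cond_a, t)
        ids_b = sheet.samples_for(cond_b, t)
        if not ids_a or not ids_b:
            raise KeyError(f"timepoint {t!r} missing in one of the conditions")
        mean_a = tpm[ids_a].mean(axis=1)
        mean_b = tpm[ids_b].mean(axis=1)
        ratios.append((mean_b + RATIO_EPS) / (mean_a + RATIO_EPS))
    avg = pd.concat(ratios, axis=1).mean(axis=1)
    return pd.DataFrame({"avg_ratio": avg,
                         "rescued": (avg >= up) | (avg <= down)})


def build_composite(list_deseq: Sequence[str], list_tpm: Sequence[str]) -> pd.DataFrame:
    """Union of the two paths with per-gene source labels.

    Order: the count-test list first (its order preserved), then rescue-only
    genes.  \\|composite\\| = \\|A\\| + \\|B \\ A\\|.
    """
    a = list(dict.fromkeys(list_deseq))
    b = list(dict.fromkeys(list_tpm))
    a_set, b_set = set(a), set(b)
    rows = [{"gene_id": g, "source": "both" if g in b_set else "deseq_path"} for g in a]
    rows += [{"gene_id": g, "source": "tpm_path"} for g in b if g not in a_set]
    return pd.DataFrame(rows, columns=["gene_id", "source"]).set_index("gene_id")


def chip_curation(composite: pd.DataFrame, chip: ChipScoreTable,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Flag composite genes whose mean-score ratio to the reference is >= 0.5."""
    missing = [g for g in composite.index if g not in chip.scores.index]
    if missing:
        raise LookupError_(f"genes absent from ChIP table: {missing}")
    ref = float(chip.scores.loc[chip.reference_gene].mean())
    out = composite.copy()
    out["chip_ratio"] = [float(chip.scores.loc[g].mean()) / ref for g in composite.index]
    out["direct"] = out["chip_ratio"] >= threshold
    return out


def classify_timing(targets: Sequence[str], atlas: pd.DataFrame):
    """Assign each target the stage of its atlas expression peak.

    Ties break toward the earliest stage in the fixed order.  Returns
    ``(stages, counts)`` where ``counts`` additionally carries the
    early-meiotic roll-up (``emg`` = entry + replication + recombination).
    """
    missing = [g for g in targets if g not in atlas.index]
    if missing:
        raise LookupError_(f"targets absent from atlas: {missing}")
    cols = [s for s in STAGES if s in atlas.columns]
    sub = atlas.loc[list(targets), cols]
    # idxmax on the stage-ordered columns breaks ties toward the earliest stage
    stages = sub.idxmax(axis=1)
    counts = {s: int((stages == s).sum()) for s in STAGES}
    counts["emg"] = sum(counts[s] for s in EARLY_STAGES)
    return stages, counts


def call_regulon(composite_curated: pd.DataFrame, pairwise_15: pd.DataFrame,
                 ratios: pd.DataFrame, atlas: pd.DataFrame,
                 motif_hits: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Assemble the per-gene evidence trail for the curated composite list."""
    t15 = _indexed(pairwise_15)
    out = composite_curated.copy()
    out["lfc15"] = [t15.loc[g, "log2FC"] if g in t15.index else np.nan for g in out.index]
    out["avg_ratio"] = ratios["avg_ratio"].reindex(out.index)
    stages, _ = classify_timing(list(out.index), atlas)
    out["stage"] = stages
    out["motif_hits"] = [int((motif_hits or {}).get(g, 0)) for g in out.index]
    return out
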