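"""Gene set enrichment analysis and early-meiotic set curation.

Implements the running-sum enrichment statistic from scratch: genes are ranked
by a statistic, set members add \\|stat\\|^p normalized by the set total, and
non-members subtract 1/(N - N_set); the enrichment score (ES) is the signed
maximum deviation of the running sum from zero.  Significance comes from a
gene-set permutation null (random same-size sets drawn without replacement),
with a sign-stratified normalized enrichment score (NES) and permutation
p-value.  The weight defaults to p = 1.

:func:`curate_emg_set` reproduces the stepwise curation of an early-meiotic
gene set from an induction response table: keep induced genes (log2FC > 1.0,
strict), remove members of the mid-meiotic (NDT80-responsive) set, keep genes
whose staged-atlas peak falls in the early window (meiotic entry through
recombination, i.e. before the mid-meiotic program), and drop genes already
highly expressed during mitotic growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import EARLY_STAGES, STAGES


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise EnrichmentError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise EnrichmentError(f"gene set {self.name!r} has duplicate members")


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    pvalue: float
    leading_edge: list
    n_perm: int
    seed: int


def _running_sum(stats_sorted: np.ndarray, member_mask: np.ndarray,
                 weight: float) -> np.ndarray:
    n = len(stats_sorted)
    n_set = int(member_mask.sum())
    if n_set == 0:
        raise EnrichmentError("gene set does not intersect the ranked list")
    if n_set >= n:
        raise EnrichmentError("gene set covers the entire ranked list")
    w = np.abs(stats_sorted) ** weight
    w_set = w * member_mask
    total = w_set.sum()
    if total == 0:
        # all member stats are exactly zero: fall back to equal hit increments
        w_set = member_mask.astype(float)
        total = w_set.sum()
    inc = w_set / total
    miss = (~member_mask).astype(float) / (n - n_set)
    return np.cumsum(inc - miss)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    i = int(np.abs(running).argmax())
    return float(running[i]), i


def _rank(ranked) -> pd.Series:
    s = pd.Series(ranked).astype(float)
    if s.index.has_duplicates:
        raise EnrichmentError("ranked list contains duplicate genes")
    return s.sort_values(ascending=False, kind="mergesort")


def enrichment_score(ranked, gene_set: GeneSet, weight: float = 1.0):
    """ES of a gene set in a ranked list.

    ``ranked`` maps gene -> ranking statistic (a pandas Series or dict); it is
    sorted by decreasing statistic internally (stable for ties).  Returns
    ``(es, running, leading_edge)``: the signed maximum deviation, the full
    running sum, and the member genes up to (for positive ES) or after (for
    negative ES) the extremum.
    """
    s = _rank(ranked)
    member = s.index.isin(gene_set.genes)
    running = _running_sum(s.to_numpy(), member, weight)
    es, i = _es_from_running(running)
    if es >= 0:
        leading = [g for g, m in zip(s.index[:i + 1], member[:i + 1]) if m]
    else:
        leading = [g for g, m in zip(s.index[i:], member[i:]) if m]
    return es, running, leading


def gsea_permutation(ranked, gene_set: GeneSet, n_perm: int = 1000,
                     seed: int = 0, weight: float = 1.0) -> GseaResult:
    """Gene-set permutation test: null ES from random same-size sets.

    NES = ES / mean(\\|null ES\\| of matching sign);
    p = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign null).
    Deterministic given the seed.
    """
    if n_perm < 100:
        raise EnrichmentError("need at least 100 permutations")
    s = _rank(ranked)
    stats_sorted = s.to_numpy()
    n = len(s)
    member = s.index.isin(gene_set.genes)
    k = int(member.sum())
    if k == 0:
        raise EnrichmentError("gene set does not intersect the ranked list")
    if k >= n:
        raise EnrichmentError("gene set size must be smaller than the list")
    es, running, leading = enrichment_score(ranked, gene_set, weight)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null[b] = _es_from_running(_running_sum(stats_sorted, mask, weight))[0]

    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes, p = np.nan, 1.0 / (n_perm + 1)
    else:
        nes = es / np.abs(null[same_sign]).mean()
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same)
    return GseaResult(gene_set.name, es, float(nes), float(p), leading, n_perm, seed)


def curate_emg_set(response_log2fc: pd.Series, ndt80_set: GeneSet,
                   atlas: pd.DataFrame, mitotic_tpm: pd.Series,
                   lfc_cut: float = 1.0, mitotic_cut: float = 50.0,
                   name: str = "EMG"):
    """Stepwise early-meiotic gene-set curation.

    1. keep genes with induction log2FC strictly > ``lfc_cut``;
    2. remove members of the mid-meiotic (NDT80-responsive) set;
    3. keep genes whose atlas peak falls in the early window (meiotic entry,
       DNA replication, recombination);
    4. drop genes with mitotic TPM > ``mitotic_cut`` (the exclusion level for
       "already expressed during mitotic growth"; no canonical value exists,
       so it is an explicit parameter).

    Returns ``(GeneSet, sizes)`` where ``sizes`` logs every intermediate size.
    """
    induced = [g for g, v in response_log2fc.items() if v > lfc_cut]
    sizes = {"induced": len(induced)}
    mmg = set(ndt80_set.genes)
    after_mmg = [g for g in induced if g not in mmg]
    sizes["after_mmg_removal"] = len(after_mmg)
    missing = [g for g in after_mmg if g not in atlas.index]
    if missing:
        raise EnrichmentError(f"genes absent from atlas: {missing[:5]}")
    cols = [s for s in STAGES if s in atlas.columns]
    peaks = atlas.loc[after_mmg, cols].idxmax(axis=1)
    early = [g for g in after_mmg if peaks[g] in EARLY_STAGES]
    sizes["early_window"] = len(early)
    final = [g for g in early if mitotic_tpm.get(g, 0.0) <= mitotic_cut]
    sizes["final"] = len(final)
    return GeneSet(name, tuple(final)), sizes
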