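"""Synthetic experiments with planted ground truth.

Generates every input the pipeline needs — count matrices for the acute
mitotic-depletion time course and for the meiotic induction course, ChIP peak
scores, promoter/ORF/downstream sequences with planted URS1 cores, a staged
meiotic expression atlas, and the inputs to early-meiotic gene-set curation —
so that every downstream stage can be tested against known truth without any
external data.

The depletion design mirrors an auxin-inducible degron experiment: two
conditions (control, depletion) sampled at -30 (inducer addition), 0 (auxin
addition), 15, 30, 60 and 120 minutes with 3 biological replicates.  Planted
gene classes:

``direct``
    repressed at baseline (low mean counts) and derepressed in the depletion
    condition from 15 min onward with a per-gene log2 fold change drawn from
    ``effect_log2fc_range``; these are the genes the pipeline should recover.
``confounded``
    differentially expressed between the two cultures already at -30 and
    0 min (a pre-existing strain/condition difference); the baseline filter
    should remove them.
``slow``
    indirect responders whose effect appears only at 60/120 min, so they fail
    the acute 15-min filter but can be rescued by the average TPM ratio.
``null``
    identical means in both conditions.

Counts are negative binomial with variance mu + alpha*mu^2 (``dispersion`` =
alpha, default 0.05, typical bulk RNA-seq overdispersion).  Per-sample library
sizes are drawn log-uniformly from ``library_size_range`` to exercise the
size-factor estimator.  One global seed drives independent per-generator
substreams (SeedSequence spawn keys), so adding a generator never perturbs
another's output, and a fixed seed gives bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .quantio import ChipScoreTable, CountMatrix, SampleSheet

STAGES = ("meiotic entry", "DNA replication", "recombination", "mid", "late")
EARLY_STAGES = STAGES[:3]
#: stage proportions planted on direct targets (entry, replication,
#: recombination, mid, late); apportioned by largest remainder so that 144
#: targets yield exactly 49/12/66/17/0.
DIRECT_STAGE_PROPORTIONS = (0.34, 0.08, 0.46, 0.12, 0.0)

URS1_CORE = "GGCGGC"

# spawn keys for independent substreams
_STREAMS = {
    "annotation": 0,
    "depletion": 1,
    "meiosis": 2,
    "chip": 3,
    "promoters": 4,
    "atlas": 5,
    "emg": 6,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions every recovery test and the acceptance
    run use; see docs/methods.md for the rationale behind each value.
    """

    n_genes: int = 2000
    n_direct_targets: int = 150
    n_confounded: int = 30
    n_slow: int = 50
    timepoints_min: tuple = (-30, 0, 15, 30, 60, 120)
    n_replicates: int = 3
    effect_log2fc_range: tuple = (1.5, 3.0)
    dispersion: float = 0.05
    library_size_range: tuple = (0.7, 1.4)
    motif_plant_fraction: float = 0.83
    chip_pass_fraction: float = 1.0
    #: baseline mean counts of repressed targets before depletion ("essentially
    #: quiescent": low but nonzero)
    baseline_target_mean: float = 5.0
    # --- meiotic induction course ---
    timepoints_hr: tuple = (0.5, 2.0, 2.5, 3.0, 4.5, 6.0)
    meiosis_group_sizes: tuple = (40, 72, 32)
    #: control-condition induction fold at the first post-induction
    #: timepoint (2.5 h)
    meiosis_induction_folds: tuple = (16.0, 3.0, 2.5)
    #: per-group temporal shape of the induction fold over the post-induction
    #: timepoints (2.5, 3, 4.5, 6 h): group 1 peaks sharply and decays,
    #: group 2 accumulates gradually to a late peak, group 3 stays flat —
    #: distinct dynamics keep the planted clusters well separated in response
    #: space (not merely scaled copies of one trajectory)
    meiosis_time_shapes: tuple = ((1.0, 0.8, 0.6, 0.5),
                                  (1.0, 2.0, 3.3, 5.0),
                                  (1.0, 1.0, 1.0, 1.0))
    #: depletion/control expression multiplier after induction for each group:
    #: ~43% and ~20% decrease for groups 1 and 2; group 3 is unaffected (the
    #: observed few-percent change in an unaffected group is sampling noise)
    meiosis_depletion_factors: tuple = (0.57, 0.80, 1.00)
    meiosis_target_baseline: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_genes, self.n_direct_targets, self.n_confounded,
                  self.n_slow, self.n_replicates)
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        if self.n_direct_targets + self.n_confounded + self.n_slow > self.n_genes:
            raise ConfigurationError("planted classes exceed n_genes")
        if len(self.timepoints_min) == 0 or len(self.timepoints_hr) == 0:
            raise ConfigurationError("empty timepoint list")
        lo, hi = self.effect_log2fc_range
        if lo > hi:
            raise ConfigurationError("effect_log2fc_range low > high")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not (0 <= self.motif_plant_fraction <= 1 and 0 <= self.chip_pass_fraction <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if self.library_size_range[0] <= 0:
            raise ConfigurationError("library size scalars must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate")


def _largest_remainder(n: int, proportions) -> list[int]:
    """Apportion n into integer counts matching proportions exactly in total."""
    raw = [n * p for p in proportions]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, variance = mean + alpha*mean^2); Poisson when alpha == 0."""
    mean = np.maximum(mean, 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _gene_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Depletion time course
# ---------------------------------------------------------------------------

def generate_depletion_experiment(config: SimConfig):
    """Simulate the acute mitotic depletion course.

    Returns ``(counts, sheet, gene_table, truth)``.  The truth table (indexed
    by gene id) records the class label, the planted per-timepoint log2 fold
    change (depletion vs control), the planted stage label and, once the ChIP /
    promoter generators have run, the planted ChIP ratio and motif position.
    """
    config.validate()
    rng = _rng(config.seed, "depletion")
    ann_rng = _rng(config.seed, "annotation")
    genes = _gene_ids("g", config.n_genes)
    tps = list(config.timepoints_min)
    conditions = ("control", "depletion")
    reps = range(1, config.n_replicates + 1)

    classes = np.array(["null"] * config.n_genes, dtype=object)
    nd, nc, ns = config.n_direct_targets, config.n_confounded, config.n_slow
    classes[:nd] = "direct"
    classes[nd:nd + nc] = "confounded"
    classes[nd + nc:nd + nc + ns] = "slow"

    # annotation: gene lengths and stage labels
    lengths = np.round(np.exp(ann_rng.uniform(np.log(500), np.log(3000), config.n_genes))).astype(int)
    stages = np.empty(config.n_genes, dtype=object)
    stage_counts = _largest_remainder(nd, DIRECT_STAGE_PROPORTIONS)
    direct_stages = [s for s, c in zip(STAGES, stage_counts) for _ in range(c)]
    stages[:nd] = direct_stages
    stages[nd:] = np.array(STAGES, dtype=object)[ann_rng.integers(0, len(STAGES), config.n_genes - nd)]

    # baseline means: targets/slow repressed and low, others log-normal
    base = np.exp(ann_rng.normal(np.log(80.0), 1.0, config.n_genes))
    base[classes == "direct"] = config.baseline_target_mean
    base[classes == "slow"] = config.baseline_target_mean

    # planted per-timepoint log2FC (depletion vs control)
    lfc = pd.DataFrame(0.0, index=genes, columns=[f"lfc_t{t}" for t in tps])
    lo, hi = config.effect_log2fc_range
    direct_eff = rng.uniform(lo, hi, nd)
    conf_eff = rng.uniform(1.5, 2.5, nc) * rng.choice([-1.0, 1.0], nc)
    slow_eff = rng.uniform(max(lo, 1.8), max(hi, 2.2), ns)
    for j, t in enumerate(tps):
        col = f"lfc_t{t}"
        if t >= 15:
            lfc.iloc[:nd, j] = direct_eff
        if t >= 60:
            lfc.iloc[nd + nc:nd + nc + ns, j] = slow_eff
        lfc.iloc[nd:nd + nc, j] = conf_eff  # pre-existing difference at every t

    sample_rows = []
    columns = {}
    lib_lo, lib_hi = config.library_size_range
    for cond in conditions:
        for t in tps:
            for r in reps:
                sid = f"{cond}_{t}_{r}"
                sample_rows.append({"sample_id": sid, "condition": cond,
                                    "timepoint": t, "replicate": r})
                libsize = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi)))
                mean = base.copy()
                if cond == "depletion":
                    mean = mean * 2.0 ** lfc[f"lfc_t{t}"].to_numpy()
                columns[sid] = _nb_draw(rng, mean * libsize, config.dispersion)

    counts = CountMatrix(pd.DataFrame(columns, index=genes))
    sheet = SampleSheet(pd.DataFrame(sample_rows), time_unit="minutes")
    gene_table = pd.DataFrame({"length_bp": lengths, "stage": stages}, index=pd.Index(genes, name="gene_id"))
    truth = pd.DataFrame({"class": classes, "stage": stages}, index=pd.Index(genes, name="gene_id"))
    truth = truth.join(lfc)
    truth["chip_ratio"] = np.nan
    truth["motif_pos"] = -1
    return counts, sheet, gene_table, truth


# ---------------------------------------------------------------------------
# ChIP peak scores
# ---------------------------------------------------------------------------

def generate_chip_scores(truth: pd.DataFrame, config: SimConfig,
                         n_chip_replicates: int = 3) -> ChipScoreTable:
    """Plant per-gene ChIP peak scores with a controlled pass fraction.

    ``floor(chip_pass_fraction * n_direct)`` direct targets receive a planted
    mean-score ratio >= 0.5 relative to the reference gene (the first direct
    target, planted at ratio exactly 1); all other genes fall below 0.5.
    Replicate scores are mean-preserving, so the realized ratio equals the
    planted one exactly.
    """
    config.validate()
    if truth.empty:
        raise ConfigurationError("truth table is empty")
    direct = list(truth.index[truth["class"] == "direct"])
    if not direct:
        raise ConfigurationError("no direct targets: no reference gene available")
    rng = _rng(config.seed, "chip")
    reference = direct[0]
    n_pass = math.floor(config.chip_pass_fraction * len(direct))
    n_pass = max(n_pass, 1)  # the reference gene always passes

    ratios = pd.Series(rng.uniform(0.05, 0.45, len(truth)), index=truth.index)
    pass_genes = direct[:n_pass]
    ratios.loc[pass_genes] = rng.uniform(0.6, 1.4, len(pass_genes))
    fail_direct = direct[n_pass:]
    ratios.loc[fail_direct] = rng.uniform(0.2, 0.45, len(fail_direct))
    ratios.loc[reference] = 1.0

    ref_level = 10.0
    noise = rng.normal(0.0, 0.05, size=(len(truth), n_chip_replicates))
    noise -= noise.mean(axis=1, keepdims=True)  # mean-preserving jitter
    scores = (ratios.to_numpy()[:, None] * ref_level) * (1.0 + noise)
    table = pd.DataFrame(scores, index=truth.index,
                         columns=[f"rep{i}" for i in range(1, n_chip_replicates + 1)])
    truth["chip_ratio"] = ratios
    return ChipScoreTable(table, reference)


# ---------------------------------------------------------------------------
# Promoter / ORF / downstream sequences
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


_CORE_RC = _revcomp(URS1_CORE)


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _find_all(seq: bytes, pat: bytes) -> list[int]:
    hits, start = [], 0
    while True:
        i = seq.find(pat, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _scrub(seq: bytearray, keep: range | None = None) -> None:
    """Mutate bases until neither the core nor its reverse complement occurs,
    leaving positions in ``keep`` untouched."""
    pats = (URS1_CORE.encode(), _CORE_RC.encode())
    for _ in range(100):
        dirty = False
        for pat in pats:
            for i in _find_all(bytes(seq), pat):
                window = [j for j in range(i, i + 6)
                          if keep is None or j not in keep]
                if not window:
                    continue  # this is the planted occurrence itself
                j = window[len(window) // 2]
                seq[j] = ord("T") if seq[j] != ord("T") else ord("A")
                dirty = True
        if not dirty:
            return
    raise RuntimeError("motif scrubbing did not converge")  # pragma: no cover


def generate_promoters(truth: pd.DataFrame, config: SimConfig,
                       upstream_bp: int = 1000, orf_bp: int = 900,
                       downstream_bp: int = 1000) -> dict[str, dict[str, str]]:
    """Per-gene upstream (1 kb), ORF and downstream (1 kb) sequences.

    The URS1 core (GGCGGC) is planted in the upstream region of
    ``floor(motif_plant_fraction * n_direct)`` direct targets; chance
    occurrences (both strands) are scrubbed from every other region so that
    motif-fraction recovery is exact.  Planted 1-based positions are written
    into ``truth['motif_pos']``.
    """
    config.validate()
    if not 0 <= config.motif_plant_fraction <= 1:
        raise ConfigurationError("motif_plant_fraction outside [0, 1]")
    rng = _rng(config.seed, "promoters")
    direct = list(truth.index[truth["class"] == "direct"])
    n_plant = math.floor(config.motif_plant_fraction * len(direct))
    planted = set(direct[:n_plant])

    regions: dict[str, dict[str, str]] = {}
    for gene in truth.index:
        per = {}
        for region, size in (("upstream", upstream_bp), ("orf", orf_bp),
                             ("downstream", downstream_bp)):
            seq = _random_seq(rng, size)
            if gene in planted and region == "upstream":
                pos = int(rng.integers(0, size - len(URS1_CORE) + 1))
                seq[pos:pos + 6] = URS1_CORE.encode()
                _scrub(seq, keep=range(pos, pos + 6))
                truth.loc[gene, "motif_pos"] = pos + 1  # 1-based
            else:
                _scrub(seq)
            per[region] = seq.decode()
        regions[gene] = per
    return regions


# ---------------------------------------------------------------------------
# Staged expression atlas
# ---------------------------------------------------------------------------

def generate_stage_atlas(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Staged expression atlas whose per-gene argmax is the planted stage."""
    config.validate()
    rng = _rng(config.seed, "atlas")
    values = rng.uniform(1.0, 5.0, size=(len(truth), len(STAGES)))
    atlas = pd.DataFrame(values, index=truth.index, columns=list(STAGES))
    for gene, stage in truth["stage"].items():
        atlas.loc[gene, stage] += 10.0
    return atlas


# ---------------------------------------------------------------------------
# Meiotic induction course
# ---------------------------------------------------------------------------

def generate_meiosis_experiment(config: SimConfig):
    """Simulate the meiotic induction course with three planted response groups.

    Target genes sit quiet until the 2 h induction point, then induce in the
    control condition by their group's fold; in the depletion condition the
    post-induction level is multiplied by the group's depletion factor (~43%
    and ~20% decrease for groups 1 and 2, ~3% increase for group 3).  Returns
    ``(counts, sheet, truth)``; all genes share a nominal length, so TPM can
    be computed with a constant-length gene table.
    """
    config.validate()
    tps = list(config.timepoints_hr)
    if 2.0 not in tps:
        raise ConfigurationError("meiotic course requires the 2 h baseline timepoint")
    rng = _rng(config.seed, "meiosis")
    n_targets = sum(config.meiosis_group_sizes)
    if n_targets > config.n_genes:
        raise ConfigurationError("meiosis groups exceed n_genes")
    genes = _gene_ids("m", config.n_genes)

    group = np.array(["null"] * config.n_genes, dtype=object)
    fold = np.ones(config.n_genes)
    dep_factor = np.ones(config.n_genes)
    shape_idx = np.zeros(config.n_genes, dtype=int)
    start = 0
    for gi, (size, f, d) in enumerate(zip(config.meiosis_group_sizes,
                                          config.meiosis_induction_folds,
                                          config.meiosis_depletion_factors), start=1):
        group[start:start + size] = f"group{gi}"
        fold[start:start + size] = f * rng.uniform(0.95, 1.05, size)
        dep_factor[start:start + size] = d
        shape_idx[start:start + size] = gi - 1
        start += size

    # background genes are drawn high enough that induction of the targets
    # shifts library composition (hence TPM ratios) by only ~1%
    base = np.exp(rng.normal(np.log(300.0), 1.0, config.n_genes))
    base[:n_targets] = config.meiosis_target_baseline

    post_tps = [t for t in tps if t > 2.0]
    shapes = np.asarray(config.meiosis_time_shapes, dtype=float)
    if shapes.shape != (len(config.meiosis_group_sizes), len(post_tps)):
        raise ConfigurationError("meiosis_time_shapes must be n_groups x n_post_timepoints")

    sample_rows, columns = [], {}
    lib_lo, lib_hi = config.library_size_range
    for cond in ("control", "depletion"):
        for t in tps:
            for r in range(1, config.n_replicates + 1):
                sid = f"{cond}_{t}_{r}"
                sample_rows.append({"sample_id": sid, "condition": cond,
                                    "timepoint": t, "replicate": r})
                mean = base.copy()
                if t > 2.0:
                    ti = post_tps.index(t)
                    fold_t = np.where(group != "null",
                                      fold * shapes[shape_idx, ti], 1.0)
                    mean = base * fold_t
                    if cond == "depletion":
                        mean = np.where(group != "null", mean * dep_factor, mean)
                libsize = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi)))
                columns[sid] = _nb_draw(rng, mean * libsize, config.dispersion)

    counts = CountMatrix(pd.DataFrame(columns, index=genes))
    sheet = SampleSheet(pd.DataFrame(sample_rows), time_unit="hours")
    truth = pd.DataFrame({"class": group, "induction_fold": fold,
                          "depletion_factor": dep_factor},
                         index=pd.Index(genes, name="gene_id"))
    return counts, sheet, truth


# ---------------------------------------------------------------------------
# Early-meiotic gene-set curation inputs
# ---------------------------------------------------------------------------

def generate_emg_curation_inputs(config: SimConfig, n_universe: int = 1200,
                                 mitotic_cut: float = 50.0):
    """Synthetic analogues of the prior datasets feeding EMG set curation.

    Fabricates an induction log2FC table, a 394-member mid-meiotic (NDT80-
    responsive) set, a staged atlas and a mitotic TPM table sized so that the
    curation cascade lands on 609 induced genes, 518 after removal of the
    mid-meiotic set, 300 inside the early stage window, and 272 after the
    mitotic-expression exclusion.
    """
    rng = _rng(config.seed, "emg")
    n_induced, n_overlap, n_mmg = 609, 91, 394
    n_early, n_high_mitotic = 300, 28
    if n_universe < n_induced + (n_mmg - n_overlap):
        raise ConfigurationError("universe too small for the planted set sizes")
    genes = _gene_ids("e", n_universe)

    lfc = pd.Series(rng.uniform(-1.0, 0.95, n_universe), index=genes, name="induction_log2fc")
    lfc.iloc[:n_induced] = rng.uniform(1.05, 4.0, n_induced)

    # the mid-meiotic set: 91 members overlap the induced list, 303 do not
    mmg_members = genes[:n_overlap] + genes[n_induced:n_induced + (n_mmg - n_overlap)]

    remaining = genes[n_overlap:n_induced]  # the 518 survivors
    stages = pd.Series("mid", index=genes, dtype=object)
    early_genes = remaining[:n_early]
    stages.loc[early_genes] = [EARLY_STAGES[i % 3] for i in range(n_early)]
    n_late_window = len(remaining) - n_early
    stages.loc[remaining[n_early:]] = (["mid", "late"] * (n_late_window // 2 + 1))[:n_late_window]

    atlas_vals = rng.uniform(1.0, 5.0, size=(n_universe, len(STAGES)))
    atlas = pd.DataFrame(atlas_vals, index=genes, columns=list(STAGES))
    for gene, stage in stages.items():
        atlas.loc[gene, stage] += 10.0

    mitotic_tpm = pd.Series(rng.uniform(1.0, 40.0, n_universe), index=genes, name="mitotic_tpm")
    mitotic_tpm.loc[early_genes[:n_high_mitotic]] = rng.uniform(
        mitotic_cut + 10.0, mitotic_cut + 150.0, n_high_mitotic)

    return lfc, list(mmg_members), atlas, mitotic_tpm
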