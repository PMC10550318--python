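"""Meiotic response analyses.

Baseline-normalized response profiles (log2 TPM relative to the pre-induction
2 h timepoint), k-means grouping with a deterministic elbow rule, per-group
percent change between conditions, Spearman sample correlation, and a pooled
two-sample t test computed from printed summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .quantio import SampleSheet

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Baseline-normalized response
# ---------------------------------------------------------------------------

def response_vs_baseline(tpm: pd.DataFrame, sheet: SampleSheet,
                         baseline_time: float = 2.0, eps: float = 1.0) -> pd.DataFrame:
    """log2 of condition-mean TPM relative to the baseline timepoint.

    Per gene, condition and timepoint: log2((mean TPM_t + eps) /
    (mean TPM_baseline + eps)), computed separately per condition, so the
    baseline column is identically zero and the pseudocount (1 TPM) keeps
    every entry finite.  Columns are a (condition, timepoint) MultiIndex.
    """
    cols = {}
    for cond in sheet.conditions:
        base_ids = sheet.samples_for(cond, baseline_time)
        if not base_ids:
            raise KeyError(f"baseline timepoint {baseline_time!r} missing for {cond!r}")
        base = tpm[base_ids].mean(axis=1)
        for t in sheet.timepoints:
            ids = sheet.samples_for(cond, t)
            if not ids:
                continue
            mean_t = tpm[ids].mean(axis=1)
            cols[(cond, t)] = np.log2(mean_t + eps) - np.log2(base + eps)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["condition", "timepoint"])
    return out


# ---------------------------------------------------------------------------
# k-means with elbow rule
# ---------------------------------------------------------------------------

@dataclass
class Grouping:
    k: int
    labels: pd.Series            # 1..k per gene
    wss: dict[int, float]        # within-cluster sum of squares for k = 1..kmax
    seed: int


def _lloyd(X: np.ndarray, k: int, seed: int, max_iter: int = 300):
    """One k-means run: k-means++ seeding then Lloyd iterations.

    The within-cluster sum of squares is asserted non-increasing across
    iterations; an emptied cluster is re-seeded to the point farthest from its
    assigned center (logged).
    """
    centers, _ = kmeans_plusplus(X, k, random_state=seed)
    prev_wss = np.inf
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        wss = float(d2[np.arange(len(X)), new_labels].sum())
        assert wss <= prev_wss + 1e-9, "k-means objective increased"
        if np.array_equal(new_labels, labels) and np.isfinite(prev_wss):
            break
        labels, prev_wss = new_labels, wss
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = X[mask].mean(axis=0)
            else:
                farthest = int(d2[np.arange(len(X)), labels].argmax())
                centers[c] = X[farthest]
                prev_wss = np.inf  # re-seeding may transiently raise the objective
                logger.info("k-means: re-seeded empty cluster %d", c)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wss = float(d2[np.arange(len(X)), labels].sum())
    return labels, wss


def kmeans_elbow(matrix: pd.DataFrame, kmax: int = 8, seed: int = 0,
                 restarts: int = 10) -> Grouping:
    """Cluster response profiles and choose k by a discrete elbow rule.

    For each k in 1..kmax the best of ``restarts`` Lloyd runs (by WSS) is
    kept; k* maximizes the second difference WSS(k-1) - 2 WSS(k) + WSS(k+1)
    over k in 2..kmax-1 — a deterministic proxy for the visual elbow.  If
    every WSS is (numerically) zero the degenerate rule returns k* = 1.
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ClusteringError("response matrix contains non-finite values")
    if len(X) < kmax:
        raise ClusteringError(f"need at least kmax={kmax} rows, got {len(X)}")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=(kmax, restarts))

    wss: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in range(1, kmax + 1):
        best = (np.inf, None)
        for r in range(restarts):
            labels, w = _lloyd(X, k, int(run_seeds[k - 1, r]))
            if w < best[0]:
                best = (w, labels)
        wss[k] = best[0]
        best_labels[k] = best[1]

    if all(w <= 1e-12 for w in wss.values()):
        k_star = 1
    else:
        candidates = range(2, kmax)
        k_star = max(candidates,
                     key=lambda k: wss[k - 1] - 2.0 * wss[k] + wss[k + 1])

    labels = pd.Series(best_labels[k_star] + 1, index=matrix.index, name="cluster")
    return Grouping(k=k_star, labels=labels, wss=wss, seed=seed)


# ---------------------------------------------------------------------------
# Group summaries and correlations
# ---------------------------------------------------------------------------

def group_summary(grouping: Grouping, tpm: pd.DataFrame, sheet: SampleSheet,
                  timepoint: float = 2.5, eps: float = 1.0,
                  cond_a: str = "control", cond_b: str = "depletion") -> pd.DataFrame:
    """Per-cluster mean percent change (condition A minus B, relative to A).

    Computed on condition-mean TPM at the given timepoint:
    (control - depletion) / control * 100, averaged over cluster members, so a
    positive value is a percent decrease under depletion.  Empty clusters are
    excluded with a warning.
    """
    ids_a = sheet.samples_for(cond_a, timepoint)
    ids_b = sheet.samples_for(cond_b, timepoint)
    if not ids_a or not ids_b:
        raise KeyError(f"timepoint {timepoint!r} missing in one of the conditions")
    mean_a = tpm[ids_a].mean(axis=1) + eps
    mean_b = tpm[ids_b].mean(axis=1) + eps
    pct = (mean_a - mean_b) / mean_a * 100.0
    rows = []
    for c in sorted(grouping.labels.unique()):
        members = grouping.labels.index[grouping.labels == c]
        if len(members) == 0:  # pragma: no cover - cannot happen post-fit
            logger.warning("cluster %d empty; excluded from summary", c)
            continue
        rows.append({"cluster": int(c), "n": len(members),
                     "pct_decrease": float(pct.reindex(members).mean())})
    return pd.DataFrame(rows).set_index("cluster")


def spearman_matrix(tpm: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman rank correlation between samples (columns).

    Average ranks resolve ties; a constant column has undefined correlation
    and its pairs are reported missing.
    """
    if len(tpm) < 3:
        raise ValueError("need at least 3 genes for rank correlation")
    import warnings

    with warnings.catch_warnings():
        # constant columns are handled explicitly below (reported missing)
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, _ = stats.spearmanr(tpm.to_numpy(), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the two-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=tpm.columns, columns=tpm.columns)
    constant = tpm.nunique(axis=0) <= 1
    for col in tpm.columns[constant]:
        out.loc[col, :] = np.nan
        out.loc[:, col] = np.nan
    np.fill_diagonal(out.values, 1.0)
    return out


# ---------------------------------------------------------------------------
# Summary-statistic t test
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    df: int
    p_one_tailed: float
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float
    infinite: bool = False


def pooled_t_from_summary(n1: int, mean1: float, sd1: float,
                          n2: int, mean2: float, sd2: float) -> TTestResult:
    """Pooled two-sample t statistic from summary statistics.

    s^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (mean1 - mean2) / (s * sqrt(1/n1 + 1/n2)); df = n1 + n2 - 2;
    the one-tailed p comes from the t distribution's upper tail at \\|t\\|.
    Zero pooled variance gives t = 0 for equal means and an infinite-t flag
    otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if s2 == 0:
        if mean1 == mean2:
            return TTestResult(0.0, df, 0.5, n1, mean1, sd1, n2, mean2, sd2)
        t = np.inf if mean1 > mean2 else -np.inf
        return TTestResult(t, df, 0.0, n1, mean1, sd1, n2, mean2, sd2, infinite=True)
    t = (mean1 - mean2) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = float(stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, n1, mean1, sd1, n2, mean2, sd2)
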