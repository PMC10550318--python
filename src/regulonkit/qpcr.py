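"""qPCR quantification: standard curves, ChIP enrichment, relative expression.

ChIP-qPCR: each immunoprecipitated (IP) sample is run alongside a dilution
series of its matched input; a least-squares line of Ct against log10 dilution
normalizes for fragment abundance, and binding enrichment at a target locus is
the ratio of its curve-derived relative quantity over that of a control locus
where the factor is not expected to bind.

RT-qPCR: expression is normalized to a reference transcript by delta-Ct,
relative quantity (1+E)^(-dCt) with per-target amplification efficiency E
(default E = 1, the classic 2^-dCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


class FitError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Dilution standard curve: Ct = slope * log10(dilution) + intercept.

    The amplification efficiency is E = 10^(-1/slope) - 1 (E = 1 means perfect
    doubling per cycle, slope ~ -3.32).  A valid series has negative slope.
    """

    slope: float
    intercept: float
    efficiency: float
    r_squared: float

    def quantity(self, ct: float) -> float:
        """Relative template quantity for an observed Ct."""
        return float(10.0 ** ((ct - self.intercept) / self.slope))


def fit_standard_curve(dilutions, cts) -> StandardCurve:
    """Least-squares Ct vs log10(dilution) from an input dilution series."""
    d = np.asarray(dilutions, dtype=float)
    y = np.asarray(cts, dtype=float)
    if d.size != y.size or d.size < 3:
        raise FitError("need >= 3 (dilution, Ct) points")
    if (d <= 0).any():
        raise FitError("dilution factors must be positive")
    x = np.log10(d)
    if np.allclose(x, x[0]):
        raise FitError("zero variance in dilutions")
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise FitError(f"non-negative slope {res.slope:.3g}: invalid dilution series")
    eff = 10.0 ** (-1.0 / res.slope) - 1.0
    return StandardCurve(float(res.slope), float(res.intercept), float(eff),
                         float(res.rvalue ** 2))


def chip_enrichment(ip_cts: Mapping[str, float],
                    curves: Mapping[str, StandardCurve],
                    control_locus: str = "pNUF2") -> pd.Series:
    """Per-locus enrichment of IP material over the unbound control locus.

    Each locus' Ct is converted to a relative quantity through its own input
    standard curve (per-primer-pair efficiency), then divided by the control
    locus quantity.
    """
    if control_locus not in ip_cts:
        raise FitError(f"control locus {control_locus!r} missing from IP records")
    missing = [loc for loc in ip_cts if loc not in curves]
    if missing:
        raise FitError(f"no standard curve for locus/loci: {missing}")
    q = {loc: curves[loc].quantity(ct) for loc, ct in ip_cts.items()}
    control = q[control_locus]
    return pd.Series({loc: qty / control for loc, qty in q.items()},
                     name="enrichment")


def rt_relative_expression(records: pd.DataFrame, reference_gene: str = "PFY1",
                           efficiencies: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Reference-normalized relative expression from cDNA Ct values.

    ``records`` needs columns sample, target, ct.  Per sample and target,
    dCt = Ct_target - Ct_reference and relative quantity = (1+E)^(-dCt) with
    per-target efficiency E (default 1).
    """
    for col in ("sample", "target", "ct"):
        if col not in records.columns:
            raise FitError(f"records missing column {col!r}")
    rows = []
    for sample, sub in records.groupby("sample", sort=True):
        ref = sub.loc[sub["target"] == reference_gene, "ct"]
        if ref.empty:
            raise FitError(f"reference {reference_gene!r} not measured in sample {sample!r}")
        ref_ct = float(ref.mean())
        for target, tsub in sub.groupby("target", sort=True):
            if target == reference_gene:
                continue
            e = (efficiencies or {}).get(target, 1.0)
            dct = float(tsub["ct"].mean()) - ref_ct
            rows.append({"sample": sample, "target": target,
                         "delta_ct": dct,
                         "relative_quantity": (1.0 + e) ** (-dct)})
    return pd.DataFrame(rows, columns=["sample", "target", "delta_ct", "relative_quantity"])


# ---------------------------------------------------------------------------
# Synthetic record generation (round-trip testing)
# ---------------------------------------------------------------------------

def simulate_chip_qpcr(enrichments: Mapping[str, float], seed: int = 0,
                       slope: float = -3.3219, intercept: float = 20.0,
                       dilutions=(1.0, 0.1, 0.01, 0.001),
                       ct_noise_sd: float = 0.0,
                       control_locus: str = "pNUF2"):
    """Synthetic ChIP-qPCR records from planted enrichments.

    Builds one input dilution series per locus from the given curve and IP Ct
    values whose curve-derived quantities reproduce the planted enrichment
    over the control locus exactly when ``ct_noise_sd`` is zero.  Returns
    ``(ip_cts, dilution_records)``.
    """
    rng = np.random.default_rng(seed)
    all_enr = dict(enrichments)
    all_enr.setdefault(control_locus, 1.0)
    control_quantity = 0.05
    dil_records = []
    ip_cts = {}
    for locus, enr in sorted(all_enr.items()):
        for d in dilutions:
            ct = slope * np.log10(d) + intercept + rng.normal(0, ct_noise_sd)
            dil_records.append({"locus": locus, "dilution": d, "ct": float(ct)})
        quantity = control_quantity * enr
        ip_cts[locus] = float(slope * np.log10(quantity) + intercept
                              + rng.normal(0, ct_noise_sd))
    return ip_cts, pd.DataFrame(dil_records)


def simulate_rt_qpcr(relative_quantities: Mapping[str, float], seed: int = 0,
                     reference_gene: str = "PFY1", reference_ct: float = 18.0,
                     efficiency: float = 1.0, sample: str = "s1") -> pd.DataFrame:
    """Synthetic RT-qPCR records realizing the planted relative quantities."""
    rows = [{"sample": sample, "target": reference_gene, "ct": reference_ct}]
    for target, q in sorted(relative_quantities.items()):
        dct = -np.log(q) / np.log(1.0 + efficiency)
        rows.append({"sample": sample, "target": target, "ct": reference_ct + float(dct)})
    return pd.DataFrame(rows)
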