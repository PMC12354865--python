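"""Binarization of risk scores and combination with MRD status.

The continuous deep-learning risk score is binarized at the median of the
training cohort's scores (the shipped default threshold, 0.9357855, is the
training-cohort median frozen into the deployed model). The binary DL class
is then crossed with the ctDNA-derived molecular residual disease (MRD)
label into three joint strata: Double High Risk (MRD-positive and DL
high-risk), Either High Risk (exactly one of the two high), and Double Low
Risk (MRD-negative and DL low-risk). MRD enters purely as a given label;
patients with missing MRD are excluded from stratified analyses with a
logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_THRESHOLD", "RiskResult", "derive_threshold", "binarize",
           "combine_mrd", "stratify_cohort", "subgroup_table", "round_pct"]

log = logging.getLogger(__name__)

#: Median training-cohort risk score frozen into the deployed model.
DEFAULT_THRESHOLD = 0.9357855

_MRD_CODES = {"positive", "negative", "missing"}
_STRATUM = {
    ("high", "positive"): "DoubleHigh",
    ("low", "positive"): "EitherHigh",
    ("high", "negative"): "EitherHigh",
    ("low", "negative"): "DoubleLow",
}


@dataclass(frozen=True)
class RiskResult:
    patient_id: str
    risk: float
    threshold: float
    dl_class: str       # "high" | "low"
    mrd: str            # "positive" | "negative" | "missing"
    stratum: str        # "DoubleHigh" | "EitherHigh" | "DoubleLow" | "NA"


def derive_threshold(training_scores) -> float:
    """Median of the training-cohort scores (midpoint of middle two for even n)."""
    scores = np.asarray(list(training_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("cannot derive a threshold from zero scores")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite training scores")
    return float(np.median(scores))


def binarize(scores, threshold: float) -> list[str]:
    """"high" iff risk > threshold (strict: ties classify as low)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    return ["high" if s > threshold else "low" for s in scores]


def combine_mrd(dl_class: str, mrd: str) -> str:
    """Joint DL x MRD stratum; missing MRD maps to "NA"."""
    if dl_class not in ("high", "low"):
        raise ValueError(f"unknown DL class {dl_class!r}")
    if mrd not in _MRD_CODES:
        raise ValueError(f"unknown MRD code {mrd!r}")
    if mrd == "missing":
        return "NA"
    return _STRATUM[(dl_class, mrd)]


def stratify_cohort(scores: pd.DataFrame, clinical: pd.DataFrame,
                    threshold: float | None = None) -> pd.DataFrame:
    """Join scores with MRD labels into a per-patient stratification table.

    ``scores`` needs columns (patient_id, risk); ``clinical`` needs
    (patient_id, mrd_status). When ``threshold`` is None the shipped default
    is used.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLD
    merged = scores.merge(clinical[["patient_id", "mrd_status"]], on="patient_id",
                          how="left", validate="one_to_one")
    mrd = merged["mrd_status"].fillna("missing").astype(str).str.lower()
    bad = set(mrd.unique()) - _MRD_CODES
    if bad:
        raise ValueError(f"unknown MRD codes in clinical table: {sorted(bad)}")
    dl = binarize(merged["risk"].to_numpy(), threshold)
    strata = [combine_mrd(c, m) for c, m in zip(dl, mrd)]
    n_missing = sum(s == "NA" for s in strata)
    if n_missing:
        log.info("%d patients have missing MRD and are excluded from joint strata",
                 n_missing)
    return pd.DataFrame({
        "patient_id": merged["patient_id"],
        "risk": merged["risk"],
        "threshold": threshold,
        "dl_class": dl,
        "mrd": mrd,
        "stratum": strata,
    })


def round_pct(numerator: int, denominator: int, decimals: int = 1):
    """Percentage with half-up rounding; None for an empty denominator."""
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100 * int(numerator)) / Decimal(int(denominator))
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def subgroup_table(results: pd.DataFrame) -> pd.DataFrame:
    """Counts and DL-class percentages within each MRD level.

    One row per (mrd level, dl class): n, subgroup total and the percentage
    of the MRD level falling in that DL class, half-up to one decimal.
    Empty subgroups are emitted with n=0 and an undefined percentage.
    """
    rows = []
    for mrd in ("positive", "negative", "missing"):
        sub = results[results["mrd"] == mrd]
        total = len(sub)
        for dl in ("high", "low"):
            n = int((sub["dl_class"] == dl).sum())
            rows.append({"mrd": mrd, "dl_class": dl, "n": n, "subgroup_total": total,
                         "pct": round_pct(n, total)})
    return pd.DataFrame(rows)
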