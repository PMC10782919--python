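"""Classification reporting, explainability summaries and cohort tables.

Covers the read-outs of the analysis: baseline-sample selection (one slide
per patient for response prediction), confusion metrics overall and per
tumor type (TPR/TNR/FPR/FNR decomposition), rank correlation of the ensemble
score with continuous TPS and CPS, a false-negative-by-TPS-bin table, and a
Table-1-style cohort summary with response rates and KM median PFS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import km_estimate

__all__ = [
    "ConfusionByGroup",
    "ScoreAssociation",
    "select_baseline_samples",
    "classification_report",
    "score_vs_continuous",
    "fn_by_tps_bin",
    "cohort_summary",
]

RESPONDER_CLASSES = ("CR", "PR")


@dataclass
class ConfusionByGroup:
    """Overall and per-group confusion counts with derived ratios.

    Ratios that are undefined for a group (the group lacks that class) are
    NaN, never 0 — a 0 would draw a misleading bar in per-tumor-type plots.
    """

    overall: dict
    per_group: pd.DataFrame
    threshold: float


@dataclass
class ScoreAssociation:
    """Spearman rank correlations of the ensemble score with TPS and CPS."""

    rho_tps: float
    p_tps: float
    rho_cps: float
    p_cps: float
    n: int
    undefined: bool = False
    pairs: pd.DataFrame | None = None


def select_baseline_samples(clinical: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one slide per patient for response prediction.

    If a ``days_from_treatment`` column is present, the sample closest to the
    start of treatment wins, preferring pre-treatment on absolute ties; with
    only an ``is_baseline`` flag, the flagged row wins.  Residual ties break
    on the lexicographically earliest ``slide_id``.  Patients with no usable
    sample are dropped with a warning.
    """
    if "patient_id" not in clinical.columns:
        raise ValueError("clinical table must have a patient_id column")
    df = clinical.copy()
    if "days_from_treatment" in df.columns:
        usable = df[df["days_from_treatment"].notna()].copy()
        usable["_key_abs"] = usable["days_from_treatment"].abs()
        usable["_key_post"] = (usable["days_from_treatment"] > 0).astype(int)
        usable = usable.sort_values(["_key_abs", "_key_post", "slide_id"])
        out = usable.groupby("patient_id", as_index=False).first()
        out = out.drop(columns=["_key_abs", "_key_post"])
    elif "is_baseline" in df.columns:
        usable = df[df["is_baseline"].astype(bool)].sort_values("slide_id")
        out = usable.groupby("patient_id", as_index=False).first()
    else:
        out = df.sort_values("slide_id").groupby("patient_id", as_index=False).first()
    dropped = set(df["patient_id"]) - set(out["patient_id"])
    if dropped:
        warnings.warn(f"{len(dropped)} patient(s) without a usable baseline sample "
                      f"dropped: {sorted(dropped)[:5]}...", stacklevel=2)
    return out.reset_index(drop=True)


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def _metrics(tp, fp, tn, fn) -> dict:
    n = tp + fp + tn + fn
    return dict(
        tp=tp, fp=fp, tn=tn, fn=fn, n=n,
        accuracy=_ratio(tp + tn, n),
        sensitivity=_ratio(tp, tp + fn),   # TPR
        specificity=_ratio(tn, tn + fp),   # TNR
        tpr=_ratio(tp, tp + fn),
        tnr=_ratio(tn, tn + fp),
        fpr=_ratio(fp, fp + tn),
        fnr=_ratio(fn, fn + tp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def classification_report(scores, labels, threshold: float = 0.5,
                          groups=None) -> ConfusionByGroup:
    """Binary status calls at ``threshold`` and confusion metrics per group."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size == 0:
        raise ValueError("empty input")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    overall = _metrics(tp, fp, tn, fn)

    rows = []
    if groups is not None:
        g = np.asarray(groups)
        for grp in pd.unique(g):
            m = g == grp
            rows.append(dict(group=grp, **_metrics(
                int(np.sum((pred == 1) & (y == 1) & m)),
                int(np.sum((pred == 1) & (y == 0) & m)),
                int(np.sum((pred == 0) & (y == 0) & m)),
                int(np.sum((pred == 0) & (y == 1) & m)))))
    per_group = pd.DataFrame(rows)
    return ConfusionByGroup(overall=overall, per_group=per_group,
                            threshold=threshold)


def score_vs_continuous(scores, tps, cps=None) -> ScoreAssociation:
    """Spearman rank correlation (mid-rank ties) of scores with TPS and CPS.

    Complete-case only; a constant vector yields the ``undefined`` flag with
    NaN coefficients rather than a spurious value.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(tps, dtype=float)
    c = np.asarray(cps, dtype=float) if cps is not None else np.full_like(s, np.nan)
    keep = np.isfinite(s) & np.isfinite(t)
    if keep.sum() < 3:
        raise ValueError("need at least 3 complete (score, TPS) pairs")

    def spear(a, b):
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan, np.nan, True
        r = stats.spearmanr(a, b)
        return float(r.statistic), float(r.pvalue), False

    rho_t, p_t, und_t = spear(s[keep], t[keep])
    keep_c = np.isfinite(s) & np.isfinite(c)
    if keep_c.sum() >= 3:
        rho_c, p_c, und_c = spear(s[keep_c], c[keep_c])
    else:
        rho_c, p_c, und_c = np.nan, np.nan, True
    pairs = pd.DataFrame(dict(score=s, tps=t, cps=c))
    return ScoreAssociation(rho_tps=rho_t, p_tps=p_t, rho_cps=rho_c, p_cps=p_c,
                            n=int(keep.sum()), undefined=und_t and und_c,
                            pairs=pairs)


def fn_by_tps_bin(scores, labels, tps, threshold: float = 0.5,
                  bins=(0.01, 0.07, 0.25, 0.50, 1.0)) -> pd.DataFrame:
    """Distribution of false-negative calls across TPS bins.

    Supports the observation that most false negatives sit just above the 1%
    positivity cutoff: the first default bin is TPS in [1%, 7%).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    t = np.asarray(tps, dtype=float)
    fn_mask = (s < threshold) & (y == 1)
    edges = np.asarray(bins, dtype=float)
    rows = []
    n_fn = int(fn_mask.sum())
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = fn_mask & (t >= lo) & (t < hi)
        rows.append(dict(tps_low=lo, tps_high=hi, n_fn=int(in_bin.sum()),
                         fraction_of_fn=_ratio(int(in_bin.sum()), n_fn)))
    return pd.DataFrame(rows)


REQUIRED_SUMMARY_COLUMNS = ("patient_id", "tumor_type", "tps", "pfs_months",
                            "event", "best_response")


def cohort_summary(clinical: pd.DataFrame) -> dict:
    """Table-1-style cohort description.

    Reports patient/slide counts, counts per categorical column present
    (tumor type, sex, biopsy location), PD-L1 class counts at the 1% TPS
    cutoff, the objective response rate (CR/PR over treated patients, to the
    nearest percent), and KM median PFS with its 95% CI.
    """
    if len(clinical) == 0:
        raise ValueError("empty cohort")
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    df = clinical
    n_patients = df["patient_id"].nunique()
    responders = df["best_response"].isin(RESPONDER_CLASSES).sum()
    treated = len(df)
    km = km_estimate(times=df["pfs_months"].to_numpy(),
                     events=df["event"].to_numpy(int))
    out = dict(
        n_patients=int(n_patients),
        n_slides=int(df["slide_id"].nunique()) if "slide_id" in df.columns else int(len(df)),
        tumor_type_counts=df["tumor_type"].value_counts().to_dict(),
        pdl1_high=int((df["tps"] >= 0.01).sum()),
        pdl1_low=int((df["tps"] < 0.01).sum()),
        n_responders=int(responders),
        n_treated=int(treated),
        response_rate_pct=int(round(100.0 * responders / treated)),
        median_pfs_months=float(km.median),
        median_pfs_ci=tuple(km.median_ci),
        pfs_iqr=(float(km.q25), float(km.q75)),
    )
    for optional in ("sex", "biopsy_location"):
        if optional in df.columns:
            out[f"{optional}_counts"] = df[optional].value_counts().to_dict()
    return out
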