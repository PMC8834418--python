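"""Cohort-level statistics: ROC/AUC, Youden thresholds, fixed-threshold
patient calls, aggregates and group comparisons.

Each phenotype parameter has a known direction of patient-likeness:
patients form thick, rough clusters, so *lower* nGV, *higher* nSD_GV and
*lower* RGVSD indicate disease.  Scores are oriented accordingly before
any ROC computation (higher oriented score = more patient-like).

AUC is the Mann-Whitney probability (ties counted 0.5); the Youden
threshold maximizes J = sensitivity + specificity - 1 over midpoints
between consecutive distinct oriented scores plus +/- infinity, breaking
ties by higher sensitivity, then lower oriented threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOWER_IS_POSITIVE = "lower_is_positive"
HIGHER_IS_POSITIVE = "higher_is_positive"

#: Direction of patient-likeness per parameter.
DIRECTIONS = {
    "nGV": LOWER_IS_POSITIVE,
    "nSD_GV": HIGHER_IS_POSITIVE,
    "RGVSD": LOWER_IS_POSITIVE,
}


@dataclass(frozen=True)
class LabeledScore:
    value: float
    label: int  # 0 = healthy, 1 = patient
    direction: str = HIGHER_IS_POSITIVE

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (healthy) or 1 (patient)")
        if self.direction not in (LOWER_IS_POSITIVE, HIGHER_IS_POSITIVE):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class RocResult:
    auc: float
    threshold: float  # in original score units
    sensitivity_pct: float
    specificity_pct: float
    youden_J: float
    direction: str = HIGHER_IS_POSITIVE


@dataclass(frozen=True)
class ThresholdRule:
    """Fixed per-parameter cutoffs for patient calls."""

    nGV_max: float = 0.685
    nSD_GV_min: float = 0.065
    RGVSD_max: float = 9.712
    combine: str = "majority"  # majority | per_parameter


def make_scores(values, labels, direction) -> list[LabeledScore]:
    """Pack parallel value/label arrays into LabeledScore objects."""
    return [LabeledScore(float(v), int(l), direction) for v, l in zip(values, labels)]


def _unpack(scores):
    values = np.array([s.value for s in scores], dtype=float)
    labels = np.array([s.label for s in scores], dtype=int)
    if len(scores) == 0 or labels.min() == labels.max():
        raise ValueError("need at least one score of each class")
    direction = scores[0].direction
    if any(s.direction != direction for s in scores):
        raise ValueError("mixed score directions")
    oriented = values if direction == HIGHER_IS_POSITIVE else -values
    return values, labels, oriented, direction


def roc_auc(scores: list[LabeledScore]) -> float:
    """AUC as the Mann-Whitney probability, ties counted 0.5."""
    _, labels, oriented, _ = _unpack(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(oriented)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _confusion_at(oriented, labels, thr_oriented):
    pred = oriented > thr_oriented
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    return sens, spec


def youden_threshold(scores: list[LabeledScore]) -> RocResult:
    """ROC summary at the Youden-optimal cutoff.

    A sample is called patient when its oriented score exceeds the oriented
    threshold; on the original scale that is ``value < threshold`` for
    lower-is-positive parameters and ``value > threshold`` otherwise.
    """
    _, labels, oriented, direction = _unpack(scores)
    distinct = np.unique(oriented)
    candidates = np.concatenate(
        ([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf])
    )
    best = None
    for thr in candidates:
        sens, spec = _confusion_at(oriented, labels, thr)
        j = sens / 100.0 + spec / 100.0 - 1.0
        key = (j, sens, -thr)  # max J, then max sens, then min threshold
        if best is None or key > best[0]:
            best = (key, thr, sens, spec, j)
    _, thr, sens, spec, j = best
    thr_orig = thr if direction == HIGHER_IS_POSITIVE else -thr
    return RocResult(
        auc=roc_auc(scores),
        threshold=float(thr_orig),
        sensitivity_pct=float(sens),
        specificity_pct=float(spec),
        youden_J=float(j),
        direction=direction,
    )


def sensitivity_specificity(
    scores: list[LabeledScore], threshold: float
) -> tuple[float, float]:
    """Sensitivity and specificity (percent) at a threshold in original units."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    _, labels, oriented, direction = _unpack(scores)
    thr_oriented = threshold if direction == HIGHER_IS_POSITIVE else -threshold
    return _confusion_at(oriented, labels, thr_oriented)


def classify_record(rec, rule: ThresholdRule = ThresholdRule()) -> dict:
    """Per-parameter patient/healthy calls plus a combined call.

    A missing metric abstains from the vote; when every vote abstains the
    combined call is ``"unknown"``.  With ``combine="majority"`` the
    combined call is the majority of non-abstaining votes ("unknown" on an
    exact tie); with ``combine="per_parameter"`` no combined call is made.
    """

    def vote(value, cutoff, lower_is_patient):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return "abstain"
        if lower_is_patient:
            return "patient" if value < cutoff else "healthy"
        return "patient" if value > cutoff else "healthy"

    calls = {
        "nGV": vote(rec.nGV, rule.nGV_max, lower_is_patient=True),
        "nSD_GV": vote(rec.nSD_GV, rule.nSD_GV_min, lower_is_patient=False),
        "RGVSD": vote(rec.RGVSD, rule.RGVSD_max, lower_is_patient=True),
    }
    if rule.combine == "per_parameter":
        combined = None
    else:
        n_pat = sum(1 for c in calls.values() if c == "patient")
        n_hea = sum(1 for c in calls.values() if c == "healthy")
        if n_pat + n_hea == 0 or n_pat == n_hea:
            combined = "unknown"
        else:
            combined = "patient" if n_pat > n_hea else "healthy"
    return {**calls, "combined": combined}


def aggregate_stats(values) -> tuple[float, float]:
    """Arithmetic mean and population (n-divisor) SD of a set of values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("aggregate_stats needs at least one value")
    return float(arr.mean()), float(arr.std(ddof=0))


def ttest_groups(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t-test, two-sided.

    Degenerate zero-variance inputs are resolved analytically: equal means
    give (0, 1); unequal means give (+/- inf, 0).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# group comparisons (treatment cycles, TNM staging)
# ---------------------------------------------------------------------------

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4, "0": 0}


def _group_key(label, grouping: str):
    """Orderable key for a grouping label; raises on unorderable labels."""
    s = str(label).strip()
    try:
        if grouping == "treatment_cycle":
            if s.lower() in ("pretreatment", "pre", "0"):
                return (0, "")
            return (int(s), "")
        if grouping in ("t_stage", "n_stage", "m_stage"):
            prefix = grouping[0].upper()
            if not s.upper().startswith(prefix):
                raise ValueError
            rest = s[1:]
            num = ""
            while rest and rest[0].isdigit():
                num += rest[0]
                rest = rest[1:]
            return (int(num), rest.lower())
        if grouping == "cancer_stage":
            core = s.upper()
            suffix = ""
            while core and core[-1] not in "IV0":
                suffix = core[-1] + suffix
                core = core[:-1]
            return (_ROMAN[core], suffix)
    except (ValueError, KeyError):
        pass
    raise ValueError(f"unorderable {grouping} label: {label!r}")


GROUP_METRICS = ("S_um2", "nGV", "RGVS")


@dataclass
class GroupReport:
    grouping: str
    summary: pd.DataFrame  # per group: n, mean and SD of each metric
    pairwise: pd.DataFrame  # columns: metric, group_a, group_b, t, p
    trend: dict  # metric -> -1 / 0 / +1


def group_trend_report(records, grouping: str) -> GroupReport:
    """Per-group summaries, all pairwise t-tests and a monotone-trend flag.

    ``records`` is a sequence of PhenotypeRecord (or anything with the
    metric attributes plus the grouping attribute).  The trend flag per
    metric is the sign of the Spearman rank correlation between the group
    order and the group means.
    """
    rows = []
    for rec in records:
        g = getattr(rec, grouping)
        if g is None:
            continue
        rows.append(
            {"group": g, **{m: getattr(rec, m) for m in GROUP_METRICS}}
        )
    df = pd.DataFrame(rows).dropna()
    if df.empty:
        raise ValueError("no records with the requested grouping")
    keys = {g: _group_key(g, grouping) for g in df["group"].unique()}
    order = sorted(keys, key=keys.get)
    counts = df.groupby("group").size()
    usable = [g for g in order if counts[g] >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with at least 2 records each")

    summary_rows = []
    for g in usable:
        sub = df[df["group"] == g]
        row = {"group": g, "n": len(sub)}
        for m in GROUP_METRICS:
            mean, sd = aggregate_stats(sub[m])
            row[f"{m}_mean"], row[f"{m}_sd"] = mean, sd
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows).set_index("group")

    pair_rows = []
    for ga, gb in itertools.combinations(usable, 2):
        for m in GROUP_METRICS:
            t, p = ttest_groups(df[df["group"] == ga][m], df[df["group"] == gb][m])
            pair_rows.append({"metric": m, "group_a": ga, "group_b": gb, "t": t, "p": p})
    pairwise = pd.DataFrame(pair_rows)

    trend = {}
    ranks = np.arange(len(usable))
    for m in GROUP_METRICS:
        means = summary[f"{m}_mean"].to_numpy()
        if len(usable) < 2 or np.all(means == means[0]):
            trend[m] = 0
            continue
        rho = stats.spearmanr(ranks, means).statistic
        trend[m] = int(np.sign(rho)) if not math.isnan(rho) else 0

    return GroupReport(grouping=grouping, summary=summary, pairwise=pairwise, trend=trend)


def stratify_tables(
    phenotypes: pd.DataFrame,
    rule: ThresholdRule = ThresholdRule(),
    unit: str = "cluster",
) -> dict:
    """ROC reports and threshold calls from a phenotype table.

    ``phenotypes`` must carry a ``cohort`` column with both "healthy" and
    "patient" rows.  ``unit="cluster"`` pools every well; ``unit="sample"``
    averages each sample's wells before ROC analysis.
    """
    df = phenotypes[phenotypes["cohort"].isin(["healthy", "patient"])].copy()
    if unit == "sample":
        df = (
            df.groupby(["sample_id", "cohort"], as_index=False)[list(DIRECTIONS)]
            .mean()
        )
    elif unit != "cluster":
        raise ValueError(f"unknown unit {unit!r}")
    labels = (df["cohort"] == "patient").astype(int).to_numpy()
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("need both healthy and patient cohorts")

    roc_report = {}
    for param, direction in DIRECTIONS.items():
        vals = df[param].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        scores = make_scores(vals[ok], labels[ok], direction)
        res = youden_threshold(scores)
        roc_report[param] = {
            "auc": res.auc,
            "threshold": res.threshold,
            "sensitivity_pct": res.sensitivity_pct,
            "specificity_pct": res.specificity_pct,
            "youden_J": res.youden_J,
            "direction": direction,
        }

    aucs = [roc_report[p]["auc"] for p in DIRECTIONS]
    senss = [roc_report[p]["sensitivity_pct"] for p in DIRECTIONS]
    specs = [roc_report[p]["specificity_pct"] for p in DIRECTIONS]
    roc_report["aggregate"] = {
        "auc_mean_sd": aggregate_stats(aucs),
        "sensitivity_mean_sd": aggregate_stats(senss),
        "specificity_mean_sd": aggregate_stats(specs),
    }

    call_rows = []
    for _, row in phenotypes.iterrows():
        rec = _RowView(row)
        calls = classify_record(rec, rule)
        call_rows.append(
            {
                "sample_id": row.get("sample_id", ""),
                "well_id": row.get("well_id", ""),
                "cohort": row.get("cohort", "unknown"),
                "call_nGV": calls["nGV"],
                "call_nSD_GV": calls["nSD_GV"],
                "call_RGVSD": calls["RGVSD"],
                "call_combined": calls["combined"],
            }
        )
    return {"roc_report": roc_report, "calls": pd.DataFrame(call_rows)}


class _RowView:
    """Attribute view over a phenotype-table row for classify_record."""

    def __init__(self, row):
        self.nGV = float(row.get("nGV", math.nan))
        self.nSD_GV = float(row.get("nSD_GV", math.nan))
        self.RGVSD = float(row.get("RGVSD", math.nan))
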