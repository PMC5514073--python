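"""Outcome layer: recurrence prediction metrics and group comparisons.

Detection of mutDNA at the early on-treatment visit (just before the
second chemotherapy cycle) is treated as a binary classifier of later
recurrence.  The 2x2 table yields sensitivity, specificity, PPV and NPV
with exact (Clopper-Pearson) binomial confidence intervals; survival is
summarised with Kaplan-Meier curves and a two-group log-rank test.
Group-level contrasts use the two-sample Kolmogorov-Smirnov test on AF
distributions, per-timepoint chi-squared tests with Bonferroni
correction, and a Kruskal-Wallis test across sample types with Dunn's
pairwise follow-up.

Patients without any panel SNV in tumour or fluids cannot be classified
by an SNV assay and form an explicit "unevaluable" stratum rather than
being silently counted as negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .detection import FLUID_SAMPLE_TYPES, Presence, patient_presence


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles.

    Lower bound is 0 when k=0 and upper bound 1 when k=n.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass(frozen=True)
class Proportion:
    """A proportion with its exact CI; ``defined`` is False on a zero
    denominator (the value is then NaN, never silently 0)."""

    k: int
    n: int
    value: float
    ci: tuple[float, float]
    defined: bool

    def percent(self, decimals: int = 1) -> float:
        return round(self.value * 100.0, decimals)

    def ci_percent(self) -> tuple[int, int]:
        """CI bounds as integer percents (reporting convention)."""
        return (_round_half_up(self.ci[0] * 100), _round_half_up(self.ci[1] * 100))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _proportion(k: int, n: int, conf: float) -> Proportion:
    if n == 0:
        return Proportion(k, n, float("nan"), (float("nan"), float("nan")), False)
    return Proportion(k, n, k / n, clopper_pearson(k, n, conf), True)


@dataclass(frozen=True)
class ContingencyMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    conf: float

    def to_dict(self) -> dict:
        out: dict = {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            p: Proportion = getattr(self, name)
            out[name] = {
                "k": p.k,
                "n": p.n,
                "percent": p.percent() if p.defined else None,
                "ci_percent": list(p.ci_percent()) if p.defined else None,
                "defined": p.defined,
            }
        return out


def contingency_metrics(
    tp: int, fp: int, fn: int, tn: int, conf: float = 0.95
) -> ContingencyMetrics:
    """Detection-vs-outcome metrics from a 2x2 table with exact CIs."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    return ContingencyMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_proportion(tp, tp + fn, conf),
        specificity=_proportion(tn, tn + fp, conf),
        ppv=_proportion(tp, tp + fp, conf),
        npv=_proportion(tn, tn + fn, conf),
        conf=conf,
    )


# -- survival ------------------------------------------------------------


def km_curve(survival: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate per group.

    ``survival`` needs columns ``time`` (days, > 0), ``event`` (1 =
    recurred, 0 = censored) and ``group``.  Returns a long table (group,
    time, survival, at_risk) with S(0)=1 and steps only at event times.
    """
    _check_survival(survival)
    out = []
    for grp, sub in survival.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            out.append(
                {
                    "group": grp,
                    "time": float(t),
                    "survival": float(s),
                    "at_risk": int(at_risk.loc[t]),
                }
            )
    return pd.DataFrame(out, columns=["group", "time", "survival", "at_risk"])


def logrank_test(survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance, chi-square(1) p)."""
    _check_survival(survival)
    groups = sorted(survival["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    a = survival[survival["group"] == groups[0]]
    b = survival[survival["group"] == groups[1]]
    if survival["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def _check_survival(survival: pd.DataFrame) -> None:
    for col in ("time", "event", "group"):
        if col not in survival.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    if len(survival) == 0:
        raise ValueError("survival table is empty")
    if (survival["time"] <= 0).any():
        raise ValueError("times must be positive")


def classify_cycle2(
    called: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    timepoint: int = 2,
) -> pd.DataFrame:
    """Per-patient mutDNA presence at the cycle-2 visit, with outcome.

    Patients whose panel has no SNV anywhere (no variant rows at all) and
    patients with no available sample at the visit are "unevaluable".
    Returns one row per patient: group in {present, absent, unevaluable},
    time (recurrence or censoring days) and event flag.
    """
    per_patient = sample_sheet.drop_duplicates("patient").set_index("patient")
    rows = []
    for patient in per_patient.index:
        info = per_patient.loc[patient]
        status = patient_presence(called, patient, timepoint)
        time = (
            float(info["recurrence_days"])
            if info["recurred"]
            else float(info["followup_days"])
        )
        rows.append(
            {
                "patient": patient,
                "group": status.value,
                "time": time,
                "event": int(bool(info["recurred"])),
            }
        )
    return pd.DataFrame(rows, columns=["patient", "group", "time", "event"])


# -- group comparisons ---------------------------------------------------


def ks_af_comparison(af_a, af_b) -> tuple[float, float]:
    """Two-sample KS test between AF distributions (e.g. recurrers vs not)."""
    a = np.asarray(af_a, dtype=float)
    b = np.asarray(af_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi2_detection_by_timepoint(
    called: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    correction: bool = False,
) -> pd.DataFrame:
    """Per-timepoint 2x2 chi-squared of detection counts, recurrers vs
    non-recurrers, Bonferroni-adjusted over timepoints.

    Units are mutant-timepoint analyses (variant x sample tests), matching
    the grid.  ``correction`` toggles Yates continuity correction (off by
    default).  Timepoints where the table is degenerate get NaN.
    """
    fluids = called[called["sample_type"].isin(FLUID_SAMPLE_TYPES)].copy()
    rec = sample_sheet.drop_duplicates("patient").set_index("patient")["recurred"]
    fluids["recurred"] = fluids["patient"].map(rec).astype(bool)
    rows = []
    timepoints = sorted(fluids["timepoint"].unique())
    for tp in timepoints:
        sub = fluids[fluids["timepoint"] == tp]
        table = np.zeros((2, 2), dtype=int)
        for i, flag in enumerate([True, False]):
            grp = sub[sub["recurred"] == flag]
            table[i, 0] = int(grp["detected"].sum())
            table[i, 1] = int((~grp["detected"]).sum())
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            chi2, p = float("nan"), float("nan")
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
        rows.append(
            {
                "timepoint": tp,
                "detected_recur": table[0, 0],
                "tested_recur": int(table[0].sum()),
                "detected_nonrecur": table[1, 0],
                "tested_nonrecur": int(table[1].sum()),
                "chi2": chi2,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    m = len(timepoints)
    out["p_bonferroni"] = np.minimum(out["p_raw"] * m, 1.0)
    return out


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(m * p, 1)``."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    return np.minimum(p * m, 1.0)


def kruskal_dunn(groups: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across groups plus Dunn's pairwise post-hoc.

    Dunn's z uses mean ranks of the pooled sample with tie correction;
    pairwise p-values are Bonferroni-adjusted over the pairs.  Raises on
    fewer than 2 non-empty groups; an all-tied pooled sample is flagged.
    """
    names = [k for k, v in groups.items() if len(v) > 0]
    if len(names) < 2:
        raise ValueError("need >= 2 non-empty groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"statistic": float("nan"), "p": float("nan"),
                "degenerate": True, "pairwise": []}
    hstat, hp = stats.kruskal(*arrays)

    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(a) for a in arrays]
    mean_ranks, pos = [], 0
    for sz in sizes:
        mean_ranks.append(ranks[pos : pos + sz].mean())
        pos += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = []
    raw_ps = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else float("nan")
            p = 2.0 * stats.norm.sf(abs(z))
            pairs.append({"a": names[i], "b": names[j], "z": float(z)})
            raw_ps.append(p)
    adj = bonferroni(raw_ps)
    for d, pr, pa in zip(pairs, raw_ps, adj):
        d["p_raw"] = float(pr)
        d["p_bonferroni"] = float(pa)
    return {
        "statistic": float(hstat),
        "p": float(hp),
        "degenerate": False,
        "pairwise": pairs,
    }


def median_time_to_event(times) -> tuple[int, float, float]:
    """Sample median of event times in days, rounded half-up, with range."""
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        raise ValueError("no event times given")
    return _round_half_up(float(np.median(t))), float(t.min()), float(t.max())


__all__ = [
    "Presence",
    "Proportion",
    "ContingencyMetrics",
    "clopper_pearson",
    "contingency_metrics",
    "km_curve",
    "logrank_test",
    "classify_cycle2",
    "ks_af_comparison",
    "chi2_detection_by_timepoint",
    "bonferroni",
    "kruskal_dunn",
    "median_time_to_event",
]
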