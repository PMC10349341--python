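"""Per-drug funding statistics and comparisons against industry benchmarks.

Builds per-drug per-phase cost profiles from the deduplicated attribution
ledger, computes per-funded-drug means, public-vs-industry percentage ratios
and paired mean-difference comparisons, designation-stratified rank tests,
grant activity-code categorization, and the sensitivity/specificity/kappa
metrics used to validate automated trial detection against manual review.

Conventions for the paired comparison: drugs without an industry estimate
are dropped; within the included drugs, a phase with no public funding
contributes zero (costs are observed absences, not missing data).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import DESIGNATION_FLAGS, REPORT_PHASES

PAIRED_PHASES = ["P1", "P2", "P3"]  # phases with industry benchmarks


@dataclass
class ComparisonResult:
    """Outcome of a two-sample or paired comparison."""

    statistic: float
    p_value: float
    estimate: float | None = None      # mean difference (paired) or None
    ci_low: float | None = None
    ci_high: float | None = None
    n1: int = 0
    n2: int = 0
    group_summaries: dict = field(default_factory=dict)  # medians/IQRs or means/SDs


@dataclass
class ValidationMetrics:
    sensitivity: float | None
    specificity: float | None
    kappa: float | None
    n_labeled: int


def per_drug_profiles(drug_phase_totals: pd.DataFrame,
                      industry_costs: pd.DataFrame,
                      drugs: pd.DataFrame) -> pd.DataFrame:
    """One profile row per drug with any funded development project-year.

    Columns: drug_id, nih_P1..nih_P4, nih_NCT_OTHER, nih_total,
    industry_P1..P3 and industry_total (NaN for drugs without a benchmark),
    plus the six designation flags.  Drugs with no funded project-year are
    absent — per-phase means downstream divide by funded drugs only.
    """
    if drug_phase_totals.empty:
        funded: dict[str, dict[str, float]] = {}
    else:
        funded = {
            did: dict(zip(grp.phase, grp.adjusted_cost))
            for did, grp in drug_phase_totals.groupby("drug_id")
        }
    industry = {
        (r.drug_id, r.phase): float(r.cost) for r in industry_costs.itertuples()
    }
    industry_drugs = {r.drug_id for r in industry_costs.itertuples()}
    flags = {r.drug_id: {f: bool(getattr(r, f)) for f in DESIGNATION_FLAGS}
             for r in drugs.itertuples()}

    rows = []
    for did in sorted(funded):
        by_phase = funded[did]
        row: dict = {"drug_id": did}
        for ph in REPORT_PHASES:
            row[f"nih_{ph.value}"] = float(by_phase.get(ph.value, 0.0))
        row["nih_total"] = float(sum(by_phase.values()))
        if did in industry_drugs:
            for ph in PAIRED_PHASES:
                row[f"industry_{ph}"] = industry.get((did, ph), 0.0)
            row["industry_total"] = sum(row[f"industry_{ph}"] for ph in PAIRED_PHASES)
        else:
            for ph in PAIRED_PHASES:
                row[f"industry_{ph}"] = np.nan
            row["industry_total"] = np.nan
        row.update(flags.get(did, {f: False for f in DESIGNATION_FLAGS}))
        rows.append(row)
    cols = (["drug_id"] + [f"nih_{p.value}" for p in REPORT_PHASES] + ["nih_total"]
            + [f"industry_{p}" for p in PAIRED_PHASES] + ["industry_total"]
            + DESIGNATION_FLAGS)
    return pd.DataFrame(rows, columns=cols)


def mean_per_funded_drug(total_cost: float, n_funded_drugs: int) -> float | None:
    """Average funding per drug among drugs funded in a phase.

    Returns ``None`` (reported as absent) when no drug is funded.
    """
    if n_funded_drugs <= 0:
        return None
    return total_cost / n_funded_drugs


def percent_of_industry(nih_mean: float, industry_mean: float) -> float:
    """Public mean as a percentage of the industry mean, to one decimal."""
    if industry_mean <= 0:
        raise ValueError("industry mean must be positive")
    return round(100.0 * nih_mean / industry_mean, 1)


def mannwhitney_two_tailed(x, y) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test with per-group median and IQR.

    Uses exact enumeration when both samples have at most 8 observations and
    no ties span the groups, otherwise the tie-corrected normal approximation
    with continuity correction.  If every value in both groups is identical
    the test is vacuous and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    summaries = {
        "x": {"median": float(np.median(x)), "iqr": float(np.subtract(*np.percentile(x, [75, 25])))},
        "y": {"median": float(np.median(y)), "iqr": float(np.subtract(*np.percentile(y, [75, 25])))},
    }
    if np.all(pooled == pooled[0]):
        return ComparisonResult(statistic=len(x) * len(y) / 2.0, p_value=1.0,
                                n1=len(x), n2=len(y), group_summaries=summaries)
    small = len(x) <= 8 and len(y) <= 8
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return ComparisonResult(statistic=float(res.statistic),
                            p_value=float(min(res.pvalue, 1.0)),
                            n1=len(x), n2=len(y), group_summaries=summaries)


def paired_t_two_tailed(first, second) -> ComparisonResult:
    """Two-tailed paired t test on per-drug cost pairs.

    Reports the mean difference ``second - first`` with its 95% confidence
    interval from the t distribution on n-1 degrees of freedom.  With all
    differences zero the comparison is vacuous and p = 1.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if len(first) != len(second):
        raise ValueError("paired samples must have equal length")
    n = len(first)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = second - first
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    summaries = {
        "first": {"mean": float(first.mean()), "sd": float(first.std(ddof=1))},
        "second": {"mean": float(second.mean()), "sd": float(second.std(ddof=1))},
    }
    if sd == 0.0:
        p = 1.0 if mean == 0 else 0.0
        return ComparisonResult(statistic=math.inf if mean else 0.0, p_value=p,
                                estimate=mean, ci_low=mean, ci_high=mean,
                                n1=n, n2=n, group_summaries=summaries)
    se = sd / math.sqrt(n)
    t_stat = mean / se
    p = float(2 * sps.t.sf(abs(t_stat), df=n - 1))
    half = float(sps.t.ppf(0.975, df=n - 1)) * se
    return ComparisonResult(statistic=t_stat, p_value=p, estimate=mean,
                            ci_low=mean - half, ci_high=mean + half,
                            n1=n, n2=n, group_summaries=summaries)


def classify_activity_code(code: str) -> str:
    """Grant-mechanism category from the activity code.

    Leading U → cooperative agreements; P (and the historical M01 general
    clinical research centers) → program projects and centers; R →
    investigator-initiated research projects; K/T/F → training and career
    programs; anything else → other.  Case-insensitive.
    """
    if not code or not str(code).strip():
        raise ValueError("empty activity code")
    code = str(code).strip().upper()
    if code == "M01":
        return "program_projects_centers"
    first = code[0]
    if first == "U":
        return "cooperative_agreement"
    if first == "P":
        return "program_projects_centers"
    if first == "R":
        return "research_project"
    if first in ("K", "T", "F"):
        return "training_career"
    return "other"


def cohen_kappa(labels_a, labels_b) -> float | None:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) between two raters."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be nonempty and equal-length")
    p_o = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_e == 1.0:
        return None  # degenerate: a single category on both sides
    return (p_o - p_e) / (1 - p_e)


def validation_metrics(predicted, reader1, reader2,
                       positive=True) -> ValidationMetrics:
    """Validate automated trial detection against two manual readers.

    The gold label is the reader consensus; items where the readers disagree
    are dropped from the sensitivity/specificity computation (kappa between
    the readers quantifies that disagreement).  Sensitivity = TP/(TP+FN) and
    specificity = TN/(TN+FP) of ``predicted`` against gold; undefined
    denominators are reported as absent with a warning.
    """
    predicted = np.asarray(predicted)
    reader1 = np.asarray(reader1)
    reader2 = np.asarray(reader2)
    if not (len(predicted) == len(reader1) == len(reader2)):
        raise ValueError("label vectors must have equal length")
    kappa = cohen_kappa(reader1, reader2)
    agree = reader1 == reader2
    gold = reader1[agree]
    pred = predicted[agree]
    pos = gold == positive
    tp = int(np.sum(pos & (pred == positive)))
    fn = int(np.sum(pos & (pred != positive)))
    tn = int(np.sum(~pos & (pred != positive)))
    fp = int(np.sum(~pos & (pred == positive)))
    sens = spec = None
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        warnings.warn("no positive gold labels; sensitivity undefined")
    if tn + fp > 0:
        spec = tn / (tn + fp)
    else:
        warnings.warn("no negative gold labels; specificity undefined")
    return ValidationMetrics(sensitivity=sens, specificity=spec, kappa=kappa,
                             n_labeled=int(agree.sum()))


def designation_comparisons(profiles: pd.DataFrame) -> pd.DataFrame:
    """Stratified rank comparisons of per-drug development totals.

    For each designation flag, compares total public development cost of
    flagged vs non-flagged funded drugs by two-tailed Mann-Whitney U test,
    reporting per-stratum n, mean (SD) and median (IQR).
    """
    rows = []
    for flag in DESIGNATION_FLAGS:
        yes = profiles.loc[profiles[flag].astype(bool), "nih_total"].to_numpy(float)
        no = profiles.loc[~profiles[flag].astype(bool), "nih_total"].to_numpy(float)
        rec = {"designation": flag, "n_yes": len(yes), "n_no": len(no)}
        for name, vals in (("yes", yes), ("no", no)):
            if len(vals):
                rec[f"mean_{name}"] = float(vals.mean())
                rec[f"sd_{name}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                rec[f"median_{name}"] = float(np.median(vals))
                rec[f"iqr_{name}"] = float(np.subtract(*np.percentile(vals, [75, 25])))
            else:
                rec[f"mean_{name}"] = rec[f"sd_{name}"] = np.nan
                rec[f"median_{name}"] = rec[f"iqr_{name}"] = np.nan
        if len(yes) and len(no):
            res = mannwhitney_two_tailed(yes, no)
            rec["u_statistic"] = res.statistic
            rec["p_value"] = res.p_value
        else:
            rec["u_statistic"] = rec["p_value"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def industry_comparison(profiles: pd.DataFrame) -> pd.DataFrame:
    """Paired per-phase comparison of public vs industry per-drug costs.

    Restricted to funded drugs with an industry benchmark; within those,
    phases with no public funding contribute zero.  One row per phase plus a
    phase 1-3 total: mean (SD) per source, the public/industry percentage,
    and the paired-t mean difference with 95% CI and p value.
    """
    paired = profiles[profiles.industry_total.notna()]
    rows = []
    specs = [(ph, f"nih_{ph}", f"industry_{ph}") for ph in PAIRED_PHASES]
    if len(paired) >= 2:
        nih_total = paired[[f"nih_{p}" for p in PAIRED_PHASES]].sum(axis=1)
        for label, nih_col, ind_col in specs + [("total_P1_P3", None, None)]:
            nih = nih_total.to_numpy(float) if nih_col is None \
                else paired[nih_col].to_numpy(float)
            ind = paired["industry_total"].to_numpy(float) if ind_col is None \
                else paired[ind_col].to_numpy(float)
            res = paired_t_two_tailed(nih, ind)
            rows.append({
                "phase": label, "n_drugs": len(paired),
                "nih_mean": res.group_summaries["first"]["mean"],
                "nih_sd": res.group_summaries["first"]["sd"],
                "industry_mean": res.group_summaries["second"]["mean"],
                "industry_sd": res.group_summaries["second"]["sd"],
                "nih_pct_of_industry": percent_of_industry(
                    res.group_summaries["first"]["mean"],
                    res.group_summaries["second"]["mean"])
                if res.group_summaries["second"]["mean"] > 0 else np.nan,
                "mean_difference": res.estimate,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value,
            })
    cols = ["phase", "n_drugs", "nih_mean", "nih_sd", "industry_mean", "industry_sd",
            "nih_pct_of_industry", "mean_difference", "ci_low", "ci_high", "p_value"]
    return pd.DataFrame(rows, columns=cols)
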