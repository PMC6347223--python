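"""Cohort-level summaries: class fractions, alteration distributions, rank tests.

Per condition x recovery time the summary reports the fractions of cells in
classes I/II/III/detached as an unweighted mean +/- sample SD across
replicates, the median and quartiles (linear interpolation between order
statistics) of each alteration parameter pooled over replicates, and a
two-sided Mann-Whitney U test of every cryopreservation condition against
the non-cryopreserved control at the same recovery time (null hypothesis:
equal medians; significance at p < 0.05, per-comparison, no multiplicity
correction by default — an optional Bonferroni correction is available).

Detached cells count toward class fractions but are excluded from the
alteration summaries and tests, since no post-thaw metrics exist for them.
Direction splits (increased vs decreased) are restricted to damaged cells
(classes II and III); cells with an exactly zero alteration count as "not
increased".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .classify import CLASS_ORDER

__all__ = [
    "mann_whitney_u", "class_fractions", "delta_summaries", "direction_split",
    "summarize_cohort", "CohortSummary",
]

DELTA_PARAMS = ("delta_nu", "delta_F", "delta_L")
#: exact enumeration is used up to this per-group size when no ties are present
EXACT_N_MAX = 8
ALPHA = 0.05


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of the first sample, p).

    The exact null distribution is enumerated when the smaller group has at
    most ``EXACT_N_MAX`` observations and there are no ties across the
    pooled sample; otherwise the tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= EXACT_N_MAX and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def class_fractions(records: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD class fractions over replicates for one stratum.

    ``records`` must carry ``replicate`` and ``assigned_class`` columns.
    Returns one row per class with columns mean_fraction and sd_fraction;
    the sample SD (ddof=1) is 0 for a single replicate.  Within each
    replicate the fractions over {I, II, III, detached} sum to 1.
    """
    reps = sorted(records["replicate"].unique())
    if not reps:
        raise ValueError("no replicates in records")
    fr = np.zeros((len(reps), len(CLASS_ORDER)))
    for i, rep in enumerate(reps):
        sub = records[records["replicate"] == rep]
        if len(sub) == 0:
            raise ValueError(f"replicate {rep!r} is empty")
        counts = sub["assigned_class"].value_counts()
        unknown = set(counts.index) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown class labels {unknown}")
        fr[i] = [counts.get(c, 0) / len(sub) for c in CLASS_ORDER]
    mean = fr.mean(axis=0)
    sd = fr.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(len(CLASS_ORDER))
    return pd.DataFrame({"assigned_class": CLASS_ORDER,
                         "mean_fraction": mean, "sd_fraction": sd})


def delta_summaries(records: pd.DataFrame, parameter: str) -> dict:
    """Median and quartiles of one alteration parameter for one stratum.

    Only finite values contribute; the number of dropped (detached or
    excluded) cells is reported alongside.  An empty stratum yields a
    flagged-empty summary rather than an error.
    """
    if parameter not in records.columns:
        raise KeyError(f"no column {parameter!r}")
    vals = records[parameter].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return {"parameter": parameter, "n": 0, "n_dropped": int(vals.size),
                "median": np.nan, "q25": np.nan, "q75": np.nan, "empty": True}
    q25, med, q75 = np.percentile(finite, [25, 50, 75])  # linear interpolation
    return {"parameter": parameter, "n": int(finite.size),
            "n_dropped": int(vals.size - finite.size),
            "median": float(med), "q25": float(q25), "q75": float(q75),
            "empty": False}


def direction_split(records: pd.DataFrame, parameter: str) -> tuple[float, float]:
    """(fraction increased, fraction decreased) among class II/III cells.

    Delta == 0 counts as "not increased".  Returns (nan, nan) when no
    damaged cell has a finite value.
    """
    sub = records[records["assigned_class"].isin(["II", "III"])]
    vals = sub[parameter].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return (float("nan"), float("nan"))
    inc = float(np.mean(vals > 0))
    return (inc, 1.0 - inc)


@dataclass
class CohortSummary:
    """Tabular summaries of a scored cohort."""

    fractions: pd.DataFrame       # per stratum x class: mean/sd fraction
    deltas: pd.DataFrame          # per stratum x parameter: median/quartiles + splits
    tests: pd.DataFrame           # per stratum x parameter: U, p, significant
    alpha: float = ALPHA
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "fractions": self.fractions.to_dict(orient="records"),
            "deltas": self.deltas.to_dict(orient="records"),
            "tests": self.tests.to_dict(orient="records"),
            "meta": self.meta,
        }


def summarize_cohort(records: pd.DataFrame, control_condition: str = "control",
                     compare: str = "control_vs_each",
                     bonferroni: bool = False) -> CohortSummary:
    """Full cohort summary from an alterations table.

    ``compare`` selects the test plan: "control_vs_each" (default) tests
    every other condition against the control at the same recovery time;
    "all_pairs" additionally tests cryo conditions against each other.
    """
    if compare not in ("control_vs_each", "all_pairs"):
        raise ValueError(f"unknown comparison plan {compare!r}")
    scored = records[records["assigned_class"].isin(CLASS_ORDER)]
    frac_rows, delta_rows = [], []
    for (cond, t), grp in scored.groupby(["condition", "recovery_min"], sort=True):
        cf = class_fractions(grp)
        for _, row in cf.iterrows():
            frac_rows.append({"condition": cond, "recovery_min": t, **row.to_dict()})
        for par in DELTA_PARAMS:
            d = delta_summaries(grp, par)
            inc, dec = direction_split(grp, par)
            delta_rows.append({"condition": cond, "recovery_min": t, **d,
                               "frac_increased": inc, "frac_decreased": dec})

    test_rows = []
    conditions = sorted(scored["condition"].unique())
    times = sorted(scored["recovery_min"].unique())
    for t in times:
        at_t = scored[scored["recovery_min"] == t]
        pairs = []
        if control_condition in conditions:
            pairs += [(control_condition, c) for c in conditions if c != control_condition]
        if compare == "all_pairs":
            others = [c for c in conditions if c != control_condition]
            pairs += [(a, b) for i, a in enumerate(others) for b in others[i + 1:]]
        for ref, other in pairs:
            for par in DELTA_PARAMS:
                x = at_t.loc[at_t["condition"] == ref, par].to_numpy(dtype=float)
                y = at_t.loc[at_t["condition"] == other, par].to_numpy(dtype=float)
                x, y = x[np.isfinite(x)], y[np.isfinite(y)]
                if x.size == 0 or y.size == 0:
                    continue
                u, p = mann_whitney_u(x, y)
                test_rows.append({"recovery_min": t, "reference": ref,
                                  "condition": other, "parameter": par,
                                  "U": u, "p": p,
                                  "n_ref": int(x.size), "n": int(y.size)})
    tests = pd.DataFrame(test_rows)
    alpha = ALPHA
    if len(tests):
        m = len(tests) if bonferroni else 1
        tests["significant"] = tests["p"] < alpha / m
    return CohortSummary(fractions=pd.DataFrame(frac_rows),
                         deltas=pd.DataFrame(delta_rows),
                         tests=tests, alpha=alpha,
                         meta={"compare": compare, "bonferroni": bonferroni,
                               "control_condition": control_condition})
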