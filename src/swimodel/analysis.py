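"""Analysis pipeline for ratio-report trial tables (real or simulated).

Reports are ratios, so every statistic is computed on natural-log
transformed values.  Trials are first mapped to the canonical
orientation ln(felt weight of the smaller cube / larger cube): B-S
presentations (small cube on the reporting side) enter directly,
S-B presentations are negated, identical-size control pairs are
excluded from pair summaries.  Positive collapsed values therefore
indicate the size-weight illusion.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "log_collapse",
    "illusion_magnitude_summary",
    "ew_pw_correlation",
    "variability_decomposition",
]


def _canonical_log(trials: pd.DataFrame) -> pd.Series:
    if (trials["report_ratio"] <= 0).any():
        raise ValueError("report ratios must be positive")
    lnr = np.log(trials["report_ratio"].to_numpy(float))
    sign = np.where(trials["ordering"].to_numpy() == "S-B", -1.0, 1.0)
    return pd.Series(lnr * sign, index=trials.index, name="ln_report")


def log_collapse(
    trials: pd.DataFrame,
    collapse_weight_class: bool = False,
    strict: bool = True,
) -> pd.DataFrame:
    """Per-subject condition means of canonical log reports.

    Collapses S-B and B-S orderings (negating S-B trials first) and
    optionally weight classes; identical-size control pairs are
    excluded.  With ``strict`` a subject missing a condition raises.
    """
    t = trials[trials["ordering"] != "I-S"].copy()
    if t.empty:
        raise ValueError("no test-pair trials to collapse")
    t["ln_report"] = _canonical_log(t)
    keys = ["subject_id", "pair"] + ([] if collapse_weight_class else ["weight_class"])
    out = t.groupby(keys, as_index=False)["ln_report"].mean()
    if strict:
        conditions = t[keys[1:]].drop_duplicates().shape[0]
        counts = out.groupby("subject_id").size()
        short = counts[counts < conditions]
        if not short.empty:
            raise ValueError(
                f"subject(s) {list(short.index)} missing conditions "
                f"({conditions} expected)"
            )
    return out


def illusion_magnitude_summary(per_subject_means: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SE of the collapsed log values, per pair.

    Adds ratio-scale columns via exp.  With a single subject the SE is
    reported as 0 and flagged degenerate.
    """
    keys = [c for c in ("pair", "weight_class") if c in per_subject_means.columns]
    rows = []
    for key_vals, grp in per_subject_means.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        vals = grp["ln_report"].to_numpy(float)
        n = vals.size
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(dict(zip(keys, key_vals)) | {
            "mean_log": mean,
            "se_log": se,
            "n_subjects": n,
            "mean_ratio": math.exp(mean),
            "degenerate": n <= 1,
        })
    return pd.DataFrame(rows)


def ew_pw_correlation(
    day1_means: pd.DataFrame,
    day2_means: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-pair correlation of subject ln(EW) with ln(PW).

    Inputs are per-subject per-pair means (weight classes already
    collapsed).  Pearson by default; Spearman available.  Requires at
    least 3 matched subjects per pair.
    """
    merged = day1_means.merge(day2_means, on=["subject_id", "pair"],
                              suffixes=("_ew", "_pw"))
    if merged.empty:
        raise ValueError("no matched subjects between the two sessions")
    rows = []
    for pair, grp in merged.groupby("pair"):
        if len(grp) < 3:
            raise ValueError(f"fewer than 3 paired subjects for pair {pair}")
        ew = grp["ln_report_ew"].to_numpy(float)
        pw = grp["ln_report_pw"].to_numpy(float)
        if np.std(ew) == 0 or np.std(pw) == 0:
            r, pval = float("nan"), float("nan")
        elif method == "pearson":
            r, pval = stats.pearsonr(ew, pw)
        elif method == "spearman":
            r, pval = stats.spearmanr(ew, pw)
        else:
            raise ValueError(f"unknown method: {method!r}")
        rows.append({"pair": pair, "r": float(r), "p_value": float(pval),
                     "n_subjects": len(grp), "degenerate": not np.isfinite(r)})
    return pd.DataFrame(rows)


def variability_decomposition(
    trials: pd.DataFrame,
    collapse_weight_class: bool = False,
) -> pd.DataFrame:
    """Between-subject vs within-subject SDs of canonical log reports.

    Within: SD across repeated trials of the same condition within a
    subject, averaged over subjects; between: SD across subjects of the
    per-subject condition means.  Reported per condition plus an
    'overall' row averaging conditions.
    """
    t = trials[trials["ordering"] != "I-S"].copy()
    t["ln_report"] = _canonical_log(t)
    keys = ["pair"] + ([] if collapse_weight_class else ["weight_class"])
    rows = []
    for key_vals, grp in t.groupby(keys):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        subj_means = grp.groupby("subject_id")["ln_report"].mean()
        between = float(subj_means.std(ddof=1)) if len(subj_means) > 1 else 0.0
        subj_sds = grp.groupby("subject_id")["ln_report"].std(ddof=1).dropna()
        within = float(subj_sds.mean()) if not subj_sds.empty else 0.0
        rows.append(dict(zip(keys, key_vals)) | {
            "between_sd": between, "within_sd": within,
        })
    out = pd.DataFrame(rows)
    overall = {k: "overall" for k in keys} | {
        "between_sd": float(out["between_sd"].mean()),
        "within_sd": float(out["within_sd"].mean()),
    }
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)
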