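"""Per-subject burden summaries, category comparisons and recovery scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def burden_by_subject(calls: pd.DataFrame,
                      sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Outlier counts (total/hyper/hypo) per sample.

    Rows are ordered by category and then gestational weight gain, the
    ordering under which the burden profile of normal subjects shows its
    U shape.  Samples without calls get zero rows.
    """
    unknown = set(calls["sample_id"]) - set(sample_sheet["Sample_ID"])
    if unknown:
        raise ValueError(f"calls reference unknown samples: {sorted(unknown)[:5]!r}")
    table = sample_sheet.set_index("Sample_ID").copy()
    counts = calls.groupby("sample_id")["probe_id"].size()
    hyper = calls[calls["direction"] == "hyper"].groupby("sample_id").size()
    hypo = calls[calls["direction"] == "hypo"].groupby("sample_id").size()
    table["n_outliers"] = counts.reindex(table.index).fillna(0).astype(int)
    table["n_hyper"] = hyper.reindex(table.index).fillna(0).astype(int)
    table["n_hypo"] = hypo.reindex(table.index).fillna(0).astype(int)
    sort_cols = ["category"]
    if "gwg_kg" in table.columns:
        sort_cols.append("gwg_kg")
    return table.sort_values(sort_cols, kind="stable").reset_index()


def category_summary(burdens: pd.DataFrame,
                     value_col: str = "n_outliers") -> pd.DataFrame:
    g = burdens.groupby("category")[value_col]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1),
                         "min": g.min(), "max": g.max(), "n": g.size()})


def tukey_hsd(burdens: pd.DataFrame,
              value_col: str = "n_outliers") -> pd.DataFrame:
    """All-pairs Tukey HSD on per-sample outlier counts across categories.

    Uses the studentized-range distribution on a one-way layout; counts
    are treated as approximately normal.  Categories with fewer than two
    samples are excluded with a warning.  Stars mark 0.05/0.01/0.001.
    """
    groups = {}
    for cat, sub in burdens.groupby("category"):
        if len(sub) < 2:
            warnings.warn(f"category {cat!r} has < 2 samples; excluded from Tukey")
            continue
        groups[cat] = sub[value_col].to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least two categories with >= 2 samples")
    cats = sorted(groups)
    within_var = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    if within_var > 0:
        res = stats.tukey_hsd(*[groups[c] for c in cats])
        pval = np.asarray(res.pvalue, dtype=float)
    else:
        # degenerate layout: identical counts within every category
        means = np.array([groups[c].mean() for c in cats])
        pval = np.where(means[:, None] == means[None, :], 1.0, 0.0)
    rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            p = float(pval[i, j])
            stars = "***" if p < 0.001 else "**" if p < 0.01 \
                else "*" if p < 0.05 else ""
            rows.append({"category_a": cats[i], "category_b": cats[j],
                         "mean_diff": float(groups[cats[i]].mean()
                                            - groups[cats[j]].mean()),
                         "p_adj": p, "stars": stars})
    return pd.DataFrame(rows)


def kruskal_categories(burdens: pd.DataFrame,
                       value_col: str = "n_outliers") -> tuple[float, float]:
    """Kruskal-Wallis alternative to the normal-theory comparison."""
    groups = [sub[value_col].to_numpy(dtype=float)
              for _, sub in burdens.groupby("category") if len(sub) >= 2]
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class RecoveryReport:
    n_injected: int
    n_recovered: int
    n_calls: int
    n_false: int
    sensitivity: float
    attribution_accuracy: float
    by_direction: dict

    def to_dict(self) -> dict:
        return {"n_injected": self.n_injected, "n_recovered": self.n_recovered,
                "n_calls": self.n_calls, "n_false": self.n_false,
                "sensitivity": self.sensitivity,
                "attribution_accuracy": self.attribution_accuracy,
                "by_direction": self.by_direction}


def score_recovery(calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryReport:
    """Score calls against the simulator's injection truth table.

    A truth record is recovered iff a call exists at the same
    (probe, sample) with matching direction.  Attribution accuracy is
    the fraction of calls at injected probes credited to the injected
    sample.  Calls matching no truth record are false calls.
    """
    truth_keys = set(zip(truth["probe_id"], truth["sample_id"], truth["direction"]))
    call_keys = set(zip(calls["probe_id"], calls["sample_id"], calls["direction"]))
    recovered = truth_keys & call_keys
    n_injected = len(truth_keys)
    sensitivity = len(recovered) / n_injected if n_injected else np.nan

    # attribution: among calls at probes with exactly one injected sample,
    # how often the call names that sample
    probe_truth = truth.drop_duplicates("probe_id").set_index("probe_id")
    at_injected = calls[calls["probe_id"].isin(probe_truth.index)]
    if len(at_injected):
        expected = probe_truth.loc[at_injected["probe_id"], "sample_id"].to_numpy()
        attribution = float((at_injected["sample_id"].to_numpy() == expected).mean())
    else:
        attribution = np.nan

    n_false = len(call_keys - truth_keys)
    by_direction = {}
    for direction in ("hyper", "hypo"):
        tk = {k for k in truth_keys if k[2] == direction}
        ck = {k for k in call_keys if k[2] == direction}
        by_direction[direction] = {
            "n_injected": len(tk),
            "n_recovered": len(tk & ck),
            "sensitivity": len(tk & ck) / len(tk) if tk else np.nan,
            "n_false": len(ck - tk),
        }
    return RecoveryReport(n_injected=n_injected, n_recovered=len(recovered),
                          n_calls=len(call_keys), n_false=n_false,
                          sensitivity=sensitivity,
                          attribution_accuracy=attribution,
                          by_direction=by_direction)


def heatmap_matrix(calls: pd.DataFrame, beta: pd.DataFrame) -> pd.DataFrame:
    """β values of called probes across all samples (heatmap-ready TSV)."""
    probes = calls["probe_id"].drop_duplicates()
    return beta.loc[beta.index.intersection(probes)]
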