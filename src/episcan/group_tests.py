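"""Per-probe two-group differential methylation testing.

Wilcoxon rank-sum (Mann-Whitney) tests per probe with
Benjamini-Hochberg control across probes.  The exact null distribution
is used when the smaller group has at most 10 samples and the probe is
tie-free; otherwise the normal approximation with tie correction.  The
cohort's standard comparisons (growth-restricted vs normal overall and
within each weight-gain stratum; insufficient/excessive vs adequate
weight gain within each phenotype) are exposed as named presets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 10

#: (column, label A, column, label B, optional (column, value) restriction)
PRESET_COMPARISONS: dict[str, dict] = {
    "fgr_vs_normal": dict(col="phenotype", a="FGR", b="normal", within=None),
    "fgr_vs_normal_insufficient": dict(col="phenotype", a="FGR", b="normal",
                                       within=("gwg_category", "insufficient")),
    "fgr_vs_normal_adequate": dict(col="phenotype", a="FGR", b="normal",
                                   within=("gwg_category", "adequate")),
    "fgr_vs_normal_excessive": dict(col="phenotype", a="FGR", b="normal",
                                    within=("gwg_category", "excessive")),
    "insufficient_vs_adequate_normal": dict(col="gwg_category", a="insufficient",
                                            b="adequate", within=("phenotype", "normal")),
    "excessive_vs_adequate_normal": dict(col="gwg_category", a="excessive",
                                         b="adequate", within=("phenotype", "normal")),
    "insufficient_vs_adequate_fgr": dict(col="gwg_category", a="insufficient",
                                         b="adequate", within=("phenotype", "FGR")),
    "excessive_vs_adequate_fgr": dict(col="gwg_category", a="excessive",
                                      b="adequate", within=("phenotype", "FGR")),
}


@dataclass
class GroupTestResult:
    table: pd.DataFrame          # per probe: mean_a, mean_b, statistic, p_raw, p_adj
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    threshold: float = 0.05

    @property
    def n_significant(self) -> int:
        return int((self.table["p_adj"] < self.threshold).sum())


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test for one probe; returns (U statistic, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 samples")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= EXACT_MAX_N and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
                   col: str, a: str, b: str,
                   within: tuple[str, str] | None = None,
                   threshold: float = 0.05) -> GroupTestResult:
    """Rank-sum test per probe between the samples labelled ``a`` and ``b``.

    ``within=(column, value)`` first restricts the sheet to a stratum.
    The exact/asymptotic switch is made per probe.
    """
    sheet = sample_sheet
    if within is not None:
        sheet = sheet[sheet[within[0]] == within[1]]
    ids_a = sheet.loc[sheet[col] == a, "Sample_ID"]
    ids_b = sheet.loc[sheet[col] == b, "Sample_ID"]
    ids_a = [s for s in ids_a if s in beta.columns]
    ids_b = [s for s in ids_b if s in beta.columns]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(f"grouping {col}: {a!r} vs {b!r}"
                         + (f" within {within}" if within else "")
                         + f" selects {len(ids_a)} vs {len(ids_b)} samples; "
                         "need at least 2 per side")
    X = beta[ids_a].to_numpy(dtype=float)
    Y = beta[ids_b].to_numpy(dtype=float)

    res_asym = stats.mannwhitneyu(X, Y, alternative="two-sided",
                                  method="asymptotic", axis=1)
    statistic = np.asarray(res_asym.statistic, dtype=float)
    p_raw = np.asarray(res_asym.pvalue, dtype=float)

    if min(len(ids_a), len(ids_b)) <= EXACT_MAX_N:
        both = np.concatenate([X, Y], axis=1)
        sorted_rows = np.sort(both, axis=1)
        tie_free = ~(np.diff(sorted_rows, axis=1) == 0).any(axis=1)
        if tie_free.any():
            res_ex = stats.mannwhitneyu(X[tie_free], Y[tie_free],
                                        alternative="two-sided",
                                        method="exact", axis=1)
            p_raw[tie_free] = res_ex.pvalue
            statistic[tie_free] = res_ex.statistic

    table = pd.DataFrame({
        "mean_a": X.mean(axis=1),
        "mean_b": Y.mean(axis=1),
        "statistic": statistic,
        "p_raw": p_raw,
        "p_adj": bh_adjust(p_raw),
    }, index=beta.index)
    return GroupTestResult(table=table, group_a=a, group_b=b,
                           n_a=len(ids_a), n_b=len(ids_b), threshold=threshold)


def run_preset(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
               name: str, threshold: float = 0.05) -> GroupTestResult:
    if name not in PRESET_COMPARISONS:
        raise KeyError(f"unknown comparison preset {name!r}; "
                       f"choose from {sorted(PRESET_COMPARISONS)}")
    return compare_groups(beta, sample_sheet, threshold=threshold,
                          **PRESET_COMPARISONS[name])
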