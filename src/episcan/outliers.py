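"""Smirnov-Grubbs single-outlier scan across probes.

For each probe the two-sided Grubbs statistic is the maximum absolute
standardized deviation G = max_i |x_i - x̄| / s (sample SD, ddof=1).
Its p-value comes from the classical t-inversion

    t_G = sqrt( N (N-2) G² / ((N-1)² - N G²) ),
    p   = min(1, 2 N · P(T_{N-2} ≥ t_G)),

a union bound over the N observations that is essentially exact deep in
the tail where calls are made.  Bonferroni correction across probes
(denominator = number of probes tested by default) with a corrected-p
cutoff of 0.1 yields at most one outlier call per probe, attributed to
the single most deviant sample.  Δβ is the outlier's β minus the mean β
of the other N-1 samples; its sign classifies the call as hyper- or
hypomethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CALL_COLUMNS = ["probe_id", "sample_id", "beta", "delta_beta", "direction",
                "grubbs_g", "p_raw", "p_bonf", "snp_flagged"]


@dataclass
class ScanParams:
    alpha_corrected: float = 0.1
    n_tests: int | None = None   # Bonferroni denominator; default = probes tested
    min_sd: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.alpha_corrected <= 1:
            raise ValueError("alpha_corrected must be in (0, 1]")
        if self.n_tests is not None and self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass
class ScanResult:
    calls: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def n_hyper(self) -> int:
        return int((self.calls["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.calls["direction"] == "hypo").sum())


def grubbs_statistic(x) -> tuple[float, int]:
    """(G, index of the most deviant sample); ties break to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    s = x.std(ddof=1)
    if s <= 0:
        raise ValueError("zero variance: no test")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    return float(dev[idx] / s), idx


def grubbs_pvalue(G, N) -> float:
    """Two-sided single-outlier p-value for statistic G at cohort size N."""
    if N < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    G = float(G)
    if G < 0:
        raise ValueError("G must be non-negative")
    gmax = (N - 1) / np.sqrt(N)
    G = min(G, gmax)  # numerical overshoot collapses to the algebraic maximum
    den = (N - 1) ** 2 - N * G ** 2
    if den <= 0:
        return 0.0
    t = np.sqrt(N * (N - 2) * G ** 2 / den)
    return float(min(1.0, 2 * N * stats.t.sf(t, N - 2)))


def scan(beta: pd.DataFrame, params: ScanParams | None = None,
         manifest: pd.DataFrame | None = None) -> ScanResult:
    """Scan every probe for a single methylation outlier.

    ``beta`` is the filtered, batch-corrected probes x samples matrix.
    If a manifest is given, calls carry its SNP flags (``snp_flagged``).
    """
    params = params or ScanParams()
    X = beta.to_numpy(dtype=float)
    n_probes, N = X.shape
    if N < 3:
        raise ValueError("cohort must have at least 3 samples")
    n_tests = params.n_tests if params.n_tests is not None else n_probes

    complete = ~np.isnan(X).any(axis=1)
    sd = np.full(n_probes, np.nan)
    sd[complete] = X[complete].std(axis=1, ddof=1)
    testable = complete & (sd > params.min_sd)

    mean = X[testable].mean(axis=1)
    dev = np.abs(X[testable] - mean[:, None])
    idx = dev.argmax(axis=1)
    rows = np.arange(testable.sum())
    G = dev[rows, idx] / sd[testable]

    # vectorised t inversion
    gmax = (N - 1) / np.sqrt(N)
    Gc = np.minimum(G, gmax)
    den = (N - 1) ** 2 - N * Gc ** 2
    p_raw = np.zeros_like(Gc)
    pos = den > 0
    t = np.sqrt(N * (N - 2) * Gc[pos] ** 2 / den[pos])
    p_raw[pos] = np.minimum(1.0, 2 * N * stats.t.sf(t, N - 2))
    p_bonf = np.minimum(1.0, p_raw * n_tests)

    called = p_bonf < params.alpha_corrected
    probe_ids = beta.index.to_numpy()[testable][called]
    call_idx = idx[called]
    out_beta = X[testable][called][np.arange(called.sum()), call_idx]
    mean_called = mean[called]
    delta = (out_beta - (mean_called * N - out_beta) / (N - 1))
    calls = pd.DataFrame({
        "probe_id": probe_ids,
        "sample_id": beta.columns.to_numpy()[call_idx],
        "beta": out_beta,
        "delta_beta": delta,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "grubbs_g": G[called],
        "p_raw": p_raw[called],
        "p_bonf": p_bonf[called],
        "snp_flagged": False,
    }, columns=CALL_COLUMNS)

    if manifest is not None:
        mani = manifest.set_index("IlmnID")
        snp = ((mani["Probe_SNPs"].fillna("").astype(str) != "")
               | (mani["Probe_SNPs_10"].fillna("").astype(str) != ""))
        calls["snp_flagged"] = snp.reindex(calls["probe_id"]).fillna(False).to_numpy()

    provenance = {
        "n_probes_input": int(n_probes),
        "n_probes_tested": int(testable.sum()),
        "n_probes_skipped": int(n_probes - testable.sum()),
        "cohort_size": int(N),
        "n_tests": int(n_tests),
        "alpha_corrected": params.alpha_corrected,
    }
    return ScanResult(calls=calls.reset_index(drop=True), provenance=provenance)


def snp_filter(result: ScanResult,
               manifest: pd.DataFrame) -> tuple[ScanResult, ScanResult]:
    """Split calls into (kept, removed) by the manifest's SNP-probe flags.

    A call is removed when its probe has a non-empty ``Probe_SNPs`` or
    ``Probe_SNPs_10`` entry (probes whose β may reflect sequence
    variation rather than methylation).
    """
    mani = manifest.set_index("IlmnID")
    missing = set(result.calls["probe_id"]) - set(mani.index)
    if missing:
        raise ValueError(f"called probes absent from manifest: {sorted(missing)[:5]!r}")
    snp = ((mani["Probe_SNPs"].fillna("").astype(str) != "")
           | (mani["Probe_SNPs_10"].fillna("").astype(str) != ""))
    flagged = snp.reindex(result.calls["probe_id"]).to_numpy(dtype=bool)
    calls = result.calls.copy()
    calls["snp_flagged"] = flagged

    kept_calls = calls[~flagged].reset_index(drop=True)
    removed_calls = calls[flagged].reset_index(drop=True)
    retention = {}
    for direction in ("hyper", "hypo"):
        n_dir = int((calls["direction"] == direction).sum())
        n_kept = int((kept_calls["direction"] == direction).sum())
        retention[direction] = n_kept / n_dir if n_dir else np.nan
    prov = dict(result.provenance)
    prov["snp_retention"] = retention
    kept = ScanResult(calls=kept_calls, provenance=prov)
    removed = ScanResult(calls=removed_calls,
                         provenance={**result.provenance, "snp_removed": True})
    return kept, removed


def summarize_deltas(result: ScanResult) -> dict[str, dict[str, float]]:
    """Per-direction mean/SD of β and Δβ (sample SD; absent if n < 2)."""
    out: dict[str, dict[str, float]] = {}
    for direction in ("hyper", "hypo"):
        sub = result.calls[result.calls["direction"] == direction]
        if len(sub) == 0:
            continue
        entry = {
            "n": int(len(sub)),
            "beta_mean": float(sub["beta"].mean()),
            "delta_mean": float(sub["delta_beta"].mean()),
        }
        if len(sub) >= 2:
            entry["beta_sd"] = float(sub["beta"].std(ddof=1))
            entry["delta_sd"] = float(sub["delta_beta"].std(ddof=1))
        out[direction] = entry
    return out
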