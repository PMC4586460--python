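"""Parametric empirical-Bayes batch correction (ComBat-style).

Location/scale model: for probe g in batch i, the standardized value
Z = (Y - α̂_g) / σ̂_g is assumed N(γ_ig, δ²_ig), with a normal prior on
the batch locations γ and an inverse-gamma prior on the batch variances
δ².  Hyperparameters are estimated by method of moments across probes
within each batch, and the posterior (γ*, δ²*) solved by the standard
fixed-point iteration.  The adjusted value is
``σ̂_g / δ*_ig · (Z - γ*_ig) + α̂_g``.

No covariates are modelled; correction is applied directly on β values
with [0, 1] clipping afterwards (clips are counted).  Probes with zero
pooled variance are passed through uncorrected and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONV_TOL = 1e-4
MAX_ITER = 500


@dataclass
class BatchModel:
    batches: list[str]
    samples_per_batch: dict[str, list[str]]
    grand_mean: np.ndarray          # per probe
    var_pooled: np.ndarray          # per probe
    gamma_hat: dict[str, np.ndarray]
    gamma_star: dict[str, np.ndarray]
    delta_hat: dict[str, np.ndarray]
    delta_star: dict[str, np.ndarray]
    priors: dict[str, dict[str, float]]
    zero_variance: np.ndarray       # boolean per probe, passed through
    probe_index: pd.Index
    identity: bool = False
    n_clipped: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "batches": self.batches,
            "identity": self.identity,
            "priors": self.priors,
            "n_zero_variance": int(self.zero_variance.sum()),
        }


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def fit_combat(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
               batch_col: str = "batch") -> BatchModel:
    """Fit the EB location/scale model on a probes x samples β matrix.

    One batch yields an identity model.  A batch with a single sample is
    an error (its variance is undefined).
    """
    sheet = sample_sheet.set_index("Sample_ID")
    missing = [s for s in beta.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing[:5]!r}")
    batch_of = sheet.loc[beta.columns, batch_col]
    batches = sorted(batch_of.unique())
    members = {b: list(beta.columns[(batch_of == b).to_numpy()]) for b in batches}

    X = beta.to_numpy(dtype=float)
    n_probes, n_arr = X.shape
    if len(batches) < 2:
        return BatchModel(batches=batches, samples_per_batch=members,
                          grand_mean=np.zeros(n_probes),
                          var_pooled=np.ones(n_probes),
                          gamma_hat={}, gamma_star={}, delta_hat={},
                          delta_star={}, priors={},
                          zero_variance=np.zeros(n_probes, dtype=bool),
                          probe_index=beta.index, identity=True)
    for b in batches:
        if len(members[b]) < 2:
            raise ValueError(f"batch {b!r} has a single sample; "
                             "its variance is undefined")

    cols = {b: np.asarray([beta.columns.get_loc(s) for s in members[b]])
            for b in batches}
    n_b = {b: len(members[b]) for b in batches}

    batch_means = {b: X[:, cols[b]].mean(axis=1) for b in batches}
    grand_mean = sum(n_b[b] * batch_means[b] for b in batches) / n_arr
    fitted = np.empty_like(X)
    for b in batches:
        fitted[:, cols[b]] = batch_means[b][:, None]
    resid = X - fitted
    # pooled residual variance with 1/n denominator (reference convention)
    var_pooled = (resid ** 2).mean(axis=1)
    zero_var = var_pooled <= 0
    sigma = np.sqrt(np.where(zero_var, 1.0, var_pooled))

    Z = (X - grand_mean[:, None]) / sigma[:, None]

    gamma_hat, delta_hat = {}, {}
    gamma_star, delta_star = {}, {}
    priors: dict[str, dict[str, float]] = {}
    for b in batches:
        Zb = Z[:, cols[b]]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        gamma_hat[b], delta_hat[b] = g_hat, d_hat
        g_bar = float(g_hat.mean())
        t2 = float(g_hat.var(ddof=1))
        m = float(d_hat.mean())
        s2 = float(d_hat.var(ddof=1))
        # degenerate across-probe spread: inverse-gamma moments undefined,
        # fall back to no shrinkage of the variances
        shrink_var = s2 > 1e-300
        a = (2 * s2 + m ** 2) / s2 if shrink_var else np.inf
        bb = (m * s2 + m ** 3) / s2 if shrink_var else np.inf
        priors[b] = {"gamma_bar": g_bar, "t2": t2, "a": a, "b": bb}

        g_old, d_old = g_hat.copy(), d_hat.copy()
        n = n_b[b]
        for _ in range(MAX_ITER):
            g_new = _postmean(g_hat, g_bar, n, d_old, t2)
            if shrink_var:
                sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
                d_new = _postvar(sum2, n, a, bb)
            else:
                d_new = d_hat
            change = max(np.max(np.abs(g_new - g_old)
                                / np.maximum(np.abs(g_old), 1e-12)),
                         np.max(np.abs(d_new - d_old)
                                / np.maximum(np.abs(d_old), 1e-12)))
            g_old, d_old = g_new, d_new
            if change < CONV_TOL:
                break
        gamma_star[b], delta_star[b] = g_old, d_old

    return BatchModel(batches=batches, samples_per_batch=members,
                      grand_mean=grand_mean, var_pooled=var_pooled,
                      gamma_hat=gamma_hat, gamma_star=gamma_star,
                      delta_hat=delta_hat, delta_star=delta_star,
                      priors=priors, zero_variance=zero_var,
                      probe_index=beta.index)


def apply_combat(beta: pd.DataFrame, model: BatchModel,
                 sample_sheet: pd.DataFrame | None = None,
                 batch_col: str = "batch",
                 clip: bool = True) -> pd.DataFrame:
    """Adjust a β matrix with a fitted model; output clipped to [0, 1]."""
    if model.identity:
        return beta.copy()
    if not beta.index.equals(model.probe_index):
        raise ValueError("β matrix probes differ from the fitted model")
    sample_to_batch: dict[str, str] = {}
    for b, ss in model.samples_per_batch.items():
        for s in ss:
            sample_to_batch[s] = b
    if sample_sheet is not None:
        sheet = sample_sheet.set_index("Sample_ID")
        for s in beta.columns:
            if s in sheet.index:
                sample_to_batch[s] = sheet.loc[s, batch_col]
    unknown = [s for s in beta.columns if s not in sample_to_batch]
    if unknown:
        raise ValueError(f"samples with unknown batch: {unknown[:5]!r}")
    bad = [s for s in beta.columns if sample_to_batch[s] not in model.gamma_star]
    if bad:
        raise ValueError(f"samples in a batch the model was not fitted on: {bad[:5]!r}")

    X = beta.to_numpy(dtype=float)
    sigma = np.sqrt(np.where(model.zero_variance, 1.0, model.var_pooled))
    Z = (X - model.grand_mean[:, None]) / sigma[:, None]
    out = np.empty_like(X)
    for j, s in enumerate(beta.columns):
        b = sample_to_batch[s]
        out[:, j] = (Z[:, j] - model.gamma_star[b]) / np.sqrt(model.delta_star[b])
    out = out * sigma[:, None] + model.grand_mean[:, None]
    out[model.zero_variance] = X[model.zero_variance]
    if clip:
        clipped = int(((out < 0) | (out > 1)).sum())
        model.n_clipped = clipped
        out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def correct_batches(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
                    batch_col: str = "batch",
                    clip: bool = True) -> tuple[pd.DataFrame, BatchModel]:
    """Fit + apply in one step."""
    model = fit_combat(beta, sample_sheet, batch_col=batch_col)
    return apply_combat(beta, model, clip=clip), model
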