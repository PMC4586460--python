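"""Empirical-Bayes batch correction: identity, shift removal, oracle."""

import numpy as np
import pandas as pd
import pytest

from episcan.combat import apply_combat, correct_batches, fit_combat

from conftest import make_beta

# Fixture matrix (6 probes x 8 samples, batches of 4+4, +0.1 shift on the
# second batch, values clipped to [0.01, 0.99]); generated once with
# numpy default_rng(42).  The expected output was computed independently
# with the reference empirical-Bayes implementation (Bioconductor
# sva::ComBat 3.50.0, par.prior=TRUE, no covariates) and frozen here.
FIXTURE = np.array([
    [0.72555686, 0.70335271, 0.71832478, 0.67651264, 0.86313474, 0.85805444, 0.82246637, 0.87552690],
    [0.47447822, 0.40813813, 0.46954029, 0.40315862, 0.59502527, 0.54860646, 0.54185963, 0.51705627],
    [0.84800540, 0.77915186, 0.76546194, 0.76927166, 0.91349380, 0.90515054, 0.90751497, 0.90841939],
    [0.76497680, 0.63757367, 0.63228229, 0.61720579, 0.78869339, 0.81434304, 0.75219705, 0.71588660],
    [0.13411782, 0.20787152, 0.21250459, 0.20249959, 0.24206639, 0.28694994, 0.28117617, 0.28627631],
    [0.92406932, 0.89167766, 0.91444356, 0.88387683, 0.99000000, 0.99000000, 0.90764009, 0.96451432],
])
SVA_ORACLE = np.array([
    [0.788730114702, 0.770796214959, 0.782888892995, 0.749117966991, 0.795176844257, 0.790301943245, 0.756152737360, 0.807067980083],
    [0.524717205749, 0.471064436168, 0.520723640063, 0.467037243327, 0.539358271918, 0.491640429073, 0.484704796274, 0.459207314295],
    [0.890782277868, 0.838494507122, 0.828098306284, 0.830991424462, 0.857525862479, 0.846911608321, 0.849919622586, 0.851070221271],
    [0.805483884406, 0.705080353937, 0.700910332435, 0.689028883240, 0.730058621384, 0.757946533805, 0.690377491113, 0.650898475451],
    [0.190312785798, 0.248408126777, 0.252057567202, 0.244176693346, 0.194489353480, 0.244216603690, 0.237819739390, 0.243470270465],
    [0.955596156609, 0.927680072974, 0.947300393801, 0.920957094210, 0.952611746892, 0.952611746892, 0.879687368778, 0.930045824526],
])


def _sheet(samples, batches):
    return pd.DataFrame({"Sample_ID": samples, "batch": batches})


def test_matches_reference_empirical_bayes_implementation():
    samples = [f"s{i}" for i in range(8)]
    beta = make_beta(FIXTURE, samples=samples)
    sheet = _sheet(samples, ["b1"] * 4 + ["b2"] * 4)
    corrected, _ = correct_batches(beta, sheet, clip=False)
    np.testing.assert_allclose(corrected.to_numpy(), SVA_ORACLE, atol=1e-6)


def test_single_batch_is_identity():
    rng = np.random.default_rng(0)
    beta = make_beta(rng.uniform(0, 1, (20, 6)))
    sheet = _sheet(list(beta.columns), ["b1"] * 6)
    corrected, model = correct_batches(beta, sheet)
    assert model.identity
    np.testing.assert_allclose(corrected.to_numpy(), beta.to_numpy(), atol=1e-10)


def test_pure_additive_shift_removed():
    # identical per-sample noise across probes: the batch deviation is
    # constant across probes, so shrinkage has no target spread and the
    # planted shift is removed exactly
    rng = np.random.default_rng(1)
    n = 100
    base = rng.uniform(0.3, 0.7, (50, 1))
    noise = 0.02 * rng.standard_normal(2 * n)
    X = base + noise[None, :]
    X[:, n:] += 0.1
    samples = [f"s{i}" for i in range(2 * n)]
    beta = make_beta(X, samples=samples)
    sheet = _sheet(samples, ["b1"] * n + ["b2"] * n)
    corrected, _ = correct_batches(beta, sheet, clip=False)
    diff = corrected.iloc[:, :n].mean(axis=1) - corrected.iloc[:, n:].mean(axis=1)
    assert np.abs(diff).max() < 1e-6


def test_batch_labels_no_longer_predict_beta_after_correction():
    # sample size chosen so chance correlation of pure noise with the
    # labels sits well below the 0.05 bar (null sd = 1/sqrt(2n) = 0.01)
    rng = np.random.default_rng(2)
    n = 5000
    X = rng.uniform(0.3, 0.7, (50, 1)) + 0.02 * rng.standard_normal((50, 2 * n))
    X[:, n:] += 0.15
    samples = [f"s{i}" for i in range(2 * n)]
    beta = make_beta(X, samples=samples)
    sheet = _sheet(samples, ["b1"] * n + ["b2"] * n)
    corrected, _ = correct_batches(beta, sheet, clip=False)
    labels = np.r_[np.zeros(n), np.ones(n)]
    Y = corrected.to_numpy()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    lc = labels - labels.mean()
    r = (Yc @ lc) / (np.linalg.norm(Yc, axis=1) * np.linalg.norm(lc))
    assert np.abs(r).max() < 0.05


def test_overall_probe_mean_approximately_preserved():
    rng = np.random.default_rng(3)
    X = rng.uniform(0.2, 0.8, (100, 1)) + 0.03 * rng.standard_normal((100, 20))
    X[:, 10:] += 0.05
    samples = [f"s{i}" for i in range(20)]
    beta = make_beta(X, samples=samples)
    sheet = _sheet(samples, ["b1"] * 10 + ["b2"] * 10)
    corrected, _ = correct_batches(beta, sheet, clip=False)
    drift = corrected.mean(axis=1) - beta.mean(axis=1)
    assert np.abs(drift).max() < 5e-3


def test_values_clipped_to_unit_interval_and_counted():
    rng = np.random.default_rng(4)
    X = np.clip(rng.uniform(0.0, 0.06, (30, 10))
                + np.r_[np.zeros(5), 0.2 * np.ones(5)][None, :], 0, 1)
    samples = [f"s{i}" for i in range(10)]
    beta = make_beta(X, samples=samples)
    sheet = _sheet(samples, ["b1"] * 5 + ["b2"] * 5)
    corrected, model = correct_batches(beta, sheet, clip=True)
    assert corrected.to_numpy().min() >= 0.0
    assert corrected.to_numpy().max() <= 1.0
    unclipped, _ = correct_batches(beta, sheet, clip=False)
    expected = int(((unclipped.to_numpy() < 0) | (unclipped.to_numpy() > 1)).sum())
    assert model.n_clipped == expected


def test_single_sample_batch_rejected():
    beta = make_beta(np.random.default_rng(5).uniform(0, 1, (10, 3)))
    sheet = _sheet(list(beta.columns), ["b1", "b1", "b2"])
    with pytest.raises(ValueError, match="single sample"):
        fit_combat(beta, sheet)


def test_unknown_batch_sample_rejected():
    rng = np.random.default_rng(6)
    beta = make_beta(rng.uniform(0, 1, (10, 6)))
    sheet = _sheet(list(beta.columns), ["b1"] * 3 + ["b2"] * 3)
    model = fit_combat(beta, sheet)
    other = make_beta(rng.uniform(0, 1, (10, 2)), samples=["x1", "x2"])
    other.index = beta.index
    with pytest.raises(ValueError, match="unknown batch"):
        apply_combat(other, model)


def test_zero_variance_probe_passes_through():
    rng = np.random.default_rng(7)
    X = rng.uniform(0.2, 0.8, (10, 8))
    X[0] = 0.5
    samples = [f"s{i}" for i in range(8)]
    beta = make_beta(X, samples=samples)
    sheet = _sheet(samples, ["b1"] * 4 + ["b2"] * 4)
    corrected, model = correct_batches(beta, sheet)
    assert model.zero_variance[0]
    np.testing.assert_allclose(corrected.iloc[0].to_numpy(), 0.5, atol=1e-12)


def test_shrinkage_tightens_with_more_samples():
    # |gamma* - gamma_hat| shrinks as the within-batch sample count grows
    rng = np.random.default_rng(8)
    gaps = []
    for n in (5, 20, 80):
        X = rng.uniform(0.3, 0.7, (100, 1)) \
            + 0.05 * rng.standard_normal((100, 2 * n))
        X[:, n:] += 0.1 * rng.standard_normal(100)[:, None]  # probe-specific shift
        samples = [f"s{i}" for i in range(2 * n)]
        beta = make_beta(X, samples=samples)
        sheet = _sheet(samples, ["b1"] * n + ["b2"] * n)
        model = fit_combat(beta, sheet)
        gaps.append(np.abs(model.gamma_star["b2"] - model.gamma_hat["b2"]).mean())
    assert gaps[0] > gaps[1] > gaps[2]
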