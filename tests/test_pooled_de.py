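"""NB-GLM contrast: TMM, fitting vs statsmodels, dispersion, LRT, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from brute import brute_tmm
from nilseq.errors import ValidationError
from nilseq.pooled_de import (
    adjust_fdr,
    build_design,
    call_de,
    cpm,
    estimate_dispersion,
    fit_nb_glm,
    lrt_qtl,
    run_de,
    tmm_factors,
)


def design_30():
    units = [f"HIF{i}" for i in range(1, 6)]
    rows = [
        (f"{u}_t{t}_{p}", u, t, 1 if p == "A" else 0)
        for u in units for t in (15, 25, 35) for p in "AB"
    ]
    return pd.DataFrame(rows, columns=["sample_id", "unit", "timepoint", "qtl_status"])


def simulate_null(rng, n_genes, samples, phi):
    units = sorted(samples["unit"].unique())
    uidx = {u: i for i, u in enumerate(units)}
    tidx = {t: i for i, t in enumerate(sorted(samples["timepoint"].unique()))}
    base = rng.normal(np.log(100), 1.0, n_genes)
    ue = rng.normal(0, 0.1, (n_genes, len(uidx)))
    te = rng.normal(0, 0.2, (n_genes, len(tidx)))
    logmu = np.stack(
        [base + ue[:, uidx[r.unit]] + te[:, tidx[r.timepoint]]
         for r in samples.itertuples()],
        axis=1,
    )
    mu = np.exp(logmu)
    if phi > 0:
        return rng.poisson(rng.gamma(1 / phi, phi * mu)), mu
    return rng.poisson(mu), mu


# ---------------------------------------------------------------------------
# TMM

def test_tmm_identical_columns_unity():
    counts = pd.DataFrame({"a": [5, 10, 20], "b": [5, 10, 20], "c": [5, 10, 20]})
    assert np.allclose(tmm_factors(counts), 1.0)


def test_tmm_pure_depth_scaling_unity():
    col = np.array([3, 11, 40, 7, 120, 55, 9, 14, 2, 31])
    counts = pd.DataFrame({"a": col, "b": 2 * col})
    assert np.allclose(tmm_factors(counts), 1.0, atol=1e-10)


def test_tmm_matches_brute_force_oracle(rng):
    mat = rng.poisson(rng.gamma(2.0, 40.0, size=(100, 4)))
    mat[:5, 1] *= 10  # a handful of inflated genes in one sample
    counts = pd.DataFrame(mat, columns=list("abcd"))
    ours = tmm_factors(counts).to_numpy()
    oracle = brute_tmm([list(mat[:, j]) for j in range(4)])
    assert np.allclose(ours, oracle, atol=1e-6)
    # geometric mean one, gene-order invariance
    assert np.isclose(np.exp(np.mean(np.log(ours))), 1.0)
    shuffled = counts.sample(frac=1.0, random_state=0)
    assert np.allclose(tmm_factors(shuffled).to_numpy(), ours)


def test_tmm_rejects_all_zero_sample():
    counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
    with pytest.raises(ValidationError, match="all-zero"):
        tmm_factors(counts)


# ---------------------------------------------------------------------------
# GLM fitting

def test_intercept_only_fit_recovers_arithmetic_mean(rng):
    y = rng.poisson(30.0, size=12)
    fit = fit_nb_glm(y, np.ones((12, 1)), phi=0.2)
    assert fit.fitted[0] == pytest.approx(y.mean(), rel=1e-6)


def test_fit_matches_statsmodels_oracle(rng):
    n, phi = 8, 0.15
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    offset = np.log(rng.uniform(0.8e6, 1.2e6, n))
    mu = np.exp(offset - np.log(1e6) + np.log(50) + 0.8 * X[:, 1] - 0.5 * X[:, 2])
    y = rng.poisson(rng.gamma(1 / phi, phi * mu))
    ours = fit_nb_glm(y, X, phi, offset=offset)
    ref = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=phi), offset=offset
    ).fit()
    assert np.allclose(ours.coef, ref.params, atol=1e-5)
    assert ours.loglik == pytest.approx(ref.llf, abs=1e-4)


def test_poisson_limit_matches_poisson_glm(rng):
    n = 10
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.poisson(20.0, size=n)
    ours = fit_nb_glm(y, X, phi=0.0)
    ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    assert np.allclose(ours.coef, ref.params, atol=1e-6)
    assert ours.deviance == pytest.approx(ref.deviance, rel=1e-6)


def test_saturated_design_zero_deviance(rng):
    y = rng.poisson(15.0, size=6) + 1
    X = np.eye(6)
    fit = fit_nb_glm(y, X, phi=0.1)
    assert fit.deviance == pytest.approx(0.0, abs=1e-6)


def test_rank_deficient_design_rejected():
    X = np.column_stack([np.ones(6), np.ones(6)])
    with pytest.raises(ValidationError, match="rank"):
        fit_nb_glm(np.arange(6), X, phi=0.1)


# ---------------------------------------------------------------------------
# dispersion

def test_dispersion_poisson_data_near_zero(rng):
    samples = design_30()
    Xf, _, _ = build_design(samples)
    Y, _ = simulate_null(rng, 500, samples, phi=0.0)
    phi = estimate_dispersion(Y, Xf, mode="common")
    assert 0.0 <= phi < 0.01


def test_dispersion_recovery_and_tagwise_shrinkage(rng):
    samples = design_30()
    Xf, _, _ = build_design(samples)
    Y, _ = simulate_null(rng, 500, samples, phi=0.2)
    common = estimate_dispersion(Y, Xf, mode="common")
    assert common == pytest.approx(0.2, abs=0.06)
    tag = estimate_dispersion(Y[:50], Xf, mode="tagwise", prior_weight=10.0)
    assert tag.shape == (50,)
    assert (tag >= 0).all()
    # shrinkage keeps tagwise values near the common estimate
    assert np.quantile(np.abs(tag - common), 0.9) < 0.25


def test_non_identifiable_design_rejected(rng):
    Y = rng.poisson(10.0, size=(5, 4))
    X = np.column_stack([np.ones(4), np.eye(4)])[:, :5]
    with pytest.raises(ValidationError):
        estimate_dispersion(Y, X)


# ---------------------------------------------------------------------------
# LRT and FDR

def test_constant_gene_has_zero_statistic():
    samples = design_30()
    Xf, Xr, _ = build_design(samples)
    Y = np.full((1, 30), 17)
    res = lrt_qtl(Y, Xf, Xr, phi=0.2)
    assert res["lrt_stat"].iloc[0] == pytest.approx(0.0, abs=1e-6)
    assert res["pvalue"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_lrt_statistics_are_nonnegative(rng):
    samples = design_30()
    Xf, Xr, _ = build_design(samples)
    Y, _ = simulate_null(rng, 200, samples, phi=0.3)
    res = lrt_qtl(Y, Xf, Xr, phi=0.3)
    assert (res["lrt_stat"] >= 0).all()
    assert res["pvalue"].between(0, 1).all()


def test_bh_hand_worked_example():
    padj = adjust_fdr([0.01, 0.02, 0.03, 0.04], method="bh")
    assert np.allclose(padj, 0.04)


@pytest.mark.parametrize("method", ["bh", "hochberg"])
def test_fdr_equal_pvalues_and_singleton(method):
    assert np.allclose(adjust_fdr([0.2, 0.2, 0.2], method=method), 0.2)
    assert adjust_fdr([0.031], method=method)[0] == pytest.approx(0.031)


@pytest.mark.parametrize("method", ["bh", "hochberg"])
def test_fdr_monotone_and_consistent_with_procedure(method, rng):
    p = np.sort(rng.uniform(size=40))
    adj = adjust_fdr(p, method=method)
    assert (np.diff(adj) >= -1e-12).all()      # order preserving on sorted p
    assert (adj >= p - 1e-12).all()
    # thresholding adjusted values reproduces the step-up rejection set
    m, alpha = len(p), 0.25
    if method == "bh":
        crossed = np.flatnonzero(p <= (np.arange(1, m + 1) / m) * alpha)
    else:
        crossed = np.flatnonzero(p <= alpha / (m - np.arange(1, m + 1) + 1))
    k = crossed.max() + 1 if crossed.size else 0
    assert set(np.flatnonzero(adj <= alpha)) == set(range(k))
    # idempotent where adjusted values are already maximally tied
    tied = adjust_fdr([0.01, 0.02, 0.03, 0.04], method=method)
    assert np.allclose(adjust_fdr(tied, method=method), tied)


def test_fdr_rejects_out_of_range():
    with pytest.raises(ValidationError, match="0, 1"):
        adjust_fdr([0.5, 1.2])


def test_call_de_strict_threshold():
    df = pd.DataFrame({"padj": [0.009, 0.01, 0.5]})
    out = call_de(df, alpha=0.01)
    assert list(out["is_de"]) == [True, False, False]
    assert call_de(pd.DataFrame({"padj": []})).empty


def test_cpm_definition_and_invariance(rng):
    counts = pd.DataFrame({"a": [10, 999_990], "b": [500, 500]})
    vals = cpm(counts)
    assert vals.loc[0, "a"] == pytest.approx(10.0)
    assert np.allclose(vals.sum(axis=0), 1e6)
    doubled = cpm(counts.assign(a=counts["a"] * 2))
    assert np.allclose(doubled["a"], vals["a"])


# ---------------------------------------------------------------------------
# power under the planted effect

def test_causal_gene_power_across_replicates():
    """With the default planted effect the causal gene is called DE in
    nearly every replicate of a 500-background-gene experiment."""
    import dataclasses

    from nilseq.magic_sim import SimConfig, simulate_dataset

    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = SimConfig(seed=3000 + rep, n_genes=500, n_decoy_sites=0,
                        n_ril=800, max_ril_batches=12, n_plates_per_class=1)
        ds = simulate_dataset(cfg)
        out = run_de(ds.counts, ds.samples, alpha=0.01)
        causal = ds.truth["causal_contig"]
        if causal in out.results.index and bool(out.results.loc[causal, "is_de"]):
            hits += 1
    assert hits >= int(np.ceil(0.95 * n_rep))
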