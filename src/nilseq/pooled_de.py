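"""Pooled QTL-positive vs QTL-negative differential expression.

The contrast is the heart of the multi-NIL design: every sample is labelled
with a *unit* (HIF family or parent cultivar), a *timepoint* (15/25/35 days
post-anthesis) and a binary *QTL status* (pool A carries the dormancy donor
allele, pool B does not). Each gene's counts are fitted to a negative
binomial generalized linear model with log link,

    log mu = offset + unit + timepoint + beta_qtl * status,

where the offset is the log effective library size (raw total x TMM factor).
The QTL effect is tested with a likelihood-ratio test of the full model
against the reduced model without the status term (chi-square, 1 df), and
p-values are adjusted for multiple testing (Benjamini-Hochberg by default,
Hochberg step-up optionally). Genes with adjusted p strictly below alpha
(default 0.01) are called differentially expressed.

The NB fitting (IRLS at fixed dispersion), TMM normalization and the
Cox-Reid adjusted profile-likelihood dispersion estimator are implemented
here; statsmodels is used only for the multiple-testing step and, in the
test suite, as an independent GLM oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# normalization

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million reads, per sample (raw library totals)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValidationError(f"cpm: zero library total in samples {bad}")
    return counts / lib * 1e6


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_o, p_r = obs / lib_obs, ref / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) precision weights
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any() or w[keep2].sum() <= 0:
        return 1.0
    log2f = np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2])
    return float(2.0 ** log2f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose upper-quartile/total ratio is
    closest to the mean such ratio. Per pair, genes with zero count in
    either sample are excluded; the stated fractions of extreme M and A
    values are trimmed from each tail and the remaining M values averaged
    with precision weights.
    """
    if counts.shape[1] < 2:
        raise ValidationError("tmm_factors: need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = list(counts.columns[lib <= 0])
        raise ValidationError(f"tmm_factors: all-zero samples {bad}")
    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_library_sizes(
    counts: pd.DataFrame, norm: str = "tmm"
) -> pd.Series:
    """Raw library totals times TMM factors (or raw totals for 'libsize')."""
    lib = counts.sum(axis=0).astype(float)
    if norm == "tmm":
        return lib * tmm_factors(counts)
    if norm == "libsize":
        return lib
    raise ValidationError(f"norm: unknown method {norm!r}")


# ---------------------------------------------------------------------------
# NB likelihood and GLM fitting

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Elementwise NB2 log-likelihood (Poisson at phi == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    if phi <= 0:
        return y * np.log(mu) - mu - special.gammaln(y + 1)
    r = 1.0 / phi
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-observation NB deviance contribution (Poisson at phi == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    if phi <= 0:
        return 2.0 * (term - (y - mu))
    return 2.0 * (term - (y + 1.0 / phi) * np.log((1.0 + phi * y) / (1.0 + phi * mu)))


@dataclass
class NBFitResult:
    """One gene's fitted NB GLM at fixed dispersion."""

    coef: np.ndarray
    fitted: np.ndarray
    deviance: float
    loglik: float
    converged: bool


def _check_design(X: np.ndarray, n_obs: int) -> None:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != n_obs:
        raise ValidationError(f"design: shape {X.shape} incompatible with {n_obs} samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design: matrix is rank-deficient")


def fit_nb_glm_many(
    Y: np.ndarray,
    X: np.ndarray,
    phi: float | np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of the same design to many genes at once.

    Y is (genes x samples); phi is a scalar or per-gene array. Returns
    (coefs (G,p), fitted (G,n), deviance (G,), loglik (G,), converged (G,)).
    Convergence is a relative deviance change below ``tol``; non-convergence
    is flagged, never raised.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    _check_design(X, n)
    p = X.shape[1]
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()
    if (phi_arr < 0).any():
        raise ValidationError("phi: dispersion must be >= 0")

    mu = np.maximum(Y, 0.0) + 0.5
    eta = np.log(mu)
    dev = np.array([nb_deviance(Y[g], mu[g], phi_arr[g]).sum() for g in range(G)])
    converged = np.zeros(G, dtype=bool)
    beta = np.zeros((G, p))
    for _ in range(max_iter):
        W = mu / (1.0 + phi_arr[:, None] * mu)  # (G, n)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, W, z)
        # small ridge keeps near-singular weighted systems solvable
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        try:
            beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta = np.array(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(G)]
            )
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        new_dev = np.stack(
            [nb_deviance(Y[g], mu[g], phi_arr[g]).sum() for g in range(G)]
        )
        rel = np.abs(new_dev - dev) / (np.abs(new_dev) + 0.1)
        dev = new_dev
        converged = rel < tol
        if converged.all():
            break
    loglik = np.array([nb_loglik(Y[g], mu[g], phi_arr[g]).sum() for g in range(G)])
    dev = np.maximum(dev, 0.0)
    return beta, mu, dev, loglik, converged


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    phi: float,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBFitResult:
    """Fit one gene's NB GLM (log link, fixed dispersion) by IRLS."""
    beta, mu, dev, ll, conv = fit_nb_glm_many(
        np.asarray(y, dtype=float)[None, :], X, phi, offset, max_iter, tol
    )
    return NBFitResult(
        coef=beta[0],
        fitted=mu[0],
        deviance=float(dev[0]),
        loglik=float(ll[0]),
        converged=bool(conv[0]),
    )


# ---------------------------------------------------------------------------
# dispersion estimation

def _cox_reid_apl(
    Y: np.ndarray, X: np.ndarray, mu: np.ndarray, phi: float
) -> float:
    """Cox-Reid adjusted profile log-likelihood at fixed fitted means."""
    ll = nb_loglik(Y, mu, phi).sum()
    W = mu / (1.0 + phi * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X)
    XtWX += 1e-10 * np.eye(X.shape[1])[None, :, :]
    sign, logdet = np.linalg.slogdet(XtWX)
    return float(ll - 0.5 * logdet.sum())


def estimate_dispersion(
    counts: pd.DataFrame | np.ndarray,
    X: np.ndarray,
    mode: str = "common",
    offset: np.ndarray | None = None,
    prior_weight: float = 10.0,
    max_outer: int = 5,
    tol: float = 1e-3,
):
    """Estimate the NB dispersion phi under the full design.

    Common mode maximizes the Cox-Reid adjusted profile likelihood over a
    single phi, alternating GLM refits of the gene-wise means with scalar
    maximization over log phi. Tagwise mode additionally maximizes the
    per-gene likelihood (means fixed from the common fit) and shrinks the
    per-gene estimates toward the common value:

        phi_g = (prior_weight * phi_common + phi_g_ml) / (prior_weight + 1)

    Returns a float (common) or a per-gene ndarray (tagwise); always >= 0.
    """
    Y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(
        counts, dtype=float
    )
    Y = np.atleast_2d(Y)
    G, n = Y.shape
    X = np.asarray(X, dtype=float)
    _check_design(X, n)
    if n <= X.shape[1]:
        raise ValidationError(
            f"design: {n} samples cannot identify {X.shape[1]} coefficients plus dispersion"
        )

    phi = 0.1
    mu = None
    for _ in range(max_outer):
        _, mu, _, _, _ = fit_nb_glm_many(Y, X, phi, offset, max_iter=50)

        def neg_apl(log_phi: float) -> float:
            return -_cox_reid_apl(Y, X, mu, float(np.exp(log_phi)))

        res = optimize.minimize_scalar(
            neg_apl, bounds=(np.log(1e-8), np.log(10.0)), method="bounded",
            options={"xatol": 1e-4},
        )
        phi_new = float(np.exp(res.x))
        if abs(phi_new - phi) < tol * max(phi, 1e-2):
            phi = phi_new
            break
        phi = phi_new
    common = max(phi, 0.0)
    if common < 1e-6:
        common = 0.0 if common < 1e-7 else common
    if mode == "common":
        return common

    if mode != "tagwise":
        raise ValidationError(f"mode: unknown dispersion mode {mode!r}")
    # per-gene ML with means held at the common-fit values, then shrinkage
    _, mu, _, _, _ = fit_nb_glm_many(Y, X, common, offset, max_iter=50)
    phis = np.empty(G)
    for g in range(G):

        def neg_ll(log_phi: float, g: int = g) -> float:
            return -float(nb_loglik(Y[g], mu[g], float(np.exp(log_phi))).sum())

        res = optimize.minimize_scalar(
            neg_ll, bounds=(np.log(1e-8), np.log(10.0)), method="bounded",
            options={"xatol": 1e-3},
        )
        phis[g] = np.exp(res.x)
    shrunk = (prior_weight * common + phis) / (prior_weight + 1.0)
    return np.maximum(shrunk, 0.0)


# ---------------------------------------------------------------------------
# design matrices, LRT, FDR

def build_design(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full and reduced design matrices from a sample sheet.

    The sheet needs columns unit, timepoint and qtl_status. Unit and
    timepoint are treatment-coded (first level dropped); qtl_status is the
    final 0/1 column of the full design. Returns (X_full, X_reduced, names).
    """
    for col in ("unit", "timepoint", "qtl_status"):
        if col not in samples.columns:
            raise ValidationError(f"samples: missing column {col}")
    status = samples["qtl_status"].astype(int).to_numpy()
    if len(np.unique(status)) < 2 or min(np.bincount(status)) < 2:
        raise ValidationError("samples: need >= 2 samples per qtl_status level")
    parts = [np.ones((len(samples), 1))]
    names = ["intercept"]
    for col in ("unit", "timepoint"):
        levels = sorted(samples[col].astype(str).unique())
        for lev in levels[1:]:
            parts.append((samples[col].astype(str) == lev).to_numpy()[:, None].astype(float))
            names.append(f"{col}[{lev}]")
    X_red = np.hstack(parts)
    X_full = np.hstack(parts + [status[:, None].astype(float)])
    names_full = names + ["qtl_status"]
    _check_design(X_full, len(samples))
    return X_full, X_red, names_full


def lrt_qtl(
    counts: pd.DataFrame | np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    phi: float | np.ndarray,
    offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene likelihood-ratio test of the QTL (last full-design) column.

    The statistic 2*(ll_full - ll_reduced) is floored at zero and referred
    to chi-square with 1 df. Also reports the QTL coefficient as log2 fold
    change.
    """
    Y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(
        counts, dtype=float
    )
    Y = np.atleast_2d(Y)
    index = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(len(Y))
    beta_f, _, _, ll_f, conv_f = fit_nb_glm_many(Y, X_full, phi, offset)
    _, _, _, ll_r, conv_r = fit_nb_glm_many(Y, X_reduced, phi, offset)
    stat = np.maximum(2.0 * (ll_f - ll_r), 0.0)
    pval = stats.chi2.sf(stat, df=1)
    return pd.DataFrame(
        {
            "log2fc_qtl": beta_f[:, -1] / np.log(2.0),
            "lrt_stat": stat,
            "pvalue": pval,
            "converged": conv_f & conv_r,
        },
        index=index,
    )


def adjust_fdr(pvalues, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default) or Hochberg step-up."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("pvalues: must lie in [0, 1]")
    key = {"bh": "fdr_bh", "hochberg": "simes-hochberg"}.get(method)
    if key is None:
        raise ValidationError(f"method: unknown FDR method {method!r}")
    return multipletests(p, method=key)[1]


def call_de(results: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Flag genes with adjusted p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha: must be in (0, 1), got {alpha}")
    out = results.copy()
    out["is_de"] = out["padj"] < alpha if len(out) else pd.Series(dtype=bool)
    return out


@dataclass
class DEOutcome:
    """Results of the pooled contrast plus the fitting context."""

    results: pd.DataFrame  # gene-indexed: log2fc_qtl, lrt_stat, pvalue, padj, is_de
    norm_factors: pd.Series
    dispersion: float | np.ndarray
    dropped_genes: list = field(default_factory=list)


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.01,
    norm: str = "tmm",
    fdr: str = "bh",
    dispersion: str | float = "common",
) -> DEOutcome:
    """Full pooled DE contrast: normalize, estimate phi, LRT, adjust, call.

    ``dispersion`` may be 'common', 'tagwise' or a known numeric phi.
    Genes with zero counts in every sample are dropped before fitting and
    reported in ``dropped_genes``. Results are sorted by adjusted p.
    """
    if list(counts.columns) != list(samples["sample_id"]):
        samples = samples.set_index("sample_id").loc[list(counts.columns)].reset_index()
    nonzero = counts.sum(axis=1) > 0
    dropped = list(counts.index[~nonzero])
    counts_nz = counts.loc[nonzero]
    if counts_nz.empty:
        raise ValidationError("counts: no gene with a positive count")
    eff_lib = effective_library_sizes(counts_nz, norm=norm)
    factors = eff_lib / counts_nz.sum(axis=0)
    offset = np.log(eff_lib.to_numpy())
    X_full, X_red, _ = build_design(samples)
    if isinstance(dispersion, str):
        phi = estimate_dispersion(counts_nz, X_full, mode=dispersion, offset=offset)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValidationError("dispersion: phi must be >= 0")
    res = lrt_qtl(counts_nz, X_full, X_red, phi, offset)
    res["padj"] = adjust_fdr(res["pvalue"].to_numpy(), method=fdr)
    res = call_de(res, alpha=alpha)
    res = res.sort_values(["padj", "pvalue"], kind="mergesort")
    res.index.name = "gene"
    return DEOutcome(
        results=res[["log2fc_qtl", "lrt_stat", "pvalue", "padj", "is_de"]],
        norm_factors=factors.rename("norm_factor"),
        dispersion=phi,
        dropped_genes=dropped,
    )
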