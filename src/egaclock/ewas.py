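"""Single-CpG epigenome-wide association with gestational age.

Each probe's M-values are regressed on chronological GA (days) with
infant sex, infant race, and estimated latent factors as covariates; the
per-probe GA coefficient, its standard error, t statistic and two-sided p
are reported with Benjamini-Hochberg FDR q-values and a genomic-inflation
diagnostic.

Because the design matrix is shared by all probes (complete data), the
whole EWAS reduces to one batched least-squares solve, which keeps
array-scale runs fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fit_site_regression",
    "run_ewas",
    "bh_fdr",
    "genomic_inflation",
    "build_design",
    "InflationResult",
]

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


def _check_full_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [int(piv[i]) for i in range(len(diag)) if diag[i] <= tol]
        labels = [names[i] if names else str(i) for i in bad]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {labels}")


def fit_site_regression(y, X, ga_col: int = 1, names=None):
    """OLS of one probe's M-values on a design matrix; stats for the GA column.

    Returns ``(estimate, se, t, p)`` for column ``ga_col`` of ``X`` (the
    design must include an intercept). Two-sided p from the t distribution
    with ``n - rank(X)`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than design columns ({k})")
    _check_full_rank(X, names)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    df = n - k
    rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[ga_col, ga_col]))
    est = float(beta[ga_col])
    if se == 0.0:
        t = np.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), df)
    return est, se, float(t), float(p)


def build_design(samples: pd.DataFrame, factors=None, ga_col: str = "ga_days"):
    """Assemble the EWAS design matrix: intercept, GA, sex, race dummies,
    latent factor scores.

    Race is dummy-coded with the largest category as reference (the
    reference choice does not change the GA coefficient). Returns
    ``(X, names)`` with GA always at column 1.
    """
    n = len(samples)
    cols = [np.ones(n), samples[ga_col].to_numpy(dtype=float)]
    names = ["intercept", ga_col]
    if "sex" in samples.columns:
        levels = pd.unique(samples["sex"])
        if len(levels) > 1:
            ref = samples["sex"].value_counts().idxmax()
            for lev in sorted(set(map(str, levels)) - {str(ref)}):
                cols.append((samples["sex"].astype(str) == lev).to_numpy(float))
                names.append(f"sex[{lev}]")
    if "race" in samples.columns:
        levels = pd.unique(samples["race"].astype(str))
        if len(levels) > 1:
            ref = samples["race"].value_counts().idxmax()
            for lev in sorted(set(levels) - {str(ref)}):
                cols.append((samples["race"].astype(str) == lev).to_numpy(float))
                names.append(f"race[{lev}]")
    if factors is not None:
        scores = getattr(factors, "scores", factors)
        scores = np.asarray(scores, dtype=float)
        if scores.ndim == 1:
            scores = scores[:, None]
        for k in range(scores.shape[1]):
            cols.append(scores[:, k])
            names.append(f"latent{k + 1}")
    return np.column_stack(cols), names


def run_ewas(ds, factors=None, ga_col: str = "ga_days") -> pd.DataFrame:
    """Per-probe association of M-values with chronological GA.

    ``ds`` must be a QC'd :class:`~egaclock.preprocess.MethylationDataset`
    on the M scale. Zero-variance probes and probes whose complete-case
    sample count is too small are flagged (``flag`` column) rather than
    aborting the run. q-values are BH-FDR over all testable probes.
    """
    if ds.scale != "M":
        raise ValueError("run_ewas expects M-values; call ds.to_m() first")
    X_full, names = build_design(ds.samples, factors, ga_col)
    _check_full_rank(X_full, names)
    Y = ds.values.to_numpy(dtype=float)  # probes x samples
    n_probes = Y.shape[0]
    est = np.full(n_probes, np.nan)
    se = np.full(n_probes, np.nan)
    tstat = np.full(n_probes, np.nan)
    pval = np.full(n_probes, np.nan)
    nobs = np.zeros(n_probes, dtype=int)
    flag = np.array([""] * n_probes, dtype=object)

    complete = ~np.isnan(Y).any(axis=1)
    zero_var = np.nanstd(Y, axis=1) == 0
    flag[zero_var] = "zero_variance"

    def _batch(rows: np.ndarray, X: np.ndarray) -> None:
        if not rows.size:
            return
        n, k = X.shape
        df = n - k
        pinv = np.linalg.pinv(X)
        xtx_inv_ga = np.linalg.inv(X.T @ X)[1, 1]
        B = Y[rows] @ pinv.T  # rows x k
        resid = Y[rows] - B @ X.T
        rss = np.sum(resid**2, axis=1)
        s2 = rss / df
        se_r = np.sqrt(s2 * xtx_inv_ga)
        est[rows] = B[:, 1]
        se[rows] = se_r
        with np.errstate(divide="ignore", invalid="ignore"):
            t_r = np.where(se_r > 0, B[:, 1] / se_r, np.where(B[:, 1] != 0, np.inf, 0.0))
        tstat[rows] = t_r
        pval[rows] = 2.0 * stats.t.sf(np.abs(t_r), df)
        nobs[rows] = n

    batch_rows = np.where(complete & ~zero_var)[0]
    _batch(batch_rows, X_full)

    # probes with missing samples: complete-case fit, one at a time
    for i in np.where(~complete & ~zero_var)[0]:
        ok = ~np.isnan(Y[i])
        Xi = X_full[ok]
        if ok.sum() <= Xi.shape[1]:
            flag[i] = "insufficient_n"
            continue
        try:
            e, s, t, p = fit_site_regression(Y[i, ok], Xi, names=names)
        except ValueError:
            flag[i] = "rank_deficient"
            continue
        est[i], se[i], tstat[i], pval[i], nobs[i] = e, s, t, p, int(ok.sum())

    out = pd.DataFrame(
        {
            "probe_id": ds.manifest["probe_id"].to_numpy(),
            "estimate": est,
            "se": se,
            "t": tstat,
            "p": pval,
            "q": bh_fdr(pval),
            "n": nobs,
            "direction": np.sign(est),
            "flag": flag,
        }
    )
    hits = out[out["q"] < 0.05]
    out.attrs["n_hits"] = int(len(hits))
    out.attrs["n_hits_positive"] = int((hits["direction"] > 0).sum())
    out.attrs["n_hits_negative"] = int((hits["direction"] < 0).sum())
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving on input order.

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1. NaN entries get NaN q and do not count toward m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.empty(m)
    qs[order] = np.minimum(ranked, 1.0)
    q[ok] = qs
    return q


@dataclass
class InflationResult:
    """Genomic inflation factor with QQ-plot coordinates."""

    lam: float
    qq: pd.DataFrame  # columns: expected, observed (-log10 p)

    def __float__(self) -> float:
        return self.lam


def genomic_inflation(p) -> InflationResult:
    """Genomic inflation lambda: median association chi-square over its
    null expectation (median of chi-square_1, ~0.4549).

    p-values of exactly 0 are clamped to the smallest positive float with a
    warning. Also returns the -log10 QQ coordinates for plotting.
    """
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(p == 0):
        import warnings

        warnings.warn("p-values of 0 clamped for inflation estimate")
        p = np.clip(p, np.finfo(float).tiny, None)
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    srt = np.sort(p)
    n = srt.size
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed": -np.log10(srt),
        }
    )
    return InflationResult(lam=lam, qq=qq)
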