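"""Elastic-net gestational-age clock: split, select, fit, cross-validate.

The clock predicts chronological GA (days) from cord-blood methylation:
an 80/20 train/test split, per-training-set EWAS feature selection at
FDR 0.05, an elastic-net fit over the selected CpGs with sex, race and
latent factors entering unpenalized, five-fold cross-validated EGA
within training, removal of samples whose CV residual exceeds 20x the
mean absolute residual (refit once), and agreement metrics on the
held-out test set (R^2, Pearson r, absolute-agreement ICC, Bland-Altman
limits). Whole-cohort five-fold CV produces per-sample epigenetic GA
(EGA) and its acceleration EGAA = EGA - GA.

The unpenalized covariate block is handled exactly via Frisch-Waugh-
Lovell: because the penalty touches only the CpG coefficients, the
solution equals an elastic net on covariate-residualized y and X, with
the covariate coefficients recovered afterwards by least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr, build_design, run_ewas
from .latent import LatentFactors, estimate_latent_factors, estimate_num_factors

__all__ = [
    "ClockModel",
    "ClockMetrics",
    "split_train_test",
    "select_features",
    "fit_elastic_net",
    "predict_ega",
    "cross_validated_ega",
    "flag_outlier_samples",
    "compute_egaa",
    "agreement_metrics",
    "train_and_evaluate",
]


@dataclass
class ClockModel:
    """Fitted clock: sparse CpG weights plus unpenalized covariate terms.

    ``probe_ids``/``weights`` hold only the nonzero CpG coefficients
    (M-units^-1 * days); ``covariate_terms`` maps design-column names
    (including the intercept, in days) to coefficients. ``latent_basis``
    stores what is needed to project latent-factor scores for new
    samples: the training probe order, training probe means, and the
    probe-space loading matrix.
    """

    probe_ids: list
    weights: np.ndarray
    intercept: float
    covariate_terms: dict
    alpha: float
    lambda_: float
    training_ids: list
    latent_basis: dict | None = None

    @property
    def n_cpgs(self) -> int:
        return len(self.probe_ids)

    def to_json(self) -> str:
        d = {
            "probe_ids": list(self.probe_ids),
            "weights": np.asarray(self.weights).tolist(),
            "intercept": self.intercept,
            "covariate_terms": self.covariate_terms,
            "alpha": self.alpha,
            "lambda": self.lambda_,
            "training_ids": list(self.training_ids),
            "latent_basis": (
                {
                    "probe_ids": list(self.latent_basis["probe_ids"]),
                    "means": np.asarray(self.latent_basis["means"]).tolist(),
                    "loadings": np.asarray(self.latent_basis["loadings"]).tolist(),
                }
                if self.latent_basis
                else None
            ),
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        lb = d.get("latent_basis")
        return cls(
            probe_ids=d["probe_ids"],
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            covariate_terms=d["covariate_terms"],
            alpha=float(d["alpha"]),
            lambda_=float(d["lambda"]),
            training_ids=d["training_ids"],
            latent_basis=(
                {
                    "probe_ids": lb["probe_ids"],
                    "means": np.asarray(lb["means"], dtype=float),
                    "loadings": np.asarray(lb["loadings"], dtype=float),
                }
                if lb
                else None
            ),
        )


@dataclass
class ClockMetrics:
    """Agreement between predicted and observed GA."""

    r: float
    r2: float
    icc: float
    ba_mean_diff: float
    ba_limits: tuple

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ba_limits"] = list(d["ba_limits"])
        return d


def split_train_test(sample_ids, train_frac: float = 0.8, seed: int = 0):
    """Deterministic random split; test size = floor(n * (1 - train_frac)).

    With n = 391 and the default fraction this yields 313 training and 78
    test samples. ``train_frac`` of 0 or 1 (empty side) raises.
    """
    ids = list(sample_ids)
    n = len(ids)
    n_test = int(np.floor(n * (1.0 - train_frac) + 1e-9))  # guard fp error
    n_train = n - n_test
    if n_test < 1 or n_train < 1:
        raise ValueError(f"degenerate split: train={n_train}, test={n_test}")
    order = np.random.default_rng(seed).permutation(n)
    train = [ids[i] for i in sorted(order[:n_train])]
    test = [ids[i] for i in sorted(order[n_train:])]
    return train, test


def select_features(ewas_results: pd.DataFrame, q_threshold: float = 0.05) -> list:
    """CpGs passing the FDR threshold in a training-set EWAS (no leakage:
    callers must fit the EWAS on training samples only)."""
    ok = ewas_results["q"] < q_threshold
    return list(ewas_results.loc[ok & ewas_results["q"].notna(), "probe_id"])


def _residualize_on(Z: np.ndarray, A: np.ndarray):
    """Return (residual of A on Z, coefficient solver for later recovery)."""
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


def fit_elastic_net(
    X_penalized: np.ndarray,
    X_unpenalized: np.ndarray | None,
    y: np.ndarray,
    alpha: float = 0.5,
    lambda_: float | None = None,
    lambda_grid=None,
    cv_folds: int = 5,
    seed: int = 0,
    probe_ids=None,
    covariate_names=None,
    training_ids=None,
) -> ClockModel:
    """Elastic net on CpGs with an exactly-unpenalized covariate block.

    Minimizes ``(1/2n)||y - X b - Z g||^2 + lambda (alpha ||b||_1 +
    (1-alpha)/2 ||b||_2^2)`` with ``g`` free. ``Z`` always contains an
    intercept. When ``lambda_`` is None the penalty is chosen by internal
    ``cv_folds``-fold CV minimizing MSE over a 100-point log grid (or the
    supplied ``lambda_grid``). ``lambda_ = 0`` reduces exactly to OLS.
    CpG columns are standardized internally; coefficients are returned on
    the original scale.
    """
    from sklearn.linear_model import ElasticNet, ElasticNetCV
    from sklearn.model_selection import KFold

    X = np.asarray(X_penalized, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p_feat = X.shape
    if p_feat == 0:
        raise ValueError("no features to fit ('no features' selection upstream?)")
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance")
    Z = np.ones((n, 1))
    if X_unpenalized is not None and np.size(X_unpenalized):
        U = np.asarray(X_unpenalized, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        Z = np.column_stack([Z, U])
    sds = X.std(axis=0)
    if np.all(sds == 0):
        raise ValueError("all penalized features have zero variance")
    usable = sds > 0
    Xr = _residualize_on(Z, X[:, usable])
    yr = _residualize_on(Z, y)
    r_sds = Xr.std(axis=0)
    keep = r_sds > 1e-12
    Xs = Xr[:, keep] / r_sds[keep]

    beta_std = np.zeros(int(keep.sum()))
    if lambda_ is not None and lambda_ == 0:
        beta_std, *_ = np.linalg.lstsq(Xs, yr, rcond=None)
        lam = 0.0
    elif lambda_ is not None:
        en = ElasticNet(alpha=lambda_, l1_ratio=alpha, fit_intercept=False, max_iter=50_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            en.fit(Xs, yr)
        beta_std = en.coef_
        lam = float(lambda_)
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        kwargs = dict(l1_ratio=alpha, fit_intercept=False, cv=cv, max_iter=50_000)
        # 100-point log grid by default (sklearn derives it from the data)
        kwargs["alphas"] = np.asarray(lambda_grid, dtype=float) if lambda_grid is not None else 100
        encv = ElasticNetCV(**kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            encv.fit(Xs, yr)
        beta_std = encv.coef_
        lam = float(encv.alpha_)

    beta = np.zeros(p_feat)
    sub = np.zeros(int(keep.sum()))
    sub[:] = beta_std / r_sds[keep]
    tmp = np.zeros(int(usable.sum()))
    tmp[keep] = sub
    beta[usable] = tmp
    gamma, *_ = np.linalg.lstsq(Z, y - X @ beta, rcond=None)

    probe_ids = list(probe_ids) if probe_ids is not None else [f"f{i}" for i in range(p_feat)]
    covariate_names = (
        list(covariate_names)
        if covariate_names is not None
        else [f"z{i}" for i in range(Z.shape[1] - 1)]
    )
    nz = beta != 0
    cov_terms = {"intercept": float(gamma[0])}
    for name, g in zip(covariate_names, gamma[1:]):
        cov_terms[name] = float(g)
    return ClockModel(
        probe_ids=[pid for pid, m in zip(probe_ids, nz) if m],
        weights=beta[nz],
        intercept=float(gamma[0]),
        covariate_terms=cov_terms,
        alpha=float(alpha),
        lambda_=lam,
        training_ids=list(training_ids) if training_ids is not None else [],
    )


def predict_ega(model: ClockModel, X_penalized: np.ndarray, X_unpenalized=None) -> np.ndarray:
    """EGA for new samples: CpG block times weights plus covariate terms.

    Columns of ``X_penalized`` must follow ``model.probe_ids`` and
    ``X_unpenalized`` the order of ``model.covariate_terms`` (minus the
    intercept).
    """
    X = np.asarray(X_penalized, dtype=float)
    yhat = model.intercept + X @ np.asarray(model.weights, dtype=float)
    names = [k for k in model.covariate_terms if k != "intercept"]
    if names:
        U = np.asarray(X_unpenalized, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        g = np.array([model.covariate_terms[k] for k in names])
        yhat = yhat + U @ g
    return yhat


def flag_outlier_samples(residuals, multiplier: float = 20.0) -> list:
    """Samples whose |CV residual| exceeds ``multiplier`` times the mean
    absolute residual. Accepts a Series (ids in the index) or array."""
    if isinstance(residuals, pd.Series):
        r = residuals.to_numpy(dtype=float)
        ids = list(residuals.index)
    else:
        r = np.asarray(residuals, dtype=float)
        ids = list(range(len(r)))
    if r.size == 0:
        return []
    thresh = multiplier * np.mean(np.abs(r))
    if thresh == 0:
        return []
    return [i for i, v in zip(ids, r) if abs(v) > thresh]


def compute_egaa(ega, ga) -> np.ndarray:
    """Epigenetic GA acceleration: EGA minus chronological GA, in days."""
    return np.asarray(ega, dtype=float) - np.asarray(ga, dtype=float)


def agreement_metrics(pred, obs) -> ClockMetrics:
    """Pearson r, R^2 (squared correlation), two-way absolute-agreement
    single-measures ICC, and Bland-Altman mean difference and 95% limits
    of agreement (mean +- 1.96 SD of the differences)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = pred.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    r = float(np.corrcoef(pred, obs)[0, 1])
    data = np.column_stack([obs, pred])  # n subjects x 2 raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    diff = pred - obs
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    return ClockMetrics(
        r=r,
        r2=r**2,
        icc=float(icc),
        ba_mean_diff=mean_diff,
        ba_limits=(mean_diff - 1.96 * sd_diff, mean_diff + 1.96 * sd_diff),
    )


def _ordered_subset(ds_m, sample_ids):
    """Subset samples and put them in exactly the requested order, so fits
    and predictions are invariant to the dataset's own column order."""
    from dataclasses import replace

    sub = ds_m.subset_samples(sample_ids)
    order = list(sample_ids)
    return replace(
        sub,
        values=sub.values.loc[:, order],
        samples=sub.samples.set_index("sample_id").loc[order].reset_index(),
    )


def _fit_fold(ds_m, train_ids, q_threshold, alpha, n_latent, seed, max_k, lambda_=None):
    """EWAS + selection + elastic net on a training subset; returns the
    model or None when no features pass selection."""
    train_ds = _ordered_subset(ds_m, sorted(train_ids))
    M = train_ds.values.to_numpy()
    cov_X, cov_names = build_design(train_ds.samples, factors=None)
    cov_only = cov_X[:, [0] + list(range(2, cov_X.shape[1]))]  # drop GA column
    ga_train = train_ds.samples["ga_days"].to_numpy()
    if n_latent == "auto":
        # count factors beyond the full design (GA included)
        K = estimate_num_factors(M, cov_X, max_k=max_k, n_perm=20, seed=seed)
    else:
        K = int(n_latent)
    # outcome-protected: factors cannot absorb the GA signal being modelled
    factors = estimate_latent_factors(M, cov_only, outcome=ga_train, K=K) if K else None
    res = run_ewas(train_ds, factors=factors)
    selected = select_features(res, q_threshold)
    if not selected:
        return None
    sel_idx = train_ds.manifest["probe_id"].isin(selected).to_numpy()
    Xp = M[sel_idx].T
    design, names = build_design(train_ds.samples, factors)
    Z = design[:, 2:]  # unpenalized block (design minus intercept and GA)
    model = fit_elastic_net(
        Xp,
        Z if Z.size else None,
        train_ds.samples["ga_days"].to_numpy(),
        alpha=alpha,
        lambda_=lambda_,
        seed=seed,
        probe_ids=list(train_ds.manifest.loc[sel_idx, "probe_id"]),
        covariate_names=names[2:],
        training_ids=train_ids,
    )
    # store what prediction on new samples needs for latent projection
    if factors is not None and factors.K:
        means = M.mean(axis=1)
        R = M - means[:, None]
        scores = factors.scores
        # loadings such that new_scores = (m_new - means) @ loadings
        loadings, *_ = np.linalg.lstsq(R.T, scores, rcond=None)
        model.latent_basis = {
            "probe_ids": list(train_ds.manifest["probe_id"]),
            "means": means,
            "loadings": loadings,
        }
    model._covariate_names = names[2:]  # transient, for prediction plumbing
    model._n_latent = factors.K if factors is not None else 0
    return model


def _predict_samples(model: ClockModel, ds_m, sample_ids) -> np.ndarray:
    """Predictions aligned to ``sample_ids`` order."""
    sub = _ordered_subset(ds_m, list(sample_ids))
    pid_to_row = {pid: i for i, pid in enumerate(sub.manifest["probe_id"])}
    rows = [pid_to_row[p] for p in model.probe_ids]
    Xp = sub.values.to_numpy()[rows].T if rows else np.zeros((sub.n_samples, 0))
    names = [k for k in model.covariate_terms if k != "intercept"]
    n_lat = sum(1 for k in names if k.startswith("latent"))
    base_names = [k for k in names if not k.startswith("latent")]
    cols = []
    for name in base_names:
        var, lev = name.split("[", 1)
        lev = lev.rstrip("]")
        cols.append((sub.samples[var].astype(str) == lev).to_numpy(float))
    if n_lat:
        lb = model.latent_basis
        pid_rows = [pid_to_row[p] for p in lb["probe_ids"]]
        Mnew = sub.values.to_numpy()[pid_rows]
        scores = (Mnew - np.asarray(lb["means"])[:, None]).T @ np.asarray(lb["loadings"])
        for k in range(n_lat):
            cols.append(scores[:, k])
    U = np.column_stack(cols) if cols else None
    return predict_ega(model, Xp, U)


def cross_validated_ega(
    ds,
    folds: int = 5,
    seed: int = 0,
    q_threshold: float = 0.05,
    alpha: float = 0.5,
    n_latent: int | str = 0,
    max_k: int = 10,
    lambda_: float | None = None,
) -> pd.DataFrame:
    """Out-of-fold EGA for every sample in the cohort.

    Samples are apportioned into ``folds`` folds (deterministic in the
    seed and invariant to input order: folds are assigned on the sorted
    sample ids); in each round the EWAS, feature selection, latent-factor
    estimation and elastic-net fit all use only the 4/5 training portion,
    and the held-out fold receives predictions. A fold whose training
    selection is empty is flagged (NaN predictions).

    Returns an EGA table: sample_id, ga_observed, ega, egaa, fold.
    """
    ds_m = ds.to_m()
    ids = sorted(ds_m.samples["sample_id"])
    rng = np.random.default_rng(seed)
    fold_of = {}
    order = rng.permutation(len(ids))
    for i, idx in enumerate(order):
        fold_of[ids[idx]] = i % folds
    rows = []
    for f in range(folds):
        test_ids = [s for s in ids if fold_of[s] == f]
        train_ids = [s for s in ids if fold_of[s] != f]
        model = _fit_fold(ds_m, train_ids, q_threshold, alpha, n_latent, seed, max_k, lambda_)
        sub = ds_m.samples.set_index("sample_id").loc[test_ids]
        if model is None:
            warnings.warn(f"fold {f}: no features passed selection; predictions missing")
            ega = np.full(len(test_ids), np.nan)
        else:
            ega = _predict_samples(model, ds_m, test_ids)
        for sid, e in zip(test_ids, ega):
            ga = float(sub.loc[sid, "ga_days"])
            rows.append(
                {"sample_id": sid, "ga_observed": ga, "ega": float(e), "egaa": float(e) - ga, "fold": f}
            )
    out = pd.DataFrame(rows).sort_values("sample_id", kind="mergesort").reset_index(drop=True)
    return out


def train_and_evaluate(
    ds,
    train_frac: float = 0.8,
    seed: int = 0,
    q_threshold: float = 0.05,
    alpha: float = 0.5,
    n_latent: int | str = 0,
    max_k: int = 10,
    outlier_multiplier: float = 20.0,
    lambda_: float | None = None,
):
    """The full split/select/fit/trim/evaluate procedure.

    1. 80/20 train/test split; 2. five-fold CV EGA within training;
    3. flag training samples with |CV residual| > 20x mean absolute
    residual, drop them and refit once; 4. apply the final model to the
    held-out test set and score agreement.

    Returns ``(model, metrics, test EGA table, flagged ids)``.
    """
    ds_m = ds.to_m()
    train_ids, test_ids = split_train_test(list(ds_m.samples["sample_id"]), train_frac, seed)
    train_ds = ds_m.subset_samples(train_ids)
    cv = cross_validated_ega(
        train_ds, folds=5, seed=seed, q_threshold=q_threshold, alpha=alpha,
        n_latent=n_latent, max_k=max_k, lambda_=lambda_,
    )
    resid = pd.Series(cv["egaa"].to_numpy(), index=cv["sample_id"])
    flagged = flag_outlier_samples(resid.dropna(), outlier_multiplier)
    kept = [s for s in train_ids if s not in set(flagged)]
    model = _fit_fold(ds_m, kept, q_threshold, alpha, n_latent, seed, max_k, lambda_)
    if model is None:
        raise ValueError("no features passed selection on the training set")
    ega_test = _predict_samples(model, ds_m, test_ids)
    obs = ds_m.samples.set_index("sample_id").loc[test_ids, "ga_days"].to_numpy(dtype=float)
    metrics = agreement_metrics(ega_test, obs)
    table = pd.DataFrame(
        {
            "sample_id": test_ids,
            "ga_observed": obs,
            "ega": ega_test,
            "egaa": compute_egaa(ega_test, obs),
            "fold": -1,
        }
    )
    return model, metrics, table, flagged
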