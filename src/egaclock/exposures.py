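"""Prenatal/perinatal exposure models for GA, EGA, and EGAA.

Single-exposure linear models (one unadjusted OLS per exposure, F-test
for the whole term, BH-FDR across exposures within each outcome) and a
multi-exposure backward-selection model where terms are greedily dropped
whole (all dummy levels at once) while the AIC decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ewas import bh_fdr

__all__ = [
    "fit_exposure_model",
    "run_all_exposures",
    "backward_select_aic",
    "SelectionResult",
    "aic_from_rss",
]


def _is_categorical(col: pd.Series) -> bool:
    return isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object or col.dtype == bool


def _dummy_columns(col: pd.Series):
    """Dummy-code a categorical column against its reference level.

    The reference is the first declared category (ordered Categorical) or
    the first level in order of appearance otherwise. Returns (matrix,
    level labels, reference label).
    """
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = [lev for lev in col.cat.categories if (col == lev).any()]
    else:
        levels = list(pd.unique(col.dropna().astype(str)))
        col = col.astype(str)
    ref = levels[0]
    mats = [np.asarray(col == lev, dtype=float) for lev in levels[1:]]
    return np.column_stack(mats) if mats else np.zeros((len(col), 0)), levels[1:], ref


def fit_exposure_model(outcome: pd.Series, exposure: pd.Series, outcome_name: str = "GA",
                       exposure_name: str | None = None) -> pd.DataFrame:
    """Unadjusted OLS of an outcome on one exposure.

    Categorical exposures are dummy-coded against their reference level;
    continuous exposures give a single slope. Returns one row per
    non-reference level with the coefficient, its 95% CI (t quantile),
    and the overall F-test p shared by the rows of the term. Complete
    cases only; constant exposures raise.
    """
    exposure_name = exposure_name or (exposure.name or "exposure")
    df = pd.DataFrame({"y": pd.to_numeric(outcome, errors="coerce"), "x": exposure}).dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete cases")
    y = df["y"].to_numpy(dtype=float)
    if np.var(y) == 0:
        raise ValueError(f"outcome {outcome_name!r} is degenerate (zero variance)")
    x = df["x"]
    if _is_categorical(x):
        X, levels, ref = _dummy_columns(x)
        if X.shape[1] == 0:
            raise ValueError(f"exposure {exposure_name!r} is constant")
    else:
        xv = x.to_numpy(dtype=float)
        if np.var(xv) == 0:
            raise ValueError(f"exposure {exposure_name!r} is constant")
        X, levels, ref = xv[:, None], [""], None
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    rows = []
    for i, lev in enumerate(levels):
        rows.append(
            {
                "outcome": outcome_name,
                "exposure": exposure_name,
                "level": lev,
                "reference": ref if ref is not None else "",
                "coefficient": float(model.params[i + 1]),
                "ci_low": float(ci[i + 1, 0]),
                "ci_high": float(ci[i + 1, 1]),
                "f_p": float(model.f_pvalue),
                "n": int(len(df)),
            }
        )
    return pd.DataFrame(rows)


def run_all_exposures(outcomes: pd.DataFrame, exposures: pd.DataFrame,
                      exposure_cols=None) -> pd.DataFrame:
    """Single-exposure models for every (outcome, exposure) pair.

    ``outcomes`` holds one column per GA measure (e.g. GA, EGA, EGAA);
    ``exposures`` the exposure sheet (a ``sample_id`` column is ignored).
    BH-FDR q-values are computed within each outcome across the
    exposures' F-test p-values and broadcast to the term's rows.
    Exposures constant within the complete cases are skipped (they carry
    no contrast to test); a degenerate outcome still raises.
    """
    exposure_cols = exposure_cols or [c for c in exposures.columns if c != "sample_id"]
    frames = []
    for out_name in outcomes.columns:
        res = []
        for exp_name in exposure_cols:
            try:
                res.append(
                    fit_exposure_model(
                        outcomes[out_name], exposures[exp_name], out_name, exp_name
                    )
                )
            except ValueError as err:
                if "constant" in str(err):
                    continue
                raise
        block = pd.concat(res, ignore_index=True)
        term_p = block.groupby("exposure", sort=False)["f_p"].first()
        term_q = pd.Series(bh_fdr(term_p.to_numpy()), index=term_p.index)
        block["q"] = block["exposure"].map(term_q)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def aic_from_rss(rss: float, n: int, k: int) -> float:
    """AIC up to additive constants: n ln(RSS/n) + 2k (k = fitted params)."""
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * k


@dataclass
class SelectionResult:
    """Outcome of AIC backward selection."""

    outcome: str
    retained_exposures: list
    coefficients: dict  # column label -> coefficient (incl. intercept)
    aic_trace: list  # (step, dropped term or "<start>", AIC)
    r2: float
    adj_r2: float


def backward_select_aic(outcome: pd.Series, exposures: pd.DataFrame,
                        candidates=None, outcome_name: str = "GA") -> SelectionResult:
    """Greedy backward elimination of whole exposure terms by AIC.

    Rows are complete cases across *all* candidates (fixed n keeps AIC
    comparable across steps). Starting from the full model, the term
    whose removal lowers AIC the most is dropped, repeating until no
    removal lowers it. Categorical terms enter and leave as a block of
    dummy columns.
    """
    candidates = list(candidates or [c for c in exposures.columns if c != "sample_id"])
    df = exposures[candidates].copy()
    df["__y"] = pd.to_numeric(outcome, errors="coerce").to_numpy()
    df = df.dropna()
    y = df["__y"].to_numpy(dtype=float)
    n = len(df)
    if np.var(y) == 0:
        raise ValueError(f"outcome {outcome_name!r} is degenerate (zero variance)")

    blocks: dict = {}
    labels: dict = {}
    for name in candidates:
        col = df[name]
        if _is_categorical(col):
            X, levels, ref = _dummy_columns(col)
            if X.shape[1] == 0:
                continue  # constant within complete cases: nothing to fit
            blocks[name] = X
            labels[name] = [f"{name}[{lev}]" for lev in levels]
        else:
            xv = col.to_numpy(dtype=float)
            if np.var(xv) == 0:
                continue
            blocks[name] = xv[:, None]
            labels[name] = [name]

    def _fit(terms):
        X = np.column_stack([np.ones(n)] + [blocks[t] for t in terms])
        k = X.shape[1]
        if n <= k:
            raise ValueError(f"n={n} samples cannot fit {k} parameters")
        beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((y - X @ beta) ** 2))
        return beta, rss, k

    terms = list(blocks)
    _, rss, k = _fit(terms)
    aic = aic_from_rss(rss, n, k)
    trace = [(0, "<start>", aic)]
    step = 0
    while terms:
        best_term, best_aic = None, aic
        for t in terms:
            reduced = [u for u in terms if u != t]
            _, rss_r, k_r = _fit(reduced)
            a = aic_from_rss(rss_r, n, k_r)
            if a < best_aic - 1e-12:
                best_term, best_aic = t, a
        if best_term is None:
            break
        terms = [u for u in terms if u != best_term]
        aic = best_aic
        step += 1
        trace.append((step, best_term, aic))

    beta, rss, k = _fit(terms)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1 - rss / tss
    adj_r2 = 1 - (1 - r2) * (n - 1) / (n - k)
    coef = {"intercept": float(beta[0])}
    i = 1
    for t in terms:
        for lab in labels[t]:
            coef[lab] = float(beta[i])
            i += 1
    return SelectionResult(
        outcome=outcome_name,
        retained_exposures=terms,
        coefficients=coef,
        aic_trace=trace,
        r2=float(r2),
        adj_r2=float(adj_r2),
    )
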