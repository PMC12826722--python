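"""Cohort descriptive statistics and reproducible run outputs.

The descriptive machinery mirrors a study's "Table 1": chi-square tests
(Yates-corrected for 2x2 tables) for categorical variables and pooled
two-sample t-tests computed directly from group summaries for continuous
ones, so a published table's printed counts/means/SDs suffice to
recompute its p-values. ``write_results`` serializes stage outputs with
a run manifest (config hash, seed, file digests) so identical configs
reproduce identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryTest",
    "chi_square_test",
    "t_test_from_summary",
    "build_table_one",
    "write_results",
    "config_hash",
]


@dataclass
class SummaryTest:
    """One descriptive-table hypothesis test."""

    variable: str
    kind: str  # "chi-square" | "t-test"
    statistic: float
    df: float
    p: float
    table: object = None  # counts DataFrame or per-group (mean, sd, n)


def chi_square_test(counts, variable: str = "") -> SummaryTest:
    """Pearson chi-square on an r x c count table.

    Yates continuity correction is applied iff the table is 2x2 (the
    convention that reproduces published 2x2 descriptive p-values);
    larger tables use the uncorrected statistic. Zero marginals raise.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(c, correction=(c.shape == (2, 2)))
    return SummaryTest(
        variable=variable,
        kind="chi-square",
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        table=pd.DataFrame(c),
    )


def t_test_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> SummaryTest:
    """Pooled-variance two-sample Student t-test from group summaries.

    df = n1 + n2 - 2, two-sided p. Needs n >= 2 and sd > 0 per group.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return SummaryTest(
        variable=variable,
        kind="t-test",
        statistic=float(res.statistic),
        df=float(n1 + n2 - 2),
        p=float(res.pvalue),
        table={"group1": (mean1, sd1, n1), "group2": (mean2, sd2, n2)},
    )


def _is_categorical(col: pd.Series) -> bool:
    return isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object or col.dtype == bool


def build_table_one(samples: pd.DataFrame, group_col: str, variables=None):
    """Descriptive table stratified by a two-level grouping variable.

    Categorical variables get a count (column %) cross-tab and a
    chi-square test; continuous variables get mean (SD) per group and a
    pooled t-test computed via the group summaries. Rows with a missing
    value are dropped per variable, so per-variable totals may differ.

    Returns ``(tests, formatted)``: a list of :class:`SummaryTest` and a
    long-format display DataFrame with "count (pct)" / "mean (SD)" cells.
    """
    groups = [g for g in pd.unique(samples[group_col].dropna())]
    if len(groups) != 2:
        raise ValueError("build_table_one expects exactly two groups")
    variables = variables or [c for c in samples.columns if c not in (group_col, "sample_id")]
    tests, rows = [], []
    for var in variables:
        sub = samples[[var, group_col]].dropna()
        if _is_categorical(sub[var]):
            ct = pd.crosstab(sub[var], sub[group_col])
            ct = ct.reindex(columns=groups, fill_value=0)
            ct = ct.loc[(ct.sum(axis=1) > 0)]
            test = chi_square_test(ct.to_numpy(), variable=var)
            test.table = ct
            tests.append(test)
            col_tot = ct.sum(axis=0)
            for lev in ct.index:
                cells = {
                    str(g): f"{int(ct.loc[lev, g])} ({100 * ct.loc[lev, g] / col_tot[g]:.1f})"
                    for g in groups
                }
                rows.append({"variable": var, "level": str(lev), **cells,
                             "p": f"{test.p:.3g}" if lev == ct.index[0] else ""})
        else:
            g1 = sub.loc[sub[group_col] == groups[0], var].astype(float)
            g2 = sub.loc[sub[group_col] == groups[1], var].astype(float)
            test = t_test_from_summary(
                g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2),
                variable=var,
            )
            tests.append(test)
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    str(groups[0]): f"{g1.mean():.2f} ({g1.std(ddof=1):.2f})",
                    str(groups[1]): f"{g2.mean():.2f} ({g2.std(ddof=1):.2f})",
                    "p": f"{test.p:.3g}",
                }
            )
    return tests, pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serializable config."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_results(run_dir, outputs: dict, config: dict | None = None, seed: int | None = None) -> dict:
    """Write stage outputs and a run manifest; returns the manifest.

    ``outputs`` maps a name to a DataFrame (written as ``<name>.tsv``) or
    a JSON-serializable object (written as ``<name>.json``). The manifest
    records the config hash, seed, and a SHA-256 digest per file, so two
    runs with identical config and seed produce identical digests.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            path = run_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t", index=False, float_format="%.10g")
        else:
            path = run_dir / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "config_hash": config_hash(config or {}),
        "seed": seed,
        "files": files,
    }
    (run_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
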