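"""Probe QC, quantile normalization, and beta/M-value conversion.

The analysis entry point is a beta-value matrix (probes x samples) plus a
probe manifest; raw intensity processing is upstream and out of scope.
The pipeline here mirrors standard methylation-array practice: drop probes
that fail detection, carry SNPs at the 3'/5' ends, sit on sex chromosomes,
or are off-target; quantile-normalize the beta matrix across samples; then
move to the logit (M-value) scale for regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "QCConfig",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "quantile_normalize",
]

#: columns every probe manifest must carry
MANIFEST_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "snp_3p_flag",
    "snp_5p_flag",
    "sex_chromosome",
    "off_target",
    "detection_fail_fraction",
]

BETA_CLAMP = 1e-6  # beta values of exactly 0/1 are clamped before logit


@dataclass
class MethylationDataset:
    """Methylation matrix with aligned probe manifest and sample metadata.

    Parameters
    ----------
    values
        probes x samples matrix; rows indexed by probe id, columns by
        sample id. Interpreted on the scale given by ``scale``.
    manifest
        One row per probe, same order as ``values`` rows; columns at least
        :data:`MANIFEST_COLUMNS` (``gene``/``category`` filled by the
        annotation step).
    samples
        One row per sample (``sample_id``, ``ga_days``, ``sex``, ``race``,
        exposures...), same order as ``values`` columns.
    scale
        ``"beta"`` (proportions in [0, 1]) or ``"M"`` (log2 logit).
    """

    values: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if list(self.values.index) != list(self.manifest["probe_id"]):
            raise ValueError("values row order does not match manifest probe order")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("values column order does not match sample metadata")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated probe ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids")
        if self.scale == "beta":
            v = self.values.to_numpy()
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("scale='beta' but values fall outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_m(self) -> "MethylationDataset":
        """Return the dataset on the M-value scale (no-op if already M)."""
        if self.scale == "M":
            return self
        m = beta_to_m(self.values.to_numpy(), clamp=True)
        return replace(
            self,
            values=pd.DataFrame(m, index=self.values.index, columns=self.values.columns),
            scale="M",
        )

    def to_beta(self) -> "MethylationDataset":
        if self.scale == "beta":
            return self
        b = m_to_beta(self.values.to_numpy())
        return replace(
            self,
            values=pd.DataFrame(b, index=self.values.index, columns=self.values.columns),
            scale="beta",
        )

    def subset_probes(self, probe_ids) -> "MethylationDataset":
        keep = self.manifest["probe_id"].isin(set(probe_ids)).to_numpy()
        return replace(
            self,
            values=self.values.loc[keep],
            manifest=self.manifest.loc[keep].reset_index(drop=True),
        )

    def subset_samples(self, sample_ids) -> "MethylationDataset":
        keep = self.samples["sample_id"].isin(set(sample_ids)).to_numpy()
        return replace(
            self,
            values=self.values.loc[:, keep],
            samples=self.samples.loc[keep].reset_index(drop=True),
        )


@dataclass
class QCConfig:
    """Probe-filtering rules.

    ``detection_fail_fraction_max = 0`` removes a probe if detection failed
    (p > ``detection_p_threshold``) in *any* sample — the strictest reading
    of a "detection p > 0.05" exclusion; raise it to tolerate a fraction of
    failing samples.
    """

    detection_p_threshold: float = 0.05
    detection_fail_fraction_max: float = 0.0
    drop_snp: bool = True
    drop_sex: bool = True
    drop_off_target: bool = True

    def __post_init__(self) -> None:
        for name in ("detection_p_threshold", "detection_fail_fraction_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def beta_to_m(beta, clamp: bool = True):
    """log2 logit transform: M = log2(beta / (1 - beta)).

    Values of exactly 0/1 are clamped to ``[1e-6, 1 - 1e-6]`` first when
    ``clamp`` is true (the default), so the transform is finite.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    if clamp:
        b = np.clip(b, BETA_CLAMP, 1 - BETA_CLAMP)
    elif np.any((b <= 0) | (b >= 1)):
        raise ValueError("beta values must lie strictly in (0, 1) when clamp=False")
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    m = np.asarray(m, dtype=float)
    # expit on the natural-log scale for numerical stability at large |M|
    from scipy.special import expit

    return expit(m * np.log(2.0))


def filter_probes(ds: MethylationDataset, qc: QCConfig | None = None):
    """Apply probe-level QC and return (filtered dataset, report).

    A probe is removed if it fails *any* enabled rule. The report counts
    probes failing each rule (a probe may be counted under several rules)
    and the retained total. Raises if nothing survives.
    """
    qc = qc or QCConfig()
    man = ds.manifest
    fail = {}
    fail["detection"] = (
        man["detection_fail_fraction"].to_numpy() > qc.detection_fail_fraction_max
    )
    fail["snp"] = (
        (man["snp_3p_flag"] | man["snp_5p_flag"]).to_numpy()
        if qc.drop_snp
        else np.zeros(len(man), bool)
    )
    fail["sex_chromosome"] = (
        man["sex_chromosome"].to_numpy() if qc.drop_sex else np.zeros(len(man), bool)
    )
    fail["off_target"] = (
        man["off_target"].to_numpy() if qc.drop_off_target else np.zeros(len(man), bool)
    )
    any_fail = np.zeros(len(man), bool)
    for mask in fail.values():
        any_fail |= mask
    keep = ~any_fail
    if not keep.any():
        raise ValueError("all probes removed by QC filters")
    report = {
        "n_input": int(len(man)),
        "n_retained": int(keep.sum()),
        "removed_per_rule": {k: int(v.sum()) for k, v in fail.items()},
        "n_removed": int(any_fail.sum()),
        "beta_clamp": BETA_CLAMP,
        "config": {
            "detection_p_threshold": qc.detection_p_threshold,
            "detection_fail_fraction_max": qc.detection_fail_fraction_max,
            "drop_snp": qc.drop_snp,
            "drop_sex": qc.drop_sex,
            "drop_off_target": qc.drop_off_target,
        },
    }
    out = replace(
        ds,
        values=ds.values.loc[keep],
        manifest=man.loc[keep].reset_index(drop=True),
    )
    return out, report


def quantile_normalize(values):
    """Force every sample (column) to share the mean order-statistic distribution.

    Each column's sorted values are replaced by the across-column mean of
    order statistics; ranks within a column are preserved, and tied values
    receive the mean of their tied ranks' reference values (rank averaging),
    so the result is deterministic.

    Accepts and returns either a DataFrame (probes x samples) or ndarray.
    """
    is_df = isinstance(values, pd.DataFrame)
    v = values.to_numpy(dtype=float) if is_df else np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected a 2-D probes x samples matrix")
    if np.isnan(v).any():
        raise ValueError("missing values are not supported in quantile normalization")
    n, k = v.shape
    if k < 2:
        warnings.warn("single-sample input: quantile normalization is the identity")
        return values.copy() if is_df else v.copy()
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    from scipy.stats import rankdata

    grid = np.arange(n, dtype=float)
    for j in range(k):
        ranks = rankdata(v[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    if is_df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out
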