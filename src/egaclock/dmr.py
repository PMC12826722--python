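"""Region detection from spatially correlated EWAS p-values (comb-p style).

Nearby CpGs are correlated, so runs of moderately small p-values carry
more evidence than any single site. The procedure: (1) estimate the
autocorrelation of probit-transformed p-values as a function of genomic
distance; (2) smooth each site's p by Stouffer-Liptak combination with
its neighbors, using the ACF for the correlation matrix; (3) find maximal
runs of sites below a seed threshold within a gap limit; (4) assign each
region a Stouffer-Liptak combined p over its members, Sidak-correct it
for the effective search space, and BH-FDR the regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .ewas import bh_fdr

__all__ = [
    "AcfEstimate",
    "estimate_acf",
    "stouffer_liptak",
    "adjust_site_pvalues",
    "find_regions",
    "region_pvalue_sidak",
    "call_dmrs",
]

P_CLIP = 1e-15  # keep probit transforms finite


@dataclass
class AcfEstimate:
    """Distance-binned autocorrelation of probit-transformed p-values.

    ``bin_edges[i] .. bin_edges[i+1]`` (left-exclusive, right-inclusive)
    maps to ``correlations[i]``; distance 0 has correlation 1 by
    definition; distances beyond the last edge are treated as independent.
    """

    bin_edges: np.ndarray
    correlations: np.ndarray
    n_pairs: np.ndarray
    low_count_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def corr_for_distance(self, d) -> np.ndarray:
        d = np.atleast_1d(np.asarray(d, dtype=float))
        out = np.zeros(d.shape)
        out[d == 0] = 1.0
        idx = np.searchsorted(self.bin_edges[1:], d, side="left")
        inside = (d > 0) & (d <= self.bin_edges[-1])
        out[inside] = self.correlations[idx[inside]]
        return out


def _probit(p: np.ndarray) -> np.ndarray:
    return norm.isf(np.clip(p, P_CLIP, 1 - P_CLIP))


def estimate_acf(p, chrom, pos, max_dist: int = 1000, bin_width: int = 50) -> AcfEstimate:
    """Pearson correlation of z = probit(1 - p) over intra-chromosome probe
    pairs, binned by genomic distance.

    Positions must be sorted within each chromosome. Bins with fewer than
    10 pairs get correlation 0 and are flagged.
    """
    if max_dist <= 0 or bin_width <= 0:
        raise ValueError("max_dist and bin_width must be positive")
    p = np.asarray(p, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    z = _probit(p)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    pairs_a: list = [[] for _ in range(n_bins)]
    pairs_b: list = [[] for _ in range(n_bins)]
    for c in pd.unique(chrom):
        sel = np.where(chrom == c)[0]
        cp = pos[sel]
        if np.any(np.diff(cp) < 0):
            raise ValueError(f"positions not sorted within chromosome {c}")
        cz = z[sel]
        for i in range(len(sel)):
            j = i + 1
            while j < len(sel) and cp[j] - cp[i] <= max_dist:
                d = cp[j] - cp[i]
                if d > 0:
                    b = int(np.searchsorted(edges[1:], d, side="left"))
                    pairs_a[b].append(cz[i])
                    pairs_b[b].append(cz[j])
                j += 1
    corr = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    flags = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        counts[b] = len(pairs_a[b])
        if counts[b] < 10:
            flags[b] = True
            continue
        a_arr, b_arr = np.asarray(pairs_a[b]), np.asarray(pairs_b[b])
        if a_arr.std() == 0 or b_arr.std() == 0:
            flags[b] = True
            continue
        corr[b] = float(np.corrcoef(a_arr, b_arr)[0, 1])
    return AcfEstimate(bin_edges=edges, correlations=corr, n_pairs=counts, low_count_flags=flags)


def _nearest_pd(sigma: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, V = np.linalg.eigh(sigma)
    w = np.clip(w, 1e-8, None)
    S = V @ np.diag(w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def stouffer_liptak(p, sigma=None) -> float:
    """Combine k p-values under a known correlation matrix.

    z_i = probit(1 - p_i); combined z = sum(z) / sqrt(sum(sigma));
    returns 1 - Phi(z_combined). ``sigma=None`` means independence. A
    non-positive-definite sigma is repaired by eigenvalue clipping (with a
    warning).
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    k = p.size
    if k == 0:
        raise ValueError("no p-values to combine")
    if sigma is None:
        sigma = np.eye(k)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (k, k):
        raise ValueError("sigma shape must match the number of p-values")
    if not np.allclose(np.diag(sigma), 1.0):
        raise ValueError("sigma must have a unit diagonal")
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-10:
        warnings.warn("correlation matrix not positive semi-definite; repaired")
        sigma = _nearest_pd(sigma)
    z = _probit(p)
    denom = float(np.sqrt(sigma.sum()))
    return float(norm.sf(z.sum() / denom))


def adjust_site_pvalues(p, chrom, pos, acf: AcfEstimate, window: int = 1000) -> np.ndarray:
    """Replace each site's p with a Stouffer-Liptak combination over all
    sites within +-window on the same chromosome (sigma from the ACF).

    Isolated sites are returned unchanged.
    """
    p = np.asarray(p, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    out = p.copy()
    for c in pd.unique(chrom):
        sel = np.where(chrom == c)[0]
        cp = pos[sel]
        for ii, i in enumerate(sel):
            lo = int(np.searchsorted(cp, cp[ii] - window, side="left"))
            hi = int(np.searchsorted(cp, cp[ii] + window, side="right"))
            members = sel[lo:hi]
            if members.size == 1:
                continue
            mpos = pos[members]
            dist = np.abs(mpos[:, None] - mpos[None, :])
            sigma = acf.corr_for_distance(dist.ravel()).reshape(dist.shape)
            np.fill_diagonal(sigma, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[i] = stouffer_liptak(p[members], sigma)
    return out


def find_regions(
    adjusted_p,
    chrom,
    pos,
    acf: AcfEstimate,
    seed_p: float = 0.05,
    max_gap: int = 1000,
    raw_p=None,
    probe_ids=None,
) -> pd.DataFrame:
    """Maximal runs of sites with adjusted p below ``seed_p``.

    Consecutive members must be at most ``max_gap`` bp apart and a region
    needs at least two probes. Each region's ``p_combined`` is a
    Stouffer-Liptak combination of the member sites' p-values (the raw
    EWAS p if supplied, else the adjusted p) with ACF-derived sigma.
    Coordinates in the returned frame are 1-based inclusive.
    """
    adjusted_p = np.asarray(adjusted_p, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    base_p = np.asarray(raw_p, dtype=float) if raw_p is not None else adjusted_p
    if probe_ids is None:
        probe_ids = np.array([f"site{i}" for i in range(len(pos))], dtype=object)
    else:
        probe_ids = np.asarray(probe_ids, dtype=object)
    rows = []
    for c in pd.unique(chrom):
        sel = np.where(chrom == c)[0]
        cp = pos[sel]
        run: list = []
        for ii in range(len(sel) + 1):
            ok = (
                ii < len(sel)
                and adjusted_p[sel[ii]] < seed_p
                and (not run or cp[ii] - pos[run[-1]] <= max_gap)
            )
            if ok:
                run.append(sel[ii])
                continue
            if len(run) >= 2:
                members = np.array(run)
                mpos = pos[members]
                dist = np.abs(mpos[:, None] - mpos[None, :])
                sigma = acf.corr_for_distance(dist.ravel()).reshape(dist.shape)
                np.fill_diagonal(sigma, 1.0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pc = stouffer_liptak(base_p[members], sigma)
                rows.append(
                    {
                        "chromosome": c,
                        "start": int(mpos.min()),
                        "end": int(mpos.max()),
                        "probe_ids": list(probe_ids[members]),
                        "n_probes": int(len(members)),
                        "p_combined": pc,
                    }
                )
            run = [sel[ii]] if ii < len(sel) and adjusted_p[sel[ii]] < seed_p else []
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "probe_ids", "n_probes", "p_combined"]
    )


def region_pvalue_sidak(p_combined: float, region_span: int, total_span: int) -> float:
    """Sidak correction for the effective number of regions searched:
    1 - (1 - p)^(total_span / region_span), capped at 1."""
    if region_span <= 0 or total_span <= 0:
        raise ValueError("spans must be positive")
    m = total_span / region_span
    if p_combined <= 0:
        return 0.0
    if p_combined >= 1:
        return 1.0
    return float(min(1.0, -np.expm1(m * np.log1p(-p_combined))))


def _covered_span(chrom, pos, window: int) -> int:
    """Total bp covered by probes +- window, unioned per chromosome."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    total = 0
    for c in pd.unique(chrom):
        cp = np.sort(pos[chrom == c])
        start, end = cp[0] - window, cp[0] + window
        for x in cp[1:]:
            if x - window <= end:
                end = x + window
            else:
                total += end - start + 1
                start, end = x - window, x + window
        total += end - start + 1
    return int(total)


def call_dmrs(
    ewas_results: pd.DataFrame,
    manifest: pd.DataFrame,
    seed_p: float = 0.05,
    window: int = 1000,
    max_gap: int = 1000,
    acf_bin_width: int = 50,
    acf_max_dist: int = 1000,
) -> pd.DataFrame:
    """Full region pipeline from an EWAS result + probe manifest.

    Probes are ordered by (chromosome, position); the returned frame adds
    ``p_sidak`` (search-space corrected, with the search space the total
    probe-covered bp per chromosome) and ``q`` (BH-FDR over regions).
    """
    df = ewas_results.merge(
        manifest[["probe_id", "chromosome", "position"]], on="probe_id", how="inner"
    )
    df = df.dropna(subset=["p"]).sort_values(["chromosome", "position"], kind="mergesort")
    p = df["p"].to_numpy()
    chrom = df["chromosome"].to_numpy()
    pos = df["position"].to_numpy(dtype=np.int64)
    acf = estimate_acf(p, chrom, pos, max_dist=acf_max_dist, bin_width=acf_bin_width)
    adj = adjust_site_pvalues(p, chrom, pos, acf, window=window)
    regions = find_regions(
        adj, chrom, pos, acf, seed_p=seed_p, max_gap=max_gap, raw_p=p,
        probe_ids=df["probe_id"].to_numpy(),
    )
    if regions.empty:
        regions["p_sidak"] = pd.Series(dtype=float)
        regions["q"] = pd.Series(dtype=float)
        return regions
    total_span = _covered_span(chrom, pos, window)
    regions["p_sidak"] = [
        region_pvalue_sidak(pc, int(e - s + 1), total_span)
        for pc, s, e in zip(regions["p_combined"], regions["start"], regions["end"])
    ]
    regions["q"] = bh_fdr(regions["p_sidak"].to_numpy())
    return regions


def regions_to_bed(regions: pd.DataFrame) -> pd.DataFrame:
    """0-based half-open BED representation of a region table."""
    bed = pd.DataFrame(
        {
            "chrom": regions["chromosome"],
            "chromStart": regions["start"] - 1,
            "chromEnd": regions["end"],
            "name": [f"dmr{i}" for i in range(len(regions))],
            "score": np.minimum(1000, (-np.log10(np.clip(regions["p_sidak"], 1e-300, None)) * 100).astype(int)),
        }
    )
    return bed
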