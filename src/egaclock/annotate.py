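"""Nearest-gene / functional-category annotation and enrichment tests.

Probes are assigned to the gene with the smallest absolute distance to a
transcription start site (TSS) and to exactly one functional category out
of a fixed eleven-category scheme (promoter distance bands upstream of the
TSS, UTRs, exons, introns, a short downstream window past the gene end,
and distal intergenic). Category enrichment of a significant probe set
against the whole array uses one-sided hypergeometric tests; gene-set
enrichment restricts a Fisher exact test to the array's annotated-gene
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .ewas import bh_fdr

__all__ = [
    "GeneModel",
    "CATEGORIES",
    "assign_functional_category",
    "annotate_probes",
    "category_enrichment",
    "gene_set_enrichment",
    "read_gmt",
]

CATEGORIES = [
    "Promoter (<=1kb)",
    "Promoter (1-2kb)",
    "Promoter (2-3kb)",
    "5' UTR",
    "3' UTR",
    "1st Exon",
    "Other Exon",
    "1st Intron",
    "Other Intron",
    "Downstream (<=300)",
    "Distal Intergenic",
]

DOWNSTREAM_BP = 300
PROMOTER_BANDS = ((1, 1000), (1001, 2000), (2001, 3000))


@dataclass
class GeneModel:
    """A single-transcript gene model on genomic coordinates (1-based, inclusive).

    ``exons`` are non-overlapping (start, end) intervals in ascending genomic
    order; ``utr5``/``utr3`` are sub-intervals of the terminal exons (the
    synthetic generator fills them; real models may leave them ``None``).
    ``tss``/``tes`` are the transcription start/end: for ``+`` strand genes
    tss < tes, for ``-`` strand tss > tes.
    """

    gene: str
    chromosome: str
    strand: str
    tss: int
    tes: int
    exons: list = field(default_factory=list)
    utr5: tuple | None = None
    utr3: tuple | None = None

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def exons_in_transcription_order(self) -> list:
        return self.exons if self.strand == "+" else list(reversed(self.exons))


def _category_within_gene(pos: int, g: GeneModel) -> str | None:
    """Category for a probe relative to one gene, or None if unrelated."""
    # upstream promoter bands, strand-aware
    up = g.tss - pos if g.strand == "+" else pos - g.tss
    if up >= 1:
        for band, (lo, hi) in zip(CATEGORIES[:3], PROMOTER_BANDS):
            if lo <= up <= hi:
                return band
        return None
    if g.start <= pos <= g.end:
        if g.utr5 and g.utr5[0] <= pos <= g.utr5[1]:
            return "5' UTR"
        if g.utr3 and g.utr3[0] <= pos <= g.utr3[1]:
            return "3' UTR"
        exons = g.exons_in_transcription_order()
        for i, (s, e) in enumerate(exons):
            if s <= pos <= e:
                return "1st Exon" if i == 0 else "Other Exon"
        # inside the gene but in no exon: locate the intron index
        for i in range(len(exons) - 1):
            a, b = exons[i], exons[i + 1]
            lo, hi = (a[1], b[0]) if g.strand == "+" else (b[1], a[0])
            if lo < pos < hi:
                return "1st Intron" if i == 0 else "Other Intron"
        return "1st Intron" if len(exons) > 1 else None
    down = pos - g.tes if g.strand == "+" else g.tes - pos
    if 1 <= down <= DOWNSTREAM_BP:
        return "Downstream (<=300)"
    return None


def assign_functional_category(chromosome: str, position: int, gene_models) -> tuple:
    """Return ``(nearest_gene, category)`` for one probe.

    The nearest gene is the one with minimal absolute TSS distance on the
    probe's chromosome (ties broken alphabetically by gene symbol); the
    category is determined relative to that gene, falling back to
    ``Distal Intergenic`` when the probe lies outside all of its features.
    """
    candidates = [g for g in gene_models if g.chromosome == chromosome]
    if not candidates:
        return "", "Distal Intergenic"
    best = min(candidates, key=lambda g: (abs(g.tss - position), g.gene))
    cat = _category_within_gene(position, best)
    return best.gene, cat if cat is not None else "Distal Intergenic"


def annotate_probes(manifest: pd.DataFrame, gene_models) -> pd.DataFrame:
    """Fill ``gene`` and ``category`` columns of a probe manifest.

    Vectorized over probes by grouping per chromosome and using a sorted
    TSS index for nearest-gene lookup; category logic is then applied per
    probe against its single nearest gene.
    """
    man = manifest.copy()
    genes = np.empty(len(man), dtype=object)
    cats = np.empty(len(man), dtype=object)
    by_chrom: dict = {}
    for g in gene_models:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, sub in by_chrom.items():
        # sort by (tss, gene) so equidistant ties resolve alphabetically
        sub.sort(key=lambda g: (g.tss, g.gene))
    for chrom, idx in man.groupby("chromosome", sort=False).indices.items():
        models = by_chrom.get(chrom)
        if not models:
            genes[idx] = ""
            cats[idx] = "Distal Intergenic"
            continue
        tss = np.array([g.tss for g in models])
        pos = man["position"].to_numpy()[idx]
        right = np.searchsorted(tss, pos)
        for j, (p, r) in enumerate(zip(pos, right)):
            lo = max(r - 2, 0)
            hi = min(r + 2, len(models))
            best = min(models[lo:hi], key=lambda g: (abs(g.tss - p), g.gene))
            cat = _category_within_gene(int(p), best)
            genes[idx[j]] = best.gene
            cats[idx[j]] = cat if cat is not None else "Distal Intergenic"
    man["gene"] = genes
    man["category"] = cats
    return man


def category_enrichment(sig_probe_ids, all_probe_ids, manifest: pd.DataFrame) -> pd.DataFrame:
    """One-sided hypergeometric over/under-representation per category.

    With population N = all array probes, K probes of a category on the
    array, and n significant draws, the observed count x is tested with
    p_over = P(X >= x) and p_under = P(X <= x); the two one-sided tests
    share the mass at x, so p_over + p_under >= 1.
    """
    sig = set(sig_probe_ids)
    allp = set(all_probe_ids)
    if not sig <= allp:
        raise ValueError("significant probes must be a subset of the array probes")
    man = manifest[manifest["probe_id"].isin(allp)]
    cat_all = man.groupby("category")["probe_id"].apply(set)
    N, n = len(allp), len(sig)
    rows = []
    for cat in CATEGORIES:
        if cat not in cat_all.index:
            continue  # category absent from the array background
        members = cat_all[cat]
        K = len(members)
        obs = len(sig & members)
        rows.append(
            {
                "category": cat,
                "observed": obs,
                "array_count": K,
                "n_sig": n,
                "n_array": N,
                "observed_pct": 100.0 * obs / n if n else np.nan,
                "array_pct": 100.0 * K / N,
                "p_under": float(hypergeom.cdf(obs, N, K, n)),
                "p_over": float(hypergeom.sf(obs - 1, N, K, n)),
            }
        )
    return pd.DataFrame(rows)


def gene_set_enrichment(hit_genes, background_genes, gene_sets: dict) -> pd.DataFrame:
    """Fisher exact enrichment of hit genes in each gene set, restricted to
    a background (e.g., all genes annotated to probes on the array).

    The one-sided enrichment p for the 2x2 table (in set / not) x (hit /
    not) equals the hypergeometric upper tail. Sets with no background
    overlap are excluded (noted in the ``note`` column of the result).
    """
    bg = set(background_genes)
    hits = set(hit_genes)
    if not hits <= bg:
        raise ValueError("hit genes must be a subset of the background")
    rows = []
    for name, members in gene_sets.items():
        in_bg = set(members) & bg
        if not in_bg:
            rows.append(
                {"gene_set": name, "n_set": 0, "n_overlap": 0, "p": np.nan, "note": "no background overlap"}
            )
            continue
        a = len(hits & in_bg)
        p = float(hypergeom.sf(a - 1, len(bg), len(in_bg), len(hits)))
        rows.append(
            {"gene_set": name, "n_set": len(in_bg), "n_overlap": a, "p": p, "note": ""}
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> gene..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
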