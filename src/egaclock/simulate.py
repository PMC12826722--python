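"""Synthetic cord-blood methylation cohorts with known ground truth.

The generator emulates an array-scale methylation study of newborns:
gestational age (GA) drawn truncated-normal around a term mean, a sparse
set of causal CpGs whose M-values drift linearly with GA, latent factors
that can be made to confound GA, sex/ancestry effects on a probe subset,
per-probe noise, a probe manifest with QC flags and gene annotation, and
a sheet of prenatal/perinatal exposures with configurable GA effects.

Everything is driven by a single integer seed: the same
:class:`SimulationConfig` always yields bit-identical outputs, so the
downstream EWAS / DMR / clock / exposure machinery can be tested against
the recorded :class:`SyntheticTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .annotate import GeneModel, annotate_probes
from .preprocess import MethylationDataset, m_to_beta

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_gene_models",
    "simulate_manifest",
    "simulate_methylation",
    "simulate_exposures",
    "simulate_cohort",
]

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
SEX_CHROMS = ["chrX", "chrY"]
CHROM_LENGTH = 50_000_000  # synthetic chromosome span, bp

#: default exposure effects on GA, in days (delivery-mode and birth-weight
#: magnitudes mirror a term-birth cohort's strongest perinatal signals)
DEFAULT_EXPOSURE_EFFECTS = {
    "delivery_mode:Planned C-section": -4.38,
    "delivery_mode:Unplanned C-section": 3.29,
    "birthweight_z": 2.28,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults reproduce the shape of a term-birth cord-blood study: 391
    newborns, GA ~ truncated Normal(274, 11) days on (210, 300), an
    array of ~46k CpGs, 5% of probes causally tied to GA with slopes of
    SD 0.02 M-units/day, and three latent factors.
    """

    n_samples: int = 391
    n_probes: int = 45_954
    frac_causal: float = 0.05
    effect_sd: float = 0.02  # M-units per day, SD of causal slopes
    n_latent: int = 3
    confounding_strength: float = 0.0  # corr(latent_k, GA)
    ga_mean: float = 274.02
    ga_sd: float = 11.02
    ga_range: tuple = (210.0, 300.0)
    noise_sd_range: tuple = (0.2, 0.6)  # per-probe residual SD, M-units
    frac_sex_chrom: float = 0.03
    frac_snp_flagged: float = 0.01
    frac_off_target: float = 0.005
    # per-(probe, sample) failure rate; with ~400 samples and the
    # any-sample removal rule this drops ~0.4% of probes, the scale of
    # detection exclusions seen on real arrays
    detection_fail_rate: float = 1e-5
    latent_loading_sd: float = 0.1  # M-units per unit latent score
    n_genes: int = 1000
    exposure_effects: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_causal",
            "frac_sex_chrom",
            "frac_snp_flagged",
            "frac_off_target",
            "detection_fail_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1 <= self.confounding_strength <= 1:
            raise ValueError("confounding_strength must be in [-1, 1]")
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10")
        if self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_probes and n_genes must be positive")
        lo, hi = self.ga_range
        if not (lo <= self.ga_mean <= hi):
            raise ValueError("ga_range must contain ga_mean")
        if self.noise_sd_range[0] <= 0 or self.noise_sd_range[1] < self.noise_sd_range[0]:
            raise ValueError("noise_sd_range must be positive and ordered")
        if self.exposure_effects is None:
            self.exposure_effects = dict(DEFAULT_EXPOSURE_EFFECTS)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ga_range"] = list(d["ga_range"])
        d["noise_sd_range"] = list(d["noise_sd_range"])
        return d


@dataclass
class SyntheticTruth:
    """Generative parameters recorded alongside a synthetic dataset."""

    causal_probe_ids: list
    causal_slopes: pd.Series  # indexed by causal probe id, M-units/day
    latent_scores: np.ndarray  # n_samples x n_latent
    latent_loadings: np.ndarray  # n_probes x n_latent
    exposure_effects: dict
    sex_effect_probes: list = field(default_factory=list)
    race_effect_probes: list = field(default_factory=list)

    def slopes_full(self, probe_ids) -> pd.Series:
        """Per-probe slope over all probes (exactly 0 off the causal set)."""
        s = pd.Series(0.0, index=pd.Index(probe_ids, name="probe_id"))
        s.loc[self.causal_slopes.index] = self.causal_slopes.to_numpy()
        return s

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_probe_ids": list(self.causal_probe_ids),
                "causal_slopes": self.causal_slopes.to_dict(),
                "latent_scores": self.latent_scores.tolist(),
                "latent_loadings": self.latent_loadings.tolist(),
                "exposure_effects": self.exposure_effects,
                "sex_effect_probes": list(self.sex_effect_probes),
                "race_effect_probes": list(self.race_effect_probes),
            }
        )


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def simulate_gene_models(config: SimulationConfig) -> list:
    """Draw synthetic single-transcript gene models across the chromosomes.

    Genes get 2-8 exons of 100-500 bp separated by 0.5-5 kb introns, a
    5' UTR occupying the leading half of the first exon and a 3' UTR the
    trailing half of the last, random strand, and TSS positions spread
    uniformly along each chromosome. Deterministic in the config seed.
    """
    rng = _rng(config, 1)
    chroms = AUTOSOMES + SEX_CHROMS
    # allocate genes to chromosomes roughly evenly, sex chroms included
    assignment = rng.integers(0, len(chroms), size=config.n_genes)
    models = []
    for i in range(config.n_genes):
        chrom = chroms[assignment[i]]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 9))
        exon_lens = rng.integers(100, 501, size=n_exons)
        intron_lens = rng.integers(500, 5001, size=n_exons - 1)
        anchor = int(rng.integers(10_000, CHROM_LENGTH - 100_000))
        # build exon coordinates in transcription order, then orient
        starts, cur = [], anchor
        exons_tx = []
        for k in range(n_exons):
            exons_tx.append((cur, cur + int(exon_lens[k]) - 1))
            if k < n_exons - 1:
                cur = exons_tx[-1][1] + 1 + int(intron_lens[k])
        if strand == "+":
            exons = exons_tx
            tss, tes = exons[0][0], exons[-1][1]
            first, last = exons[0], exons[-1]
        else:
            # mirror so transcription runs right-to-left
            span_end = exons_tx[-1][1]
            exons = sorted(
                ((anchor + (span_end - e)), (anchor + (span_end - s))) for s, e in exons_tx
            )
            tss, tes = exons[-1][1], exons[0][0]
            first, last = exons[-1], exons[0]

        def _half(interval, leading, strand_):
            s, e = interval
            mid = (s + e) // 2
            if (strand_ == "+") == leading:
                return (s, mid)
            return (mid + 1, e)

        utr5 = _half(first, True, strand) if strand == "+" else _half(first, False, strand)
        utr3 = _half(last, False, strand) if strand == "+" else _half(last, True, strand)
        models.append(
            GeneModel(
                gene=f"GENE{i:05d}",
                chromosome=chrom,
                strand=strand,
                tss=int(tss),
                tes=int(tes),
                exons=[(int(s), int(e)) for s, e in exons],
                utr5=(int(utr5[0]), int(utr5[1])),
                utr3=(int(utr3[0]), int(utr3[1])),
            )
        )
    return models


def simulate_manifest(config: SimulationConfig, gene_models=None) -> pd.DataFrame:
    """Synthetic probe manifest: positions, QC flags, gene/category annotation.

    Exactly ``round(frac_sex_chrom * n_probes)`` probes land on sex
    chromosomes; SNP and off-target flags are Bernoulli draws. Probe
    positions mix gene-anchored placements (promoter/body/downstream
    offsets from a random gene) with uniform intergenic positions, and are
    sorted within chromosome. Categories come from
    :func:`egaclock.annotate.annotate_probes` on the same gene models, so
    re-deriving a category from a probe's coordinates is an exact
    round-trip.
    """
    if gene_models is None:
        gene_models = simulate_gene_models(config)
    rng = _rng(config, 2)
    n = config.n_probes
    n_sex = int(round(config.frac_sex_chrom * n))
    sex_genes = [g for g in gene_models if g.chromosome in SEX_CHROMS]
    auto_genes = [g for g in gene_models if g.chromosome in AUTOSOMES]

    def _positions(genes, count, chrom_pool):
        chroms, pos = [], []
        anchored = int(round(0.8 * count)) if genes else 0
        if anchored:
            pick = rng.integers(0, len(genes), size=anchored)
            offs = rng.integers(-3500, 3501, size=anchored)
            for gi, off in zip(pick, offs):
                g = genes[gi]
                p = int(np.clip(g.tss + int(off), 1, CHROM_LENGTH))
                chroms.append(g.chromosome)
                pos.append(p)
        for _ in range(count - anchored):
            chroms.append(chrom_pool[rng.integers(0, len(chrom_pool))])
            pos.append(int(rng.integers(1, CHROM_LENGTH)))
        return chroms, pos

    c1, p1 = _positions(auto_genes, n - n_sex, AUTOSOMES)
    c2, p2 = _positions(sex_genes, n_sex, SEX_CHROMS)
    man = pd.DataFrame(
        {
            "chromosome": c1 + c2,
            "position": p1 + p2,
            "sex_chromosome": [False] * (n - n_sex) + [True] * n_sex,
        }
    )
    # deduplicate positions within chromosome to keep probes distinct
    man["position"] += man.groupby(["chromosome", "position"]).cumcount()
    man = man.sort_values(["chromosome", "position"], kind="mergesort").reset_index(drop=True)
    man.insert(0, "probe_id", [f"cg{i:08d}" for i in range(n)])
    snp = rng.random(n) < config.frac_snp_flagged
    side = rng.random(n) < 0.5
    man["snp_3p_flag"] = snp & side
    man["snp_5p_flag"] = snp & ~side
    man["off_target"] = rng.random(n) < config.frac_off_target
    man["detection_fail_fraction"] = 0.0
    man = annotate_probes(man, gene_models)
    return man


def simulate_methylation(config: SimulationConfig, manifest: pd.DataFrame):
    """Generate the methylation matrix and its ground truth.

    The M-value of probe j in sample i is

        baseline_j + slope_j * (GA_i - ga_mean) + loadings_j . latent_i
        + sex/race shifts (for a designated 2% probe subset each)
        + Normal(0, sd_j) noise,

    with GA truncated-normal and each latent factor correlated with GA at
    ``confounding_strength`` (drawn jointly in z-space). Beta values are
    the inverse-logit of M; baselines are drawn so betas concentrate in
    (0.05, 0.95). Detection failures hit ``detection_fail_rate`` of
    (probe, sample) pairs and are recorded as per-probe fail fractions in
    the returned dataset's manifest.

    Returns ``(MethylationDataset on the beta scale, SyntheticTruth)``.
    """
    # independent sub-streams per component, so e.g. setting effect_sd=0
    # yields a matrix identical to frac_causal=0 under the same seed
    rng_ga = _rng(config, 30)
    rng_lat = _rng(config, 31)
    rng_cov = _rng(config, 32)
    rng_causal = _rng(config, 33)
    rng_base = _rng(config, 34)
    rng_noise = _rng(config, 35)
    rng_detect = _rng(config, 36)
    n, p = config.n_samples, config.n_probes
    if len(manifest) != p:
        raise ValueError("manifest size does not match config.n_probes")
    lo, hi = config.ga_range
    a, b = (lo - config.ga_mean) / config.ga_sd, (hi - config.ga_mean) / config.ga_sd
    z_ga = truncnorm.rvs(a, b, size=n, random_state=rng_ga)
    ga = config.ga_mean + config.ga_sd * z_ga

    c = config.confounding_strength
    latent = np.empty((n, config.n_latent))
    for k in range(config.n_latent):
        latent[:, k] = c * z_ga + np.sqrt(max(1 - c**2, 0.0)) * rng_lat.standard_normal(n)
    loadings = rng_lat.normal(0.0, config.latent_loading_sd, size=(p, config.n_latent))

    sex = np.where(rng_cov.random(n) < 0.51, "male", "female")
    race = rng_cov.choice(
        ["African American", "European American", "Other"], size=n, p=[0.62, 0.24, 0.14]
    )

    n_causal = int(round(config.frac_causal * p))
    causal_idx = (
        rng_causal.choice(p, size=n_causal, replace=False) if n_causal else np.array([], int)
    )
    slopes = np.zeros(p)
    if n_causal:
        slopes[causal_idx] = rng_causal.normal(0.0, config.effect_sd, size=n_causal)

    n_covar = max(int(round(0.02 * p)), 0)
    sex_idx = rng_cov.choice(p, size=n_covar, replace=False) if n_covar else np.array([], int)
    race_idx = rng_cov.choice(p, size=n_covar, replace=False) if n_covar else np.array([], int)
    sex_eff = np.zeros(p)
    sex_eff[sex_idx] = rng_cov.normal(0.0, 0.15, size=len(sex_idx))
    race_eff = np.zeros((p, 2))
    race_eff[race_idx] = rng_cov.normal(0.0, 0.15, size=(len(race_idx), 2))

    baseline_beta = rng_base.uniform(0.1, 0.9, size=p)
    baseline = np.log2(baseline_beta / (1 - baseline_beta))
    noise_sd = rng_base.uniform(*config.noise_sd_range, size=p)

    is_male = (sex == "male").astype(float)
    race_d = np.column_stack(
        [(race == "European American").astype(float), (race == "Other").astype(float)]
    )
    M = (
        baseline[:, None]
        + slopes[:, None] * (ga - config.ga_mean)[None, :]
        + loadings @ latent.T
        + sex_eff[:, None] * is_male[None, :]
        + race_eff @ race_d.T
        + rng_noise.standard_normal((p, n)) * noise_sd[:, None]
    )
    beta = m_to_beta(M)

    fail = rng_detect.random((p, n)) < config.detection_fail_rate
    man = manifest.copy()
    man["detection_fail_fraction"] = fail.mean(axis=1)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "ga_days": ga, "sex": sex, "race": race}
    )
    ds = MethylationDataset(
        values=pd.DataFrame(beta, index=man["probe_id"].to_numpy(), columns=sample_ids),
        manifest=man,
        samples=samples,
        scale="beta",
    )
    probe_ids = man["probe_id"].to_numpy()
    truth = SyntheticTruth(
        causal_probe_ids=list(probe_ids[causal_idx]),
        causal_slopes=pd.Series(slopes[causal_idx], index=probe_ids[causal_idx]),
        latent_scores=latent,
        latent_loadings=loadings,
        exposure_effects=dict(config.exposure_effects),
        sex_effect_probes=list(probe_ids[sex_idx]),
        race_effect_probes=list(probe_ids[race_idx]),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# exposures

# (name, kind, spec): binary -> prevalence; categorical -> {level: prob}
# (first level is the reference); continuous -> (mean, sd)
EXPOSURE_SHEET = [
    ("maternal_age", "continuous", (29.98, 5.30)),
    ("paternal_age", "continuous", (32.57, 6.86)),
    ("bmi_first", "continuous", (30.51, 8.36)),
    ("bmi_last", "continuous", (34.95, 7.89)),
    ("birthweight_z", "continuous", (0.0, 1.0)),
    ("parity", "continuous", (1.09, 1.13)),
    ("marital_status", "categorical", {"Not Married": 0.33, "Married": 0.67}),
    ("urban_residence", "categorical", {"Suburban": 0.44, "Urban": 0.56}),
    (
        "household_income",
        "categorical",
        {"<20k": 0.13, "20-40k": 0.21, "40-80k": 0.27, "80-100k": 0.13, ">=100k": 0.14, "refused": 0.12},
    ),
    (
        "maternal_education",
        "categorical",
        {"<=HS": 0.04, "HS": 0.14, "Some college": 0.47, "Bachelors": 0.35},
    ),
    (
        "delivery_mode",
        "categorical",
        {"Vaginal": 0.64, "Planned C-section": 0.19, "Unplanned C-section": 0.17},
    ),
    ("first_born", "categorical", {"No": 0.65, "Yes": 0.35}),
    (
        "prev_live_births",
        "categorical",
        {"0": 0.23, "1": 0.24, "2": 0.25, "3": 0.14, ">=4": 0.14},
    ),
    ("infant_sex", "categorical", {"male": 0.51, "female": 0.49}),
    ("antibiotic_use", "categorical", {"No": 0.45, "Yes": 0.55}),
    ("antifungal_use", "categorical", {"No": 0.82, "Yes": 0.18}),
    ("ets", "categorical", {"No": 0.75, "Yes": 0.25}),
    ("mom_smoking", "categorical", {"No": 0.89, "Yes": 0.11}),
    ("indoor_pets", "categorical", {"No": 0.63, "Yes": 0.37}),
    ("outdoor_pets", "categorical", {"No": 0.96, "Yes": 0.04}),
    (
        "maternal_race",
        "categorical",
        {"African American": 0.61, "European American": 0.24, "Other": 0.15},
    ),
    (
        "infant_race",
        "categorical",
        {"African American": 0.62, "European American": 0.24, "Other": 0.14},
    ),
]


def simulate_exposures(
    config: SimulationConfig, ga: np.ndarray, truth: SyntheticTruth | None = None
) -> pd.DataFrame:
    """Draw the 22-column prenatal/perinatal exposure sheet.

    Exposures named in ``truth.exposure_effects`` (``"name"`` for
    continuous/binary, ``"name:level"`` for one level of a categorical)
    are tilted against the supplied GA vector so that the single-exposure
    regression coefficient equals the stated effect (days) in expectation;
    all other exposures are drawn independently of GA.

    For a categorical exposure the level probabilities are exponentially
    tilted, ``P(level | GA) ~ pi_level * exp(delta_level * (GA - mean)/var(GA))``,
    which for near-Gaussian GA shifts the conditional GA mean of a level by
    ``delta_level`` relative to the reference. Continuous exposures gain a
    ``delta * (GA - mean) * sd_x^2 / var(GA)`` component, giving a GA-on-X
    slope of ``delta`` days per unit.
    """
    rng = _rng(config, 4)
    ga = np.asarray(ga, dtype=float)
    n = ga.size
    if n != config.n_samples:
        raise ValueError("ga length must equal config.n_samples")
    effects = dict(truth.exposure_effects) if truth is not None else {}
    ga_c = ga - ga.mean()
    ga_var = ga.var() if n > 1 else 1.0
    out = {}
    for name, kind, spec in EXPOSURE_SHEET:
        if kind == "continuous":
            mu, sd = spec
            delta = effects.get(name, 0.0)
            x = mu + delta * (sd**2) * ga_c / ga_var + rng.normal(
                0.0, np.sqrt(max(sd**2 - (delta * sd**2 / np.sqrt(ga_var)) ** 2, 1e-12)), size=n
            )
            out[name] = x
        else:
            levels = list(spec.keys())
            base = np.array(list(spec.values()), dtype=float)
            base = base / base.sum()
            deltas = np.array([effects.get(f"{name}:{lev}", 0.0) for lev in levels])
            if np.any(deltas):
                w = base[None, :] * np.exp(np.outer(ga_c / ga_var, deltas))
                w = w / w.sum(axis=1, keepdims=True)
                draws = np.array([rng.choice(len(levels), p=w[i]) for i in range(n)])
            else:
                draws = rng.choice(len(levels), size=n, p=base)
            out[name] = pd.Categorical.from_codes(draws, categories=levels)
    df = pd.DataFrame(out)
    df.insert(0, "sample_id", [f"S{i:04d}" for i in range(n)])
    return df


def plant_cluster(
    ds: MethylationDataset,
    slope: float = 0.03,
    n_cluster: int = 5,
    max_gap: int = 300,
    seed: int = 0,
):
    """Impose a shared GA slope on a run of adjacent probes (a true DMR).

    Scans the manifest for a window of ``n_cluster`` consecutive probes on
    one chromosome with inter-probe gaps at most ``max_gap`` bp, picks one
    such window at random, and adds ``slope * (GA - mean GA)`` to those
    probes' M-values. Returns ``(modified dataset, cluster probe ids)``.
    Used by the region-calling recovery experiments.
    """
    rng = np.random.default_rng(seed)
    man = ds.manifest
    candidates = []
    for _, grp in man.groupby("chromosome", sort=False):
        pos = grp["position"].to_numpy()
        idx = grp.index.to_numpy()
        for i in range(len(pos) - n_cluster + 1):
            gaps = np.diff(pos[i : i + n_cluster])
            if len(gaps) and gaps.max() <= max_gap:
                candidates.append(idx[i : i + n_cluster])
    if not candidates:
        raise ValueError("no sufficiently tight probe cluster in the manifest")
    chosen = candidates[rng.integers(0, len(candidates))]
    cluster_ids = list(man.loc[chosen, "probe_id"])
    ga = ds.samples["ga_days"].to_numpy(dtype=float)
    m_ds = ds.to_m()
    vals = m_ds.values.copy()
    vals.loc[cluster_ids] = vals.loc[cluster_ids].to_numpy() + slope * (ga - ga.mean())[None, :]
    out = MethylationDataset(vals, m_ds.manifest, m_ds.samples, scale="M")
    if ds.scale == "beta":
        out = out.to_beta()
    return out, cluster_ids


def simulate_cohort(config: SimulationConfig):
    """Full cohort draw: (dataset, truth, exposures, gene_models)."""
    gene_models = simulate_gene_models(config)
    manifest = simulate_manifest(config, gene_models)
    ds, truth = simulate_methylation(config, manifest)
    exposures = simulate_exposures(config, ds.samples["ga_days"].to_numpy(), truth)
    samples = ds.samples.merge(exposures, on="sample_id")
    ds = MethylationDataset(ds.values, ds.manifest, samples, scale=ds.scale)
    return ds, truth, exposures, gene_models
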