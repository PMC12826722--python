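import numpy as np
import pandas as pd
import pytest

import egaclock as eg


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = eg.SimulationConfig(
        n_samples=60, n_probes=400, n_genes=60, seed=42, detection_fail_rate=0.002
    )
    ds, truth, exposures, gene_models = eg.simulate_cohort(cfg)
    return cfg, ds, truth, exposures, gene_models


@pytest.fixture()
def toy_manifest():
    """Hand-built 10-probe manifest: 2 sex-chromosome probes, 1 SNP-flagged,
    1 with detection failures, no overlaps -> 6 survive default QC."""
    n = 10
    man = pd.DataFrame(
        {
            "probe_id": [f"cg{i:03d}" for i in range(n)],
            "chromosome": ["chr1"] * 8 + ["chrX", "chrY"],
            "position": list(range(100, 100 + 8 * 50, 50)) + [100, 100],
            "snp_3p_flag": [True] + [False] * 9,
            "snp_5p_flag": [False] * 10,
            "sex_chromosome": [False] * 8 + [True, True],
            "off_target": [False] * 10,
            "detection_fail_fraction": [0.0, 0.5] + [0.0] * 8,
        }
    )
    return man


def make_dataset(manifest, n_samples=4, seed=0, scale="beta"):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.1, 0.9, size=(len(manifest), n_samples))
    sample_ids = [f"S{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ga_days": rng.normal(274, 11, n_samples),
            "sex": rng.choice(["male", "female"], n_samples),
            "race": rng.choice(["A", "B"], n_samples),
        }
    )
    return eg.MethylationDataset(
        values=pd.DataFrame(vals, index=manifest["probe_id"].to_numpy(), columns=sample_ids),
        manifest=manifest,
        samples=samples,
        scale=scale,
    )
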