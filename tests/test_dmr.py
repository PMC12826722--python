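import numpy as np
import pandas as pd
import pytest
from scipy.special import erfc, ndtri
from scipy.stats import norm

import egaclock as eg
from egaclock.dmr import AcfEstimate, _covered_span


def slk_oracle(p, sigma):
    """Independent arithmetic path for the correlated combination."""
    z = np.array([ndtri(1 - pi) for pi in np.clip(p, 1e-15, 1 - 1e-15)])
    zc = z.sum() / np.sqrt(np.sum(sigma))
    return 0.5 * erfc(zc / np.sqrt(2))


def flat_acf(corr=0.0, max_dist=1000, bin_width=50):
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n = len(edges) - 1
    return AcfEstimate(
        bin_edges=edges,
        correlations=np.full(n, corr),
        n_pairs=np.full(n, 100),
        low_count_flags=np.zeros(n, bool),
    )


class TestStoufferLiptak:
    def test_single_p_identity(self):
        assert eg.stouffer_liptak([0.37]) == pytest.approx(0.37, abs=1e-12)

    def test_two_halves_independent(self):
        assert eg.stouffer_liptak([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_small_independent(self):
        expected = norm.sf(2 * norm.isf(0.05) / np.sqrt(2))  # ~0.0100
        assert eg.stouffer_liptak([0.05, 0.05]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0100, abs=2e-4)

    def test_fully_correlated_redundant(self):
        sigma = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert eg.stouffer_liptak([0.05, 0.05], sigma) == pytest.approx(0.05, abs=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            eg.stouffer_liptak([])

    def test_matches_oracle_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(1, 6))
            p = rng.uniform(0.001, 0.999, size=k)
            A = rng.normal(size=(k, k))
            S = A @ A.T
            d = np.sqrt(np.diag(S))
            sigma = S / np.outer(d, d)
            assert eg.stouffer_liptak(p, sigma) == pytest.approx(
                slk_oracle(p, sigma), abs=1e-10
            )

    def test_monotone_in_each_p(self):
        rng = np.random.default_rng(3)
        sigma = np.array([[1, 0.3, 0.1], [0.3, 1, 0.2], [0.1, 0.2, 1.0]])
        for _ in range(50):
            p = rng.uniform(0.05, 0.95, size=3)
            base = eg.stouffer_liptak(p, sigma)
            for i in range(3):
                smaller = p.copy()
                smaller[i] *= 0.5
                assert eg.stouffer_liptak(smaller, sigma) <= base + 1e-12

    def test_non_psd_repaired_with_warning(self):
        sigma = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.warns(UserWarning):
            out = eg.stouffer_liptak([0.1, 0.2, 0.3], sigma)
        assert 0 <= out <= 1


class TestAcf:
    def test_null_correlations_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        # dense spacing so every bin collects thousands of pairs and the
        # Monte-Carlo error on each correlation stays well below 0.1
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=n, replace=False))
        p = rng.uniform(size=n)
        acf = eg.estimate_acf(p, np.array(["chr1"] * n), pos)
        assert np.all(np.abs(acf.correlations[~acf.low_count_flags]) < 0.1)

    def test_duplicated_probes_force_first_bin(self):
        rng = np.random.default_rng(1)
        base_pos = np.arange(1000, 21000, 1000)
        base_p = rng.uniform(size=base_pos.size)
        pos = np.sort(np.concatenate([base_pos, base_pos + 1]))
        p = np.repeat(base_p, 2)
        acf = eg.estimate_acf(p, np.array(["chr1"] * pos.size), pos)
        assert acf.correlations[0] == pytest.approx(1.0)

    def test_degenerate_distance_rejected(self):
        with pytest.raises(ValueError):
            eg.estimate_acf([0.5], ["chr1"], [100], max_dist=0)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            eg.estimate_acf([0.5, 0.5], ["chr1", "chr1"], [200, 100])

    def test_sparse_bins_flagged_zero(self):
        acf = eg.estimate_acf(
            [0.1, 0.2], ["chr1", "chr1"], [100, 150], max_dist=1000, bin_width=50
        )
        assert acf.low_count_flags.all()
        assert np.all(acf.correlations == 0)


class TestAdjustSites:
    def test_isolated_probe_unchanged(self):
        acf = flat_acf()
        p = np.array([0.3, 0.7])
        adj = eg.adjust_site_pvalues(p, ["chr1", "chr2"], [100, 100], acf)
        np.testing.assert_allclose(adj, p)

    def test_concordant_neighbors_strengthen(self):
        acf = flat_acf(0.0)
        p = np.array([0.01, 0.01, 0.01])
        adj = eg.adjust_site_pvalues(p, ["chr1"] * 3, [100, 200, 300], acf)
        assert adj[1] < 0.01

    def test_matches_per_site_oracle(self):
        """Six-probe toy agrees with a direct per-site combination."""
        acf = flat_acf(0.2)
        rng = np.random.default_rng(5)
        pos = np.array([100, 300, 450, 5000, 5200, 9000])
        p = rng.uniform(0.001, 0.9, size=6)
        chrom = np.array(["chr1"] * 6)
        adj = eg.adjust_site_pvalues(p, chrom, pos, acf, window=1000)
        for i in range(6):
            members = [j for j in range(6) if abs(pos[j] - pos[i]) <= 1000]
            sub = pos[members]
            d = np.abs(sub[:, None] - sub[None, :])
            sigma = acf.corr_for_distance(d.ravel()).reshape(d.shape)
            np.fill_diagonal(sigma, 1.0)
            assert adj[i] == pytest.approx(slk_oracle(p[members], sigma), abs=1e-10)


class TestFindRegions:
    def test_no_seed_probes_empty(self):
        acf = flat_acf()
        out = eg.find_regions([0.5, 0.6], ["chr1"] * 2, [100, 200], acf)
        assert out.empty

    def test_three_probe_region(self):
        acf = flat_acf()
        out = eg.find_regions(
            [0.001, 0.001, 0.001], ["chr1"] * 3, [100, 200, 300], acf, max_gap=500
        )
        assert len(out) == 1
        assert out.iloc[0]["n_probes"] == 3
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 300)

    def test_broken_run_drops_singletons(self):
        acf = flat_acf()
        out = eg.find_regions(
            [0.001, 0.9, 0.001], ["chr1"] * 3, [100, 200, 300], acf, max_gap=500
        )
        assert out.empty

    def test_gap_rule_splits(self):
        acf = flat_acf()
        out = eg.find_regions(
            [0.001] * 4, ["chr1"] * 4, [100, 200, 5000, 5100], acf, max_gap=500
        )
        assert len(out) == 2


class TestSidak:
    def test_whole_span_identity(self):
        assert eg.region_pvalue_sidak(0.01, 1000, 1000) == pytest.approx(0.01)

    def test_zero_p(self):
        assert eg.region_pvalue_sidak(0.0, 10, 100000) == 0.0

    def test_closed_form(self):
        val = eg.region_pvalue_sidak(0.001, 500, 1_000_000)
        assert val == pytest.approx(1 - 0.999**2000, rel=1e-9)
        assert val == pytest.approx(0.8648, abs=1e-3)

    def test_covered_span_unions_overlaps(self):
        # intervals [0, 2000] and [500, 2500] merge into [0, 2500]
        span = _covered_span(np.array(["chr1"] * 2), np.array([1000, 1500]), window=1000)
        assert span == 2501


class TestCallDmrs:
    def test_planted_cluster_recovered(self):
        from egaclock.simulate import plant_cluster

        cfg = eg.SimulationConfig(
            n_samples=300, n_probes=1500, frac_causal=0, n_latent=0,
            n_genes=100, seed=21, detection_fail_rate=0,
        )
        ds, _ = eg.simulate_methylation(cfg, eg.simulate_manifest(cfg))
        planted, cluster = plant_cluster(ds, slope=0.03, seed=2)
        res = eg.run_ewas(planted.to_m())
        regions = eg.call_dmrs(res, planted.manifest)
        sig = regions[regions["q"] < 0.05]
        assert any(len(set(r) & set(cluster)) >= 1 for r in sig["probe_ids"])
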