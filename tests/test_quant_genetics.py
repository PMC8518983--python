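"""REML variance components, SNP QC, kinship and mixed-model scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootecon import (
    GenotypeData,
    SimulationConfig,
    VarianceComponents,
    broad_sense_h2,
    candidate_windows,
    declare_significant,
    filter_markers,
    fit_rcbd_reml,
    genomic_inflation,
    lmm_scan,
    mv_lmm_scan,
    pc_gwas,
    relatedness_matrix,
    simulate_genotypes,
    simulate_traits,
)


def anova_sigma_g2(plants, value_col="trait_1"):
    """Balanced-design ANOVA oracle: (MS_genotype - MS_error) / r."""
    y = plants.pivot(index="genotype_id", columns="block_id", values=value_col).to_numpy()
    g, b = y.shape
    grand = y.mean()
    ms_g = b * ((y.mean(axis=1) - grand) ** 2).sum() / (g - 1)
    sse = ((y - y.mean(1)[:, None] - y.mean(0)[None, :] + grand) ** 2).sum()
    ms_e = sse / ((g - 1) * (b - 1))
    return max((ms_g - ms_e) / b, 0.0), ms_e


class TestRcbdReml:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equals_balanced_anova_oracle(self, small_genotypes, seed):
        plants, _ = simulate_traits(
            small_genotypes, sigma_g2=1.0, sigma_e2=3.0,
            block_effects=(0.0, 1.0, -0.5, 0.3), seed=seed,
        )
        vc = fit_rcbd_reml(plants)
        sg2, se2 = anova_sigma_g2(plants)
        assert vc.sigma_g2 == pytest.approx(sg2, abs=1e-6)
        assert vc.sigma_e2 == pytest.approx(se2, abs=1e-6)

    def test_pure_noise_estimates_near_zero(self, small_genotypes):
        ests = []
        for seed in range(7):
            plants, _ = simulate_traits(small_genotypes, sigma_g2=0.0, sigma_e2=1.0, seed=seed)
            vc = fit_rcbd_reml(plants)
            ests.append(vc.sigma_g2 / vc.sigma_e2)
        assert np.median(ests) < 0.05

    def test_no_genetic_signal_variance_of_means(self, small_genotypes):
        plants, _ = simulate_traits(small_genotypes, sigma_g2=0.0, sigma_e2=1.0, seed=5)
        gm = plants.groupby("genotype_id")["trait_1"].mean()
        assert gm.var() == pytest.approx(1.0 / 4.0, rel=0.5)

    def test_recovery_without_bias_over_replicates(self):
        """Panel-scale recovery: < 5% bias over 200 simulated studies."""
        cfg = SimulationConfig(n_genotypes=276, n_blocks=4, n_markers=2,
                               n_chromosomes=1, missing_rate=0.0, seed=0)
        G = simulate_genotypes(cfg)
        sg, se = [], []
        for rep in range(200):
            plants, _ = simulate_traits(G, sigma_g2=1.0, sigma_e2=3.0, seed=rep)
            vc = fit_rcbd_reml(plants)
            sg.append(vc.sigma_g2)
            se.append(vc.sigma_e2)
        assert abs(np.mean(sg) - 1.0) < 0.05
        assert abs(np.mean(se) - 3.0) < 0.05 * 3.0

    def test_all_missing_trait_is_error(self, small_genotypes):
        plants, _ = simulate_traits(small_genotypes, seed=1)
        plants["trait_1"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            fit_rcbd_reml(plants)


class TestBroadSenseH2:
    @pytest.mark.parametrize(
        "sg2,se2,r,expected",
        [(1.0, 1.0, 4, 0.8), (0.0, 1.0, 4, 0.0), (1.0, 3.0, 4, 4.0 / 7.0)],
    )
    def test_formula(self, sg2, se2, r, expected):
        vc = VarianceComponents(sg2, se2, r, 0.0)
        assert broad_sense_h2(vc) == pytest.approx(expected, abs=1e-10)


class TestFilterMarkers:
    def make(self, dosage_cols):
        n_g = len(dosage_cols[0])
        mat = np.array(dosage_cols, dtype=float).T
        mmap = pd.DataFrame({
            "marker_id": [f"m{j}" for j in range(len(dosage_cols))],
            "chrom": "chr1", "pos": np.arange(1, len(dosage_cols) + 1) * 100,
        })
        return GenotypeData(mat, [f"g{i}" for i in range(n_g)], mmap)

    def test_majority_missing_dropped(self):
        nan = np.nan
        G = self.make([
            [nan, nan, nan, nan, nan, nan, 1, 1, 2, 0],  # 60% missing
            [0, 1, 2, 1, 0, 1, 1, 1, 2, 0],
        ])
        filt, report = filter_markers(G)
        assert list(filt.marker_map["marker_id"]) == ["m1"]
        assert report["n_dropped_missing"] == 1

    def test_maf_exactly_at_threshold_kept(self):
        # 10 genotypes, one heterozygote -> freq 1/20 = 0.05 exactly
        G = self.make([
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # monomorphic
        ])
        filt, report = filter_markers(G)
        assert list(filt.marker_map["marker_id"]) == ["m0"]
        assert report["n_dropped_maf"] == 1

    def test_idempotent(self, small_genotypes):
        once, _ = filter_markers(small_genotypes)
        twice, report = filter_markers(once)
        assert twice.n_markers == once.n_markers
        assert report["n_dropped_maf"] == 0 and report["n_dropped_missing"] == 0

    def test_all_dropped_is_error(self):
        G = self.make([[0, 0, 0, 0, 0, 0, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="all markers"):
            filter_markers(G)


class TestRelatednessMatrix:
    def test_identical_genotypes_identical_rows(self, small_genotypes):
        X = small_genotypes.imputed()
        X[1, :] = X[0, :]
        G = GenotypeData(X, small_genotypes.genotype_ids, small_genotypes.marker_map)
        K = relatedness_matrix(G)
        assert np.allclose(K[0], K[1])
        assert np.allclose(K[:, 0], K[:, 1])

    def test_mean_diagonal_equals_mean_marker_variance(self, small_genotypes):
        K = relatedness_matrix(small_genotypes)
        W = small_genotypes.imputed()
        W = W - W.mean(axis=0)
        marker_var = (W**2).mean(axis=0)
        assert np.mean(np.diag(K)) == pytest.approx(marker_var.mean(), rel=1e-10)

    def test_symmetric_psd(self, small_genotypes):
        K = relatedness_matrix(small_genotypes)
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestLmmScan:
    def test_identity_kinship_equals_plain_regression(self, small_genotypes, rng):
        y = pd.Series(rng.normal(0, 1, 60), index=small_genotypes.genotype_ids)
        res = lmm_scan(y, small_genotypes, K=np.eye(60))
        X = small_genotypes.imputed()
        yv = y.to_numpy()
        for j in range(0, small_genotypes.n_markers, 7):
            A = np.column_stack([np.ones(60), X[:, j]])
            beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
            r = yv - A @ beta
            s2 = (r @ r) / (60 - 2)
            se2 = s2 * np.linalg.inv(A.T @ A)[1, 1]
            p = stats.chi2.sf(beta[1] ** 2 / se2, 1)
            assert res["p_wald"].iloc[j] == pytest.approx(p, abs=1e-6)

    def test_exact_mode_close_to_reused_lambda(self, small_genotypes):
        plants, _ = simulate_traits(small_genotypes, sigma_g2=1.0, sigma_e2=1.0, seed=3)
        gm = plants.groupby("genotype_id")["trait_1"].mean()
        sub = small_genotypes.subset_markers(np.arange(120) < 15)
        K = relatedness_matrix(small_genotypes)
        fast = lmm_scan(gm, sub, K=K)
        exact = lmm_scan(gm, sub, K=K, reuse_null_lambda=False)
        assert np.max(np.abs(fast["minus_log10_p"] - exact["minus_log10_p"])) < 0.1

    def test_monomorphic_marker_is_harmless(self, small_genotypes, rng):
        X = small_genotypes.imputed()
        X[:, 0] = 1.0
        G = GenotypeData(X, small_genotypes.genotype_ids, small_genotypes.marker_map)
        y = pd.Series(rng.normal(0, 1, 60), index=G.genotype_ids)
        res = lmm_scan(y, G)
        assert res["p_wald"].iloc[0] == 1.0


class TestMvLmmScan:
    def test_reduces_to_univariate_at_one_trait(self, small_genotypes):
        plants, _ = simulate_traits(small_genotypes, sigma_g2=1.0, sigma_e2=1.0, seed=4)
        gm = plants.groupby("genotype_id")["trait_1"].mean()
        K = relatedness_matrix(small_genotypes)
        uni = lmm_scan(gm, small_genotypes, K=K)
        mv = mv_lmm_scan(gm.to_frame("trait_1"), small_genotypes, K=K)
        assert np.max(np.abs(uni["p_wald"] - mv["p_wald"])) < 1e-6

    def test_wald_invariant_to_trait_order(self, small_genotypes):
        corr = np.array([[1, 0.5, 0.2], [0.5, 1, 0.3], [0.2, 0.3, 1]])
        plants, _ = simulate_traits(
            small_genotypes, sigma_g2=[1, 0.5, 0.8], sigma_e2=1.0,
            n_traits=3, genetic_corr=corr, seed=9,
        )
        gm = plants.groupby("genotype_id")[["trait_1", "trait_2", "trait_3"]].mean()
        a = mv_lmm_scan(gm, small_genotypes)
        b = mv_lmm_scan(gm[["trait_3", "trait_1", "trait_2"]], small_genotypes)
        assert np.array_equal(a["wald"].to_numpy(), b["wald"].to_numpy())

    def test_duplicate_traits_warn_and_dedup_matches_univariate(self, small_genotypes, caplog):
        plants, _ = simulate_traits(small_genotypes, sigma_g2=1.0, sigma_e2=1.0, seed=6)
        gm = plants.groupby("genotype_id")["trait_1"].mean()
        Y = pd.DataFrame({"a": gm, "b": gm})
        with caplog.at_level("WARNING"):
            mv_lmm_scan(Y, small_genotypes)
        assert any("singular" in r.message for r in caplog.records)
        dedup = mv_lmm_scan(Y[["a"]], small_genotypes)
        uni = lmm_scan(gm, small_genotypes)
        assert np.max(np.abs(dedup["p_wald"] - uni["p_wald"])) < 1e-6

    def test_beats_best_univariate_for_antagonistic_pleiotropy(self):
        """Opposite-sign effects on correlated traits: the joint test wins."""
        corr = np.full((3, 3), 0.6)
        np.fill_diagonal(corr, 1.0)
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimulationConfig(n_genotypes=150, n_blocks=4, n_markers=200,
                                   n_chromosomes=2, missing_rate=0.0, seed=seed)
            G = simulate_genotypes(cfg)
            plants, _ = simulate_traits(
                G, sigma_g2=1.0, sigma_e2=2.0, n_traits=3, genetic_corr=corr,
                qtl=[("M000050", [0.35, -0.35, 0.0])], seed=seed + 100,
            )
            gm = plants.groupby("genotype_id")[["trait_1", "trait_2", "trait_3"]].mean()
            K = relatedness_matrix(G)
            mv = mv_lmm_scan(gm, G, K=K)["minus_log10_p"].iloc[49]
            best = max(
                lmm_scan(gm[t], G, K=K)["minus_log10_p"].iloc[49] for t in gm.columns
            )
            wins += mv > best
        assert wins > n_seeds / 2

    def test_too_many_traits_rejected(self, small_genotypes, rng):
        Y = pd.DataFrame(
            rng.normal(0, 1, (60, 7)), index=small_genotypes.genotype_ids
        )
        with pytest.raises(ValueError, match="1-6"):
            mv_lmm_scan(Y, small_genotypes)


class TestPcGwas:
    def test_degenerate_scores_match_single_trait_scan(self, small_genotypes):
        plants, _ = simulate_traits(small_genotypes, sigma_g2=1.0, sigma_e2=1.0, seed=8)
        gm = plants.groupby("genotype_id")["trait_1"].mean()
        scores = gm.to_frame("PC1")
        K = relatedness_matrix(small_genotypes)
        pc = pc_gwas(scores, small_genotypes, K=K, n_pcs=1)
        uni = lmm_scan(gm, small_genotypes, K=K)
        assert np.allclose(pc["p_wald"], uni["p_wald"])
        assert set(pc["model"]) == {"pc"}

    def test_one_result_set_per_component(self, small_genotypes, rng):
        scores = pd.DataFrame(
            rng.normal(0, 1, (60, 10)),
            index=small_genotypes.genotype_ids,
            columns=[f"PC{k}" for k in range(1, 11)],
        )
        res = pc_gwas(scores, small_genotypes, n_pcs=10)
        assert res["trait"].nunique() == 10
        assert len(res) == 10 * small_genotypes.n_markers


class TestSignificanceAndWindows:
    def make_results(self, pvals):
        p = np.asarray(pvals, float)
        return pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(len(p))],
            "chrom": "chr1", "pos": np.arange(len(p)) + 1,
            "p_wald": p, "minus_log10_p": -np.log10(p),
            "trait": "t", "model": "univariate",
        })

    def test_threshold_is_inclusive(self):
        res = declare_significant(self.make_results([10 ** -3.5, 10 ** -3.4]))
        assert bool(res["raw_pass"].iloc[0])
        assert not res["raw_pass"].iloc[1]

    def test_uniform_null_yields_no_fdr_hits(self, rng):
        res = declare_significant(self.make_results(rng.uniform(0, 1, 1000)))
        assert res["fdr_pass"].sum() <= 2

    def test_extreme_p_passes_both(self, rng):
        p = rng.uniform(0.1, 1, 999).tolist() + [1e-8]
        res = declare_significant(self.make_results(p))
        assert bool(res["raw_pass"].iloc[-1]) and bool(res["fdr_pass"].iloc[-1])

    def annotation(self):
        return pd.DataFrame({
            "gene_id": ["span", "edge", "other_chrom"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [990_000, 500_000, 990_000],
            "end": [1_010_000, 750_000, 1_010_000],
        })

    def marker(self, pos=1_000_000):
        return pd.DataFrame({"marker_id": ["m1"], "chrom": ["chr1"], "pos": [pos]})

    def test_spanning_gene_distance_zero(self):
        hits = candidate_windows(self.marker(), self.annotation())
        d = hits.set_index("gene_id")["distance_bp"]
        assert d["span"] == 0

    def test_inclusive_window_boundary(self):
        # gene ends exactly 250 kb before the marker -> still a hit
        hits = candidate_windows(self.marker(), self.annotation())
        assert "edge" in set(hits["gene_id"])
        assert hits.set_index("gene_id").loc["edge", "distance_bp"] == 250_000

    def test_other_chromosome_not_hit(self):
        hits = candidate_windows(self.marker(), self.annotation())
        assert "other_chrom" not in set(hits["gene_id"])


class TestGenotypeDataIo:
    def test_tsv_round_trip(self, small_genotypes, tmp_path):
        path = tmp_path / "g.tsv"
        small_genotypes.to_tsv(path)
        back = GenotypeData.from_tsv(path)
        assert back.genotype_ids == small_genotypes.genotype_ids
        assert np.array_equal(
            np.isnan(back.dosages), np.isnan(small_genotypes.dosages)
        )
        mask = ~np.isnan(back.dosages)
        assert np.array_equal(back.dosages[mask], small_genotypes.dosages[mask])
        pd.testing.assert_frame_equal(back.marker_map, small_genotypes.marker_map)

    def test_genomic_inflation_of_uniform_p(self, rng):
        lam = genomic_inflation(rng.uniform(0, 1, 20000))
        assert lam == pytest.approx(1.0, abs=0.05)
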