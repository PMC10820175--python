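import numpy as np
import pandas as pd
import pytest

import promhex as ph
from promhex.enrichment import NullModel
from promhex.hexamer_core import count_matrix

from conftest import random_seq


class TestBuildNull:
    def test_background_equal_to_sample_size_is_degenerate(self):
        rng = np.random.default_rng(0)
        seqs = [random_seq(rng, 200) for _ in range(100)]
        null = ph.build_null(seqs, sample_size=100, n_replicates=50, seed=1)
        # every replicate is the whole set: no variance anywhere
        assert np.all(null.sd == 0)
        assert null.degenerate
        totals = ph.aggregate_counts(seqs).counts
        assert np.array_equal(null.mean, totals.astype(float))

    def test_identical_copies_have_zero_sd(self):
        rng = np.random.default_rng(1)
        seq = random_seq(rng, 300)
        null = ph.build_null([seq] * 250, sample_size=100, n_replicates=60, seed=2)
        single = ph.count_hexamers(seq).counts
        assert np.array_equal(null.mean, 100.0 * single)
        assert np.all(null.sd == 0)

    def test_mean_matches_binomial_expectation(self):
        # closed form: uniform iid background, w = L-5 windows per promoter,
        # expected per-100-promoter count = 100*w/4096; the null mean scatters
        # around it mainly through the background's own binomial composition
        rng = np.random.default_rng(3)
        n_bg, L = 1200, 400
        w = L - 5
        seqs = [random_seq(rng, L) for _ in range(n_bg)]
        null = ph.build_null(seqs, sample_size=100, n_replicates=400, seed=3)
        p = 1 / 4096
        expect = 100 * w * p
        se_bg = np.sqrt(n_bg * w * p * (1 - p)) * 100 / n_bg
        se_rep = null.sd / np.sqrt(null.n_replicates)
        tol = 5 * np.sqrt(se_bg**2 + se_rep**2)
        assert np.all(np.abs(null.mean - expect) <= tol)

    def test_consistency_with_background_totals(self):
        # E[replicate total] = sample_size * background_total / background_size
        # exactly under uniform without-replacement draws
        rng = np.random.default_rng(4)
        seqs = [random_seq(rng, 300) for _ in range(500)]
        mat, _ = count_matrix(seqs)
        null = ph.build_null(mat, sample_size=100, n_replicates=1000, seed=4)
        expect = 100 * mat.sum(axis=0) / 500
        se = null.sd / np.sqrt(null.n_replicates)
        ok = se > 0
        assert np.all(np.abs(null.mean[ok] - expect[ok]) <= 5 * se[ok])

    def test_errors(self):
        rng = np.random.default_rng(5)
        seqs = [random_seq(rng, 100) for _ in range(10)]
        with pytest.raises(ValueError, match="smaller than sample_size"):
            ph.build_null(seqs, sample_size=100, n_replicates=10, seed=0)
        with pytest.raises(ValueError):
            ph.build_null(seqs, sample_size=0, n_replicates=10, seed=0)
        with pytest.raises(ValueError):
            ph.build_null(seqs, sample_size=5, n_replicates=0, seed=0)

    def test_bit_identical_under_same_seed(self, small_universe):
        mat, _ = count_matrix(small_universe.records)
        a = ph.build_null(mat, sample_size=100, n_replicates=200, seed=17)
        b = ph.build_null(mat, sample_size=100, n_replicates=200, seed=17)
        assert np.array_equal(a.mean, b.mean) and np.array_equal(a.sd, b.sd)
        c = ph.build_null(mat, sample_size=100, n_replicates=200, seed=18)
        assert not np.array_equal(a.mean, c.mean)

    def test_json_round_trip(self, small_null, tmp_path):
        p = tmp_path / "null.json"
        small_null.to_json(p)
        back = NullModel.from_json(p)
        assert np.array_equal(back.mean, small_null.mean)
        assert np.array_equal(back.sd, small_null.sd)
        assert back.sample_size == small_null.sample_size
        assert back.seed == small_null.seed


def _manual_null(mean, sd, sample_size=100):
    return NullModel(sample_size=sample_size, n_replicates=2, seed=0,
                     mean=np.asarray(mean, float), sd=np.asarray(sd, float),
                     background_size=1000)


class TestZscore:
    def test_centering_gives_zero_z(self):
        counts = np.arange(4096, dtype=np.int64)
        obs = ph.HexamerCountVector(counts=counts, n_promoters=100,
                                    n_valid_windows=int(counts.sum()))
        null = _manual_null(mean=counts.astype(float), sd=np.ones(4096))
        table = ph.zscore(obs, null)
        assert np.allclose(table.df["z"], 0.0)

    def test_undefined_z_excluded_from_ranking(self):
        counts = np.ones(4096, dtype=np.int64)
        obs = ph.HexamerCountVector(counts=counts, n_promoters=100,
                                    n_valid_windows=4096)
        sd = np.ones(4096)
        sd[:7] = 0.0
        table = ph.zscore(obs, _manual_null(mean=np.zeros(4096), sd=sd))
        df = table.df
        assert df["z"].isna().sum() == 7
        assert df.loc[df["z"].isna(), "rank"].isna().all()
        ranks = df["rank"].dropna().astype(int).sort_values().to_numpy()
        assert np.array_equal(ranks, np.arange(1, 4090))

    def test_tie_break_is_lexicographic(self):
        counts = np.zeros(4096, dtype=np.int64)
        obs = ph.HexamerCountVector(counts=counts, n_promoters=100,
                                    n_valid_windows=0)
        table = ph.zscore(obs, _manual_null(mean=np.zeros(4096), sd=np.ones(4096)))
        head = table.top_k(1)
        assert list(head.index) == ["AAAAAA"]
        full = table.top_k(4096)
        assert list(full.index) == list(ph.enumerate_hexamers().motifs)

    def test_focal_set_size_rescaling(self):
        # 50 promoters with c counts standardize to 2c per 100 promoters
        counts = np.full(4096, 3, dtype=np.int64)
        obs = ph.HexamerCountVector(counts=counts, n_promoters=50,
                                    n_valid_windows=int(counts.sum()))
        table = ph.zscore(obs, _manual_null(mean=np.zeros(4096), sd=np.ones(4096)))
        assert np.allclose(table.df["observed_freq"], 6.0)

    def test_universe_mismatch_is_error(self, small_null):
        obs = ph.count_hexamers("ACGTACGT", k=3)
        with pytest.raises(ValueError, match="universe"):
            ph.zscore(obs, small_null)

    def test_top_k_rejects_nonpositive(self, small_null, small_universe):
        obs = ph.aggregate_counts(small_universe.records[:50])
        table = ph.zscore(obs, small_null)
        with pytest.raises(ValueError):
            table.top_k(0)

    def test_approx_p_matches_normal_tail(self, small_null, small_universe):
        from scipy.stats import norm
        obs = ph.aggregate_counts(small_universe.records[:50])
        df = ph.zscore(obs, small_null).df
        ok = df["z"].notna()
        assert np.allclose(df.loc[ok, "approx_p"],
                           2 * norm.sf(np.abs(df.loc[ok, "z"])))


class TestPlantedRecoveryAndMonotonicity:
    def test_monotone_in_planting_rate(self):
        cfg = ph.SyntheticConfig(n_background=800, promoter_len=500, seed=21)
        uni = ph.generate_background(cfg)
        mat, _ = count_matrix(uni.records)
        null = ph.build_null(mat, sample_size=100, n_replicates=300, seed=21)
        zs = []
        for copies in (0, 1, 2):
            bundle = ph.generate_geneset(
                cfg, ph.Planting(motif="CGTCCA", geneset_name="focal",
                                 per_promoter_copies=copies, n_genes=80))
            table = ph.zscore(ph.aggregate_counts(bundle.records), null)
            zs.append(table.df.loc["CGTCCA", "z"])
        assert zs[0] <= zs[1] <= zs[2]
        assert zs[2] > zs[0]  # planting two copies must move the score

    def test_planted_motif_annotated_in_top_k(self, dictionary):
        cfg = ph.SyntheticConfig(n_background=600, promoter_len=400, seed=5)
        uni = ph.generate_background(cfg)
        null = ph.build_null(uni.records, sample_size=100, n_replicates=300, seed=5)
        bundle = ph.generate_geneset(
            cfg, ph.Planting(motif="CGTCCA", geneset_name="focal",
                             per_promoter_copies=1, n_genes=80))
        table = ph.zscore(ph.aggregate_counts(bundle.records), null,
                          elements=dictionary)
        top = ph.top_k(table, 10)
        motifs = [m for m, _ in top]
        assert motifs[0] == "CGTCCA"
        assert "New3" in dict(top)["CGTCCA"]


class TestTableIO:
    def test_tsv_round_trip(self, small_null, small_universe, dictionary, tmp_path):
        obs = ph.aggregate_counts(small_universe.records[:60])
        table = ph.zscore(obs, small_null, elements=dictionary, name="t")
        p = tmp_path / "enrich.tsv"
        table.to_tsv(p)
        back = ph.EnrichmentTable.from_tsv(p, name="t")
        assert list(back.df.index) == list(table.df.index)
        pd.testing.assert_series_equal(back.df["rank"], table.df["rank"],
                                       check_exact=True)
        assert np.allclose(back.df["z"].fillna(0), table.df["z"].fillna(0),
                           rtol=1e-4)
        assert (back.df["elements"] == table.df["elements"]).all()
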