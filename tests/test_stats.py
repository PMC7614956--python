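import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from dropcrispr.quantify import CountTable
from dropcrispr.simulate import ScreenSimParams, simulate_screen_counts
from dropcrispr.stats import (
    DispersionEstimate,
    NormFactors,
    ScreenDesign,
    _apl,
    bh_adjust,
    call_enriched,
    droplet_occupancy,
    estimate_dispersion,
    fold_coverage,
    glm_lrt,
    low_count_filter,
    nb_loglik,
    rle_norm_factors,
    summarize_genes,
)


def _table(counts: dict, fractions: dict) -> CountTable:
    return CountTable(pd.DataFrame(counts), fractions)


def _unit_factors(columns, libsize=1000.0):
    cols = list(columns)
    return NormFactors(
        factors=pd.Series(1.0, index=cols),
        library_sizes=pd.Series(float(libsize), index=cols),
    )


class TestLowCountFilter:
    def test_zero_guide_removed_cpm2_kept(self):
        counts = pd.DataFrame(
            {"s1": [0, 400, 199_600], "s2": [0, 400, 199_600]},
            index=["zero", "cpm2", "big"],
        )
        table = CountTable(counts, {"s1": "high", "s2": "low"})
        kept, report = low_count_filter(table, min_cpm=1.0)
        assert list(kept.counts.index) == ["cpm2", "big"]
        assert report["kept"] == 2 and report["total"] == 3

    def test_kept_set_matches_direct_cpm_evaluation(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(200, 4)),
            index=[f"g{i}" for i in range(200)],
            columns=["a", "b", "c", "d"],
        )
        table = CountTable(
            counts, {"a": "high", "b": "high", "c": "low", "d": "low"}
        )
        kept, _ = low_count_filter(table, min_cpm=1.0, min_samples=0.5)
        cpm = counts / counts.sum(axis=0) * 1e6
        expected = counts.index[(cpm > 1.0).sum(axis=1) >= 2]
        assert list(kept.counts.index) == list(expected)

    def test_empty_table_is_an_error(self):
        table = _table({"s1": [1]}, {"s1": "high"})
        table.counts = table.counts.iloc[:0]
        with pytest.raises(ValueError):
            low_count_filter(table)


class TestRleNormFactors:
    def test_identical_columns_give_unit_factors(self):
        table = _table(
            {"s1": [10, 20, 30], "s2": [10, 20, 30]},
            {"s1": "high", "s2": "low"},
        )
        nf = rle_norm_factors(table)
        assert np.allclose(nf.factors, 1.0)

    def test_doubled_column_hand_computation(self):
        # ratios to the geometric mean are (1/sqrt2, sqrt2); the medians
        # (1/sqrt2, sqrt2) already have geometric mean 1
        table = _table(
            {"s1": [10, 20, 30], "s2": [20, 40, 60]},
            {"s1": "high", "s2": "low"},
        )
        nf = rle_norm_factors(table)
        assert nf.factors["s1"] == pytest.approx(1 / math.sqrt(2))
        assert nf.factors["s2"] == pytest.approx(math.sqrt(2))

    def test_single_sample_unit_factor(self):
        table = _table({"s1": [5, 8]}, {"s1": "high"})
        assert rle_norm_factors(table).factors["s1"] == pytest.approx(1.0)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(300, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        table = CountTable(counts, {f"s{i}": "high" for i in range(6)})
        nf = rle_norm_factors(table)
        assert np.exp(np.mean(np.log(nf.factors))) == pytest.approx(1.0)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(200, 3)), columns=["a", "b", "c"]
        )
        t1 = CountTable(counts, {"a": "high", "b": "low", "c": "low"})
        scaled = counts.copy()
        scaled["a"] = scaled["a"] * 3
        t2 = CountTable(scaled, {"a": "high", "b": "low", "c": "low"})
        f1, f2 = rle_norm_factors(t1), rle_norm_factors(t2)
        # pre-rescale factor of 'a' triples; after geometric rescaling the
        # ratio factor_a / geomean-free part changes by 3 exactly
        ratio = (f2.factors / f1.factors) / (f2.factors / f1.factors)["b"]
        assert ratio["a"] == pytest.approx(3.0)

    def test_no_all_positive_guide_is_an_error(self):
        table = _table(
            {"s1": [0, 5], "s2": [5, 0]}, {"s1": "high", "s2": "low"}
        )
        with pytest.raises(ValueError, match="filter"):
            rle_norm_factors(table)


class TestDispersion:
    def test_recovers_simulated_phi(self):
        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=2000, n_samples_per_group=4, mean_depth=200,
                dispersion=0.1, spike_fraction=0.0, seed=11,
            )
        )
        nf = rle_norm_factors(table)
        est = estimate_dispersion(table, nf)
        assert 0.08 <= est.common <= 0.12

    def test_poisson_boundary(self):
        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=2000, n_samples_per_group=4, mean_depth=200,
                dispersion=0.0, spike_fraction=0.0, seed=12,
            )
        )
        nf = rle_norm_factors(table)
        assert estimate_dispersion(table, nf).common <= 0.02

    def test_grid_optimum_matches_dense_grid(self):
        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=300, n_samples_per_group=3, mean_depth=100,
                dispersion=0.2, spike_fraction=0.0, seed=13,
            )
        )
        nf = rle_norm_factors(table)
        est = estimate_dispersion(table, nf)
        y = table.counts.to_numpy(dtype=float)
        offs = np.log(nf.effective_library_sizes.to_numpy())
        groups = np.array([table.fractions[s] for s in table.sample_ids])
        high, low = groups == "high", groups == "low"
        dense = np.geomspace(1e-4, 4.0, 1000)
        apls = [
            _apl(y[y.sum(axis=1) > 0], offs, high, low, p).sum() for p in dense
        ]
        best = dense[int(np.argmax(apls))]
        assert math.isclose(est.common, best, rel_tol=0.02, abs_tol=1e-3)

    def test_single_sample_is_an_error(self):
        table = _table({"s1": [5, 8]}, {"s1": "high"})
        nf = _unit_factors(["s1"])
        with pytest.raises(ValueError):
            estimate_dispersion(table, nf)

    def test_tagwise_shrinks_toward_common(self):
        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=400, n_samples_per_group=3, mean_depth=100,
                dispersion=0.15, spike_fraction=0.0, seed=14,
            )
        )
        nf = rle_norm_factors(table)
        loose = estimate_dispersion(table, nf, tagwise=True, prior_df=1)
        tight = estimate_dispersion(table, nf, tagwise=True, prior_df=500)
        spread_loose = np.std(np.log(loose.tagwise))
        spread_tight = np.std(np.log(tight.tagwise))
        assert spread_tight < spread_loose


class TestGlmLrt:
    FRACTIONS = {"h1": "high", "h2": "high", "l1": "low", "l2": "low"}

    def test_flat_guide_has_zero_statistic(self):
        table = _table(
            {"h1": [50], "h2": [50], "l1": [50], "l2": [50]}, self.FRACTIONS
        )
        res = glm_lrt(table, _unit_factors(table.sample_ids),
                      DispersionEstimate(0.05))
        assert res.loc[0, "lr_stat"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_matches_brute_force_likelihood_maximization(self):
        table = _table(
            {"h1": [100], "h2": [100], "l1": [10], "l2": [10]}, self.FRACTIONS
        )
        nf = _unit_factors(table.sample_ids)
        phi = 0.05
        res = glm_lrt(table, nf, DispersionEstimate(phi))
        y = np.array([100.0, 100.0, 10.0, 10.0])
        is_high = np.array([1.0, 1.0, 0.0, 0.0])

        def nll_full(b):
            mu = np.exp(np.where(is_high > 0, b[0], b[1])) * 1000.0
            return -nb_loglik(y[None, :], mu[None, :], phi)[0]

        def nll_red(b):
            mu = np.exp(b[0]) * np.ones(4) * 1000.0
            return -nb_loglik(y[None, :], mu[None, :], phi)[0]

        full = optimize.minimize(
            nll_full, [-2.0, -4.0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
        )
        red = optimize.minimize(
            nll_red, [-3.0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
        )
        lr_oracle = 2.0 * (red.fun - full.fun)
        assert res.loc[0, "lr_stat"] == pytest.approx(lr_oracle, abs=1e-4)
        # fitted group means equal direct maximization to 4 decimals
        assert np.exp(full.x[0]) * 1000 == pytest.approx(100.0, abs=1e-4)
        assert res.loc[0, "log2fc"] == pytest.approx(math.log2(10), abs=0.02)

    def test_all_zero_guide_untested(self):
        table = _table(
            {"h1": [0, 60], "h2": [0, 55], "l1": [0, 50], "l2": [0, 65]},
            self.FRACTIONS,
        )
        res = glm_lrt(table, _unit_factors(table.sample_ids),
                      DispersionEstimate(0.1))
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2fc"] == 0.0

    def test_group_swap_flips_sign(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 4)),
            columns=["h1", "h2", "l1", "l2"],
        )
        t1 = CountTable(counts, self.FRACTIONS)
        swapped = {
            "h1": "low", "h2": "low", "l1": "high", "l2": "high"
        }
        t2 = CountTable(counts.copy(), swapped)
        nf = _unit_factors(counts.columns)
        d = DispersionEstimate(0.1)
        r1, r2 = glm_lrt(t1, nf, d), glm_lrt(t2, nf, d)
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-6)
        assert np.allclose(r1["lr_stat"], r2["lr_stat"], atol=1e-6)

    def test_null_calibration(self):
        from scipy import stats as sps

        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=3000, n_samples_per_group=4, mean_depth=200,
                dispersion=0.15, spike_fraction=0.0, seed=31,
            )
        )
        nf = rle_norm_factors(table)
        est = estimate_dispersion(table, nf)
        res = glm_lrt(table, nf, est)
        p = res["p_value"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07
        assert sps.kstest(p, "uniform").pvalue > 0.01


class TestAgainstEdgeR:
    """Independent cross-check of the NB GLM LRT against edgeR's
    glmFit/glmLRT at a shared fixed dispersion and offsets."""

    def test_lrt_matches_edger(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        table, _ = simulate_screen_counts(
            ScreenSimParams(
                n_guides=60, n_samples_per_group=3, mean_depth=120,
                dispersion=0.1, spike_fraction=0.2, spike_log2fc=3.0, seed=55,
            )
        )
        nf = rle_norm_factors(table)
        res = glm_lrt(table, nf, DispersionEstimate(0.1))
        counts_path = tmp_path / "counts.tsv"
        table.counts.to_csv(counts_path, sep="\t")
        out_path = tmp_path / "edger.tsv"
        groups = ",".join(
            "1" if table.fractions[s] == "high" else "0"
            for s in table.sample_ids
        )
        offsets = ",".join(
            str(v) for v in np.log(nf.effective_library_sizes.to_numpy())
        )
        script = tmp_path / "edger.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.delim("{counts_path}", row.names=1))\n'
            f'grp <- factor(c({groups}), levels=c(0,1))\n'
            'design <- model.matrix(~grp)\n'
            f'off <- matrix(rep(c({offsets}), each=nrow(x)), nrow=nrow(x))\n'
            'fit <- glmFit(x, design, dispersion=0.1, offset=off, prior.count=0)\n'
            'lrt <- glmLRT(fit, coef=2)\n'
            f'write.table(lrt$table, "{out_path}", sep="\\t", quote=FALSE)\n'
        )
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            timeout=300,
        )
        assert proc.returncode == 0, proc.stderr
        edger = pd.read_csv(out_path, sep="\t")
        ours = res.set_index("guide_id").loc[table.guide_ids]
        assert np.allclose(
            ours["lr_stat"], edger["LR"].to_numpy(), atol=1e-3
        )
        assert np.allclose(
            ours["p_value"], edger["PValue"].to_numpy(), atol=1e-4
        )


class TestBhAdjust:
    def test_single_value(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1, max_size=60,
        )
    )
    def test_matches_hand_step_up_on_random_vectors(self, p_values):
        got = bh_adjust(p_values)
        m = len(p_values)
        order = np.argsort(p_values, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):  # step-up from the largest p
            i = order[rank]
            running = min(running, p_values[i] * m / (rank + 1))
            q[i] = running
        assert np.allclose(got, q, rtol=1e-12, atol=1e-12)
        # monotone in sorted order, and never below the raw p-value
        assert np.all(np.asarray(got) >= np.asarray(p_values) - 1e-15)
        assert np.all(np.diff(np.asarray(got)[order]) >= -1e-15)


class TestEnrichmentCalls:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["guide_id", "log2fc", "lr_stat", "p_value", "fdr"]
        )

    def test_strict_inequalities(self):
        res = self._results(
            [
                ("exactly3", 3.0, 10.0, 1e-4, 0.01),
                ("passes", 3.5, 10.0, 1e-4, 0.04),
                ("fdr_at_gate", 3.5, 10.0, 1e-4, 0.05),
            ]
        )
        out = call_enriched(res)
        assert list(out["enriched"]) == [False, True, False]

    def test_flag_equals_direct_predicate(self):
        rng = np.random.default_rng(17)
        res = self._results(
            [
                (f"g{i}", float(l), 1.0, 0.5, float(f))
                for i, (l, f) in enumerate(
                    zip(rng.normal(3, 1, 200), rng.uniform(0, 0.1, 200))
                )
            ]
        )
        out = call_enriched(res, 3.0, 0.05)
        expected = (res["log2fc"] > 3.0) & (res["fdr"] < 0.05)
        assert (out["enriched"] == expected).all()


class TestGeneSummary:
    def _results(self):
        return pd.DataFrame(
            {
                "guide_id": ["a1", "a2", "b1", "c1"],
                "log2fc": [4.2, 3.5, 3.2, 2.0],
                "lr_stat": [9.0, 12.0, 8.0, 1.0],
                "p_value": [0.01, 1e-4, 0.02, 0.4],
                "fdr": [0.2, 0.01, 0.25, 0.6],
            }
        )

    MAP = {"a1": "geneA", "a2": "geneA", "b1": "geneB", "c1": "geneC"}

    def test_highest_fold_change_wins_at_relaxed_gate(self):
        # a1 (4.2, fdr 0.2) fails the strict 0.05 call but represents the
        # gene under the relaxed 0.3 gate, beating a2 (3.5, fdr 0.01)
        out = summarize_genes(self._results(), self.MAP)
        row = out[out["gene_id"] == "geneA"].iloc[0]
        assert row["representative_guide"] == "a1"
        assert row["log2fc"] == pytest.approx(4.2)

    def test_gene_without_passing_guide_omitted(self):
        out = summarize_genes(self._results(), self.MAP)
        assert "geneC" not in set(out["gene_id"])

    def test_single_passing_guide(self):
        out = summarize_genes(self._results(), self.MAP)
        row = out[out["gene_id"] == "geneB"].iloc[0]
        assert row["representative_guide"] == "b1"

    def test_order_invariance(self):
        res = self._results()
        shuffled = res.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = summarize_genes(res, self.MAP)
        b = summarize_genes(shuffled, self.MAP)
        pd.testing.assert_frame_equal(a, b)

    def test_unmapped_guide_is_an_error(self):
        with pytest.raises(ValueError, match="mapping"):
            summarize_genes(self._results(), {"a1": "geneA"})


class TestDropletArithmetic:
    def test_published_screen_coverages(self):
        assert fold_coverage(ScreenDesign(800_000, 0.4, 40_890)) == pytest.approx(
            7.82, abs=0.01
        )
        assert fold_coverage(ScreenDesign(2_000_000, 0.4, 40_890)) == pytest.approx(
            19.56, abs=0.01
        )

    def test_zero_droplets(self):
        assert fold_coverage(ScreenDesign(0, 0.4, 100)) == 0.0

    def test_linear_in_droplets_and_inverse_library(self):
        base = fold_coverage(ScreenDesign(1000, 0.4, 500))
        assert fold_coverage(ScreenDesign(3000, 0.4, 500)) == pytest.approx(3 * base)
        assert fold_coverage(ScreenDesign(1000, 0.4, 1000)) == pytest.approx(base / 2)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            ScreenDesign(1000, 0.4, 0)

    def test_occupancy_closed_form(self):
        empty, single, multi = droplet_occupancy(0.4)
        assert (empty, single, multi) == pytest.approx(
            (0.6703, 0.2681, 0.0616), abs=5e-5
        )

    def test_occupancy_sums_to_one(self):
        for lam in (0.05, 0.4, 1.3, 4.0):
            assert sum(droplet_occupancy(lam)) == pytest.approx(1.0)

    def test_small_lambda_limit(self):
        empty, _, _ = droplet_occupancy(1e-9)
        assert empty == pytest.approx(1.0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            droplet_occupancy(0.0)
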