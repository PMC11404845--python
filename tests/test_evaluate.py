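"""Evaluation metrics, bootstrap uncertainty, model selection and
stepwise covariate regression."""

import numpy as np
import pandas as pd
import pytest

from prsport import evaluate as ev
from prsport import simulate as sim, distance
from prsport.io import GenotypeMatrix


class TestRSquared:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ev.r_squared(y, y) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert ev.r_squared(y, np.full(3, 2.0)) == pytest.approx(0.0)

    def test_anti_correlated_is_minus_three(self):
        # SS_res = 8, SS_tot = 2 -> R^2 = -3
        assert ev.r_squared([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_equals_one_minus_mse_over_var(self, rng):
        y = rng.standard_normal(500)
        yhat = y + rng.standard_normal(500) * 0.5
        mse = np.mean((y - yhat) ** 2)
        assert ev.r_squared(y, yhat) == pytest.approx(
            1 - mse / np.var(y), abs=1e-12)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            ev.r_squared(np.ones(10), np.ones(10))


class TestPCC:
    def test_affine_transform_is_one(self, rng):
        y = rng.standard_normal(100)
        assert ev.pcc(y, 2 * y + 1) == pytest.approx(1.0)
        assert ev.pcc(y, -y) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(5150)
        assert abs(ev.pcc(rng.standard_normal(10000),
                          rng.standard_normal(10000))) < 0.03


class TestBootstrap:
    def test_constant_metric_zero_width_ci(self):
        res = ev.bootstrap_performance(
            train_fn=lambda idx: None,
            metric_fn=lambda model, test: 0.42,
            train_data=np.arange(50), test_data=None, B=10, seed=3,
        )
        assert res["ci"] == (0.42, 0.42)

    def test_same_seed_same_ci(self, rng):
        x = rng.standard_normal(200)
        y = 2 * x + rng.standard_normal(200)
        data = np.column_stack([x, y])

        def train(idx):
            xb, yb = data[idx, 0], data[idx, 1]
            return np.polyfit(xb, yb, 1)[0]

        kw = dict(train_fn=train, metric_fn=lambda m, t: m,
                  train_data=data, test_data=None, B=25)
        a = ev.bootstrap_performance(seed=7, **kw)
        b = ev.bootstrap_performance(seed=7, **kw)
        assert a["ci"] == b["ci"]

    def test_slope_ci_coverage(self):
        rng = np.random.default_rng(88)
        covered = 0
        for _ in range(20):
            x = rng.standard_normal(500)
            y = 2 * x + rng.standard_normal(500)
            data = np.column_stack([x, y])
            res = ev.bootstrap_performance(
                train_fn=lambda idx: np.polyfit(data[idx, 0], data[idx, 1], 1)[0],
                metric_fn=lambda m, t: m,
                train_data=data, test_data=None, B=50,
                seed=int(rng.integers(2**31)),
            )
            lo, hi = res["ci"]
            covered += lo <= 2.0 <= hi
        assert covered >= 18  # >= 90% of meta-replicates

    def test_b_below_two_rejected(self):
        with pytest.raises(ValueError):
            ev.bootstrap_performance(lambda i: None, lambda m, t: 0,
                                     np.arange(5), None, B=1)


class DummyModel:
    def __init__(self, n_snps, threshold):
        self.n_snps = n_snps
        self.threshold = threshold


class TestSelectBest:
    def test_single_candidate(self):
        m = DummyModel(3, 5e-8)
        assert ev.select_best_model([m], [0.1]) is m

    def test_argmax(self):
        ms = [DummyModel(5, 5e-8), DummyModel(8, 5e-7), DummyModel(9, 5e-6)]
        assert ev.select_best_model(ms, [0.20, 0.25, 0.22]) is ms[1]

    def test_tie_prefers_fewer_snps_then_smaller_threshold(self):
        ms = [DummyModel(10, 5e-6), DummyModel(4, 5e-6), DummyModel(4, 5e-8)]
        assert ev.select_best_model(ms, [0.3, 0.3, 0.3]) is ms[2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.select_best_model([], [])


class TestResidualGDCorrelation:
    def test_constant_gd_undefined(self, rng):
        y = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="constant"):
            r, p = ev.residual_gd_correlation(y, y + 0.1, np.ones(50))
        assert np.isnan(r) and np.isnan(p)

    def test_independent_residuals_near_zero(self):
        rng = np.random.default_rng(606)
        y = rng.standard_normal(10000)
        yhat = y + rng.standard_normal(10000)
        gd = rng.uniform(0, 5, 10000)
        r, _ = ev.residual_gd_correlation(y, yhat, gd)
        assert abs(r) < 0.03

    def test_frequency_drift_induces_positive_correlation(self):
        # cline simulation: shared effects, drifted frequencies; the GD
        # pool is held-out cohorts only (training self-scores are
        # overfit and not comparable)
        spec = sim.PopulationSpec(fst=(0.0,) * 3,
                                  sample_sizes=(1200, 600, 600))
        cline = sim.ClineSpec(pop_offset=(0.0, 0.0, 0.5),
                              within_pop_sd=(0.05,) * 3)
        fq = sim.simulate_population_frequencies(spec, 300, 81, block_length=5)
        g, pops, v = sim.simulate_genotypes(fq, spec.sample_sizes,
                                            sim.LDBlockSpec(5, 0.9), 82,
                                            cline=cline)
        arch = sim.TraitArchitecture(n_causal=30, h2_snp=0.5,
                                     clinical_frac=0.0)
        rng = np.random.default_rng(83)
        causal = np.sort(rng.choice(60, 30, replace=False) * 5 + 2)
        co, truth = sim.simulate_phenotypes(g, v, arch, 84, causal_idx=causal)
        y = co["bmd_fnk"].to_numpy()
        # "trained" model = tag-SNP effects measured in the training
        # population, applied everywhere; drift degrades the tagging
        tags = causal + 1
        g0 = g[pops == 0]
        beta = np.array([
            np.cov(g0[:, t], y[pops == 0])[0, 1] / np.var(g0[:, t])
            for t in tags
        ])
        yhat = g[:, tags] @ beta
        yhat += (y[pops == 0].mean() - yhat[pops == 0].mean())
        vr = v[["chrom", "pos", "id", "ref", "alt"]]
        poly = np.flatnonzero(g0.std(axis=0) > 0)
        train = GenotypeMatrix(g0[:, poly],
                               [f"T{i}" for i in range(len(g0))],
                               vr.iloc[poly])
        # LD-prune before PCA so components track ancestry, not LD blocks
        from prsport import ld
        pruned = ld.prune_pairwise(train, ld.PruneConfig(window_variants=100,
                                                         step=25))
        train = train.subset_variants(pruned)
        poly = poly[pruned]
        pca = distance.fit_pca(train, n_pc=10)
        held = pops > 0
        gm_held = GenotypeMatrix(g[held][:, poly],
                                 [f"A{i}" for i in range(int(held.sum()))],
                                 vr.iloc[poly])
        gd = distance.genetic_distance(distance.project(pca, gm_held))
        r, p = ev.residual_gd_correlation(y[held], yhat[held], gd,
                                          sd_y=float(y.std()))
        assert r > 0 and p < 0.01


class TestBackwardStepwise:
    def test_true_covariate_consistently_retained(self):
        rng = np.random.default_rng(303)
        hits = 0
        runs = 40
        for _ in range(runs):
            n = 2000
            co = pd.DataFrame(
                {f"x{j}": rng.standard_normal(n) for j in range(6)}
            )
            y = 0.2 * co["x0"].to_numpy() + rng.standard_normal(n)
            out = ev.backward_stepwise(co, [f"x{j}" for j in range(6)], y)
            hits += "x0" in set(out["covariate"])
        assert hits >= int(0.95 * runs)

    def test_pure_noise_usually_empty(self):
        rng = np.random.default_rng(404)
        sizes = []
        for _ in range(40):
            n = 500
            co = pd.DataFrame(
                {f"x{j}": rng.standard_normal(n) for j in range(5)}
            )
            out = ev.backward_stepwise(co, [f"x{j}" for j in range(5)],
                                       rng.standard_normal(n))
            sizes.append(len(out))
        # false retention is bounded by the stepwise alpha per covariate
        assert np.mean(sizes) <= 0.05 * 5 * 2.5
        assert sum(s == 0 for s in sizes) > len(sizes) / 2

    def test_perfect_predictor_always_retained(self, rng):
        n = 200
        co = pd.DataFrame({"x0": rng.standard_normal(n),
                           "x1": rng.standard_normal(n)})
        y = co["x0"].to_numpy()
        out = ev.backward_stepwise(co, ["x0", "x1"], y)
        assert "x0" in set(out["covariate"])
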