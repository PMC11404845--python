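"""Synthetic-cohort generator: frequency model, LD structure, trait
architecture and survival outcomes."""

import numpy as np
import pandas as pd
import pytest

from prsport import simulate as sim
from prsport.evaluate import r_squared
from prsport.fracture import fit_cox, logistic_or
from prsport.ld import ld_r2


class TestPopulationFrequencies:
    def test_fst_zero_reproduces_ancestral_exactly(self):
        spec = sim.PopulationSpec(fst=(0.0, 0.0), sample_sizes=(5, 5))
        fq = sim.simulate_population_frequencies(spec, 50, 3)
        assert np.array_equal(fq.pop_freqs[0], fq.ancestral)
        assert np.array_equal(fq.pop_freqs[1], fq.ancestral)

    def test_balding_nichols_variance_moment(self):
        # across-population variance of drifted frequencies ~ F p (1-p)
        spec = sim.PopulationSpec(fst=(0.1,) * 8, sample_sizes=(10,) * 8)
        fq = sim.simulate_population_frequencies(spec, 20000, 7)
        var = fq.pop_freqs.var(axis=0, ddof=1)
        expect = 0.1 * fq.ancestral * (1 - fq.ancestral)
        rel_err = abs(var.mean() - expect.mean()) / expect.mean()
        assert rel_err < 0.10

    def test_determinism(self):
        spec = sim.PopulationSpec(fst=(0.05, 0.2), sample_sizes=(5, 5))
        a = sim.simulate_population_frequencies(spec, 100, 9)
        b = sim.simulate_population_frequencies(spec, 100, 9)
        assert np.array_equal(a.ancestral, b.ancestral)
        assert np.array_equal(a.pop_freqs, b.pop_freqs)

    @pytest.mark.parametrize("bad_fst", [-0.1, 1.0, 1.5])
    def test_invalid_fst_rejected(self, bad_fst):
        with pytest.raises(ValueError):
            sim.PopulationSpec(fst=(bad_fst,), sample_sizes=(10,))


class TestGenotypes:
    def test_zero_frequency_gives_zero_dosages(self):
        fq = sim.AlleleFrequencyTable(
            ancestral=np.full(10, 0.3), pop_freqs=np.zeros((1, 10)),
            block_length=1,
        )
        g, _, _ = sim.simulate_genotypes(fq, (50,), sim.LDBlockSpec(1, 0.0), 1)
        assert np.all(g == 0)

    def test_mean_dosage_matches_frequency(self):
        fq = sim.AlleleFrequencyTable(
            ancestral=np.full(30, 0.3), pop_freqs=np.full((1, 30), 0.3),
            block_length=1,
        )
        g, _, _ = sim.simulate_genotypes(fq, (2000,), sim.LDBlockSpec(1, 0.0), 2)
        # binomial sampling error: SE of a per-locus mean is ~0.0145
        assert abs(g.mean() - 0.6) < 0.03 / np.sqrt(30)
        assert np.all(np.abs(g.mean(axis=0) - 0.6) < 0.06)

    def test_within_block_r2_calibration(self):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(2000,))
        fq = sim.simulate_population_frequencies(spec, 200, 5, block_length=10)
        g, _, _ = sim.simulate_genotypes(fq, (2000,), sim.LDBlockSpec(10, 0.9), 6)
        adj = [
            ld_r2(g[:, j], g[:, j + 1])
            for b in range(20)
            for j in range(b * 10, b * 10 + 9)
        ]
        assert 0.7 <= np.median(adj) <= 0.9
        # blocks are independent of one another
        crossings = [ld_r2(g[:, b * 10 + 9], g[:, b * 10 + 10]) for b in range(19)]
        assert np.median(crossings) < 0.01

    def test_determinism(self):
        spec = sim.PopulationSpec(fst=(0.1,), sample_sizes=(50,))
        fq = sim.simulate_population_frequencies(spec, 40, 3, block_length=4)
        a = sim.simulate_genotypes(fq, (50,), sim.LDBlockSpec(4, 0.5), 8)[0]
        b = sim.simulate_genotypes(fq, (50,), sim.LDBlockSpec(4, 0.5), 8)[0]
        assert np.array_equal(a, b)

    def test_hudson_fst_recovery(self):
        spec = sim.PopulationSpec(fst=(0.1, 0.1), sample_sizes=(500, 500))
        fq = sim.simulate_population_frequencies(spec, 8000, 11)
        g, pops, _ = sim.simulate_genotypes(fq, (500, 500),
                                            sim.LDBlockSpec(1, 0.0), 12)
        est = sim.hudson_fst(g[pops == 0], g[pops == 1])
        assert abs(est - 0.1) < 0.02


class TestPhenotypes:
    def test_pure_residual_variance(self):
        # no genetics, no clinical signal: latent trait is standard normal
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(5000,))
        fq = sim.simulate_population_frequencies(spec, 50, 1)
        g, _, v = sim.simulate_genotypes(fq, (5000,), sim.LDBlockSpec(1, 0.0), 2)
        arch = sim.TraitArchitecture(n_causal=0, h2_snp=0.0, clinical_frac=0.0)
        co, _ = sim.simulate_phenotypes(g, v, arch, 3)
        latent_var = co["bmd_fnk"].var() / sim.SITE_SD["FNK"] ** 2
        assert 0.9 < latent_var < 1.1

    def test_no_residual_is_exact_clinical_function(self):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(500,))
        fq = sim.simulate_population_frequencies(spec, 20, 1)
        g, _, v = sim.simulate_genotypes(fq, (500,), sim.LDBlockSpec(1, 0.0), 2)
        arch = sim.TraitArchitecture(n_causal=0, h2_snp=0.0, clinical_frac=1.0)
        co, _ = sim.simulate_phenotypes(g, v, arch, 3)
        covs = ["age", "age2", "sex", "height", "weight",
                "smoking", "drinking", "exercise"]
        X = np.column_stack([np.ones(len(co)), co[covs].to_numpy(float)])
        y = co["bmd_fnk"].to_numpy()
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert r_squared(y, X @ coef) > 1 - 1e-10

    def test_h2_recovery(self, small_cohort):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(5000,))
        fq = sim.simulate_population_frequencies(spec, 200, 4)
        g, _, v = sim.simulate_genotypes(fq, (5000,), sim.LDBlockSpec(1, 0.0), 5)
        arch = sim.TraitArchitecture(n_causal=30, h2_snp=0.25, clinical_frac=0.25)
        co, truth = sim.simulate_phenotypes(g, v, arch, 6)
        y = co["bmd_fnk"].to_numpy()
        gs = truth["gscore"]["FNK"]
        frac = np.cov(y, gs)[0, 1] ** 2 / (np.var(y) * np.var(gs))
        assert abs(frac - 0.25) < 0.03

    def test_variance_fractions_sum_to_one(self):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(5000,))
        fq = sim.simulate_population_frequencies(spec, 200, 4)
        g, _, v = sim.simulate_genotypes(fq, (5000,), sim.LDBlockSpec(1, 0.0), 5)
        arch = sim.TraitArchitecture(n_causal=30, h2_snp=0.3, clinical_frac=0.3)
        co, truth = sim.simulate_phenotypes(g, v, arch, 6)
        y = co["bmd_fnk"].to_numpy() / sim.SITE_SD["FNK"]
        assert abs(np.var(y) - 1.0) < 0.05  # h2 + clin + resid fractions

    def test_overfull_variance_budget_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            sim.TraitArchitecture(h2_snp=0.6, clinical_frac=0.5)

    def test_determinism_and_shared_architecture(self):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(100,))
        fq = sim.simulate_population_frequencies(spec, 60, 4)
        g, _, v = sim.simulate_genotypes(fq, (100,), sim.LDBlockSpec(1, 0.0), 5)
        arch = sim.TraitArchitecture(n_causal=10)
        co1, t1 = sim.simulate_phenotypes(g, v, arch, 6)
        co2, t2 = sim.simulate_phenotypes(g, v, arch, 6)
        pd.testing.assert_frame_equal(co1, co2)
        # supplying the causal set must not change the effect draws
        co3, t3 = sim.simulate_phenotypes(g, v, arch, 6,
                                          causal_idx=t1["causal_idx"])
        assert np.array_equal(t1["effects"]["FNK"], t3["effects"]["FNK"])


class TestFractureOutcomes:
    @staticmethod
    def _cohort(n, seed, h2=0.0):
        spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(n,))
        fq = sim.simulate_population_frequencies(spec, 20, seed)
        g, _, v = sim.simulate_genotypes(fq, (n,), sim.LDBlockSpec(1, 0.0), seed + 1)
        arch = sim.TraitArchitecture(n_causal=0, h2_snp=0.0, clinical_frac=0.2)
        co, _ = sim.simulate_phenotypes(g, v, arch, seed + 2)
        return co

    def test_vanishing_rate_censors_everyone(self):
        co = self._cohort(500, 1)
        hz = sim.HazardSpec(baseline_rate=1e-12, censor_horizon=10.0)
        out = sim.simulate_fracture_outcomes(co, hz, 3)
        assert out["event"].sum() == 0
        assert np.all(out["time"] == 10.0)

    def test_null_bmd_effect_gives_or_near_one(self):
        co = self._cohort(20000, 5)
        hz = sim.HazardSpec(baseline_rate=0.01, gamma_bmd=0.0,
                            covariate_log_hazards={})
        out = sim.simulate_fracture_outcomes(co, hz, 7)
        res = logistic_or(out["event"].to_numpy(), out["bmd_z"].to_numpy())
        lo, hi = res["ci"]
        assert lo < 1.0 < hi

    def test_cox_recovers_protective_hazard(self):
        co = self._cohort(8000, 9)
        hz = sim.HazardSpec(baseline_rate=0.02, gamma_bmd=np.log(0.7),
                            covariate_log_hazards={})
        out = sim.simulate_fracture_outcomes(co, hz, 11)
        cph = fit_cox(out, ["bmd_z"])
        hr = float(np.exp(cph.params_["bmd_z"]))
        assert 0.6 < hr < 0.8

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            sim.HazardSpec(baseline_rate=0.0)

    def test_determinism(self):
        co = self._cohort(200, 13)
        hz = sim.HazardSpec(baseline_rate=0.05)
        a = sim.simulate_fracture_outcomes(co, hz, 15)
        b = sim.simulate_fracture_outcomes(co, hz, 15)
        pd.testing.assert_frame_equal(a, b)
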