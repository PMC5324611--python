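"""Synthetic world generator: ground truth, determinism, and round trips."""

import json

import numpy as np
import pandas as pd
import pytest

from tailkit import (CrossSpec, DemeConfig, VariantTable, WorldConfig,
                     columns_from_frame, columns_to_frame, king_kinship,
                     ols_habitat_test, simulate_columns, simulate_genotypes,
                     simulate_intercross, simulate_traits, wc_fst,
                     wc_fst_components, write_fixtures)
from tailkit.variants import MISSING


def two_deme_world(f_deme, n_per_deme=20, n_sites=5000, seed=0, **kw):
    demes = [DemeConfig(label="d1", clade="c", habitat="forest",
                        n_individuals=n_per_deme),
             DemeConfig(label="d2", clade="c", habitat="nonforest",
                        n_individuals=n_per_deme)]
    return WorldConfig(demes=demes, n_sites=n_sites, F_clade=0.0,
                       F_deme=f_deme, missing_rate=0.0, geno_error_rate=0.0,
                       seed=seed, **kw)


class TestGenotypes:
    def test_determinism(self):
        w = WorldConfig.default(n_per_deme=5, n_sites=300, seed=42)
        a = simulate_genotypes(w)
        b = simulate_genotypes(w)
        assert np.array_equal(a.dosage, b.dosage)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.gq, b.gq)

    def test_positions_strictly_increasing(self):
        v = simulate_genotypes(WorldConfig.default(n_per_deme=4, n_sites=500,
                                                   seed=3))
        assert np.all(np.diff(v.pos) > 0)

    def test_no_drift_means_no_differentiation(self):
        w = two_deme_world(0.0, seed=8)
        v = simulate_genotypes(w)
        labels = ["d1"] * 20 + ["d2"] * 20
        res = wc_fst(v, labels)
        assert abs(res.weighted_global) < 0.01

    def test_fst_matches_balding_nichols_monte_carlo_oracle(self):
        """Weighted F_ST of the simulated world agrees with a brute-force
        Monte-Carlo evaluation of the estimator under the same model."""
        f = 0.2
        n_per = 20
        w = two_deme_world(f, n_per_deme=n_per, seed=12)
        v = simulate_genotypes(w)
        res = wc_fst(v, ["d1"] * n_per + ["d2"] * n_per)

        rng = np.random.default_rng(999)   # independent MC of the same model
        m = 200000
        p0 = rng.uniform(0.1, 0.9, m)
        scale = (1 - f) / f
        p1 = rng.beta(p0 * scale, (1 - p0) * scale)
        p2 = rng.beta(p0 * scale, (1 - p0) * scale)
        g1 = rng.binomial(2, p1[:, None], (m, n_per))
        g2 = rng.binomial(2, p2[:, None], (m, n_per))
        n = np.full((m, 2), n_per)
        p = np.column_stack([g1.mean(1) / 2, g2.mean(1) / 2])
        h = np.column_stack([(g1 == 1).mean(1), (g2 == 1).mean(1)])
        a, b, c = wc_fst_components(n, p, h)
        poly = (p.mean(1) > 0) & (p.mean(1) < 1)
        expected = a[poly].sum() / (a + b + c)[poly].sum()
        assert res.weighted_global == pytest.approx(expected, abs=0.03)

    def test_fst_monotone_in_deme_drift(self):
        grid = [0.01, 0.05, 0.1, 0.2]
        fsts = []
        for f in grid:
            v = simulate_genotypes(two_deme_world(f, n_sites=3000, seed=77))
            fsts.append(wc_fst(v, ["d1"] * 20 + ["d2"] * 20).weighted_global)
        assert all(b > a for a, b in zip(fsts, fsts[1:]))

    def test_missingness_rate_honoured(self):
        w = WorldConfig.default(n_per_deme=10, n_sites=2000, seed=2)
        v = simulate_genotypes(w)
        assert (v.dosage == MISSING).mean() == pytest.approx(0.02, abs=0.005)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="F_clade"):
            WorldConfig.default(F_clade=1.0)
        with pytest.raises(ValueError, match="habitat"):
            DemeConfig(label="x", clade="c", habitat="swamp")


class TestKinshipStructure:
    def test_duplicated_and_sib_kinship(self, rng):
        """Mendelian families in a panmictic deme: dup 0.5, sibs 0.25."""
        p = rng.uniform(0.1, 0.9, 6000)
        mother = rng.binomial(2, p).astype(np.int8)
        father = rng.binomial(2, p).astype(np.int8)
        sib = []
        for _ in range(2):
            ma = (rng.random(6000) < mother / 2).astype(np.int8)
            pa = (rng.random(6000) < father / 2).astype(np.int8)
            sib.append(ma + pa)
        dosage = np.column_stack([mother, father, sib[0], sib[1], sib[0]])
        from conftest import make_table
        kin = king_kinship(make_table(dosage))
        assert kin.phi[2, 3] == pytest.approx(0.25, abs=0.03)   # full sibs
        assert kin.phi[2, 4] == pytest.approx(0.5, abs=1e-12)   # duplicate


class TestTraits:
    def test_constructed_habitat_effect_visible(self):
        w = WorldConfig.default(n_per_deme=25, n_sites=300, sigma_e=0.01,
                                sigma_g=0.0, seed=5)
        v = simulate_genotypes(w)
        s = simulate_traits(w, v)
        ratios = s["tail_mm"] / s["body_mm"]
        diff = ratios[s["habitat"] == "forest"].mean() \
            - ratios[s["habitat"] == "nonforest"].mean()
        assert diff == pytest.approx(0.15, abs=0.02)

    def test_null_world_groups_equal(self):
        w = WorldConfig.default(n_per_deme=25, n_sites=300, sigma_g=0.0,
                                beta_habitat=0.0, seed=6)
        v = simulate_genotypes(w)
        s = simulate_traits(w, v)
        ratios = s["tail_mm"] / s["body_mm"]
        diff = ratios[s["habitat"] == "forest"].mean() \
            - ratios[s["habitat"] == "nonforest"].mean()
        assert abs(diff) < 3 * 0.04 / np.sqrt(25)

    def test_confounded_null_inflates_naive_test(self):
        """Habitat aligned with clade: the naive two-group test rejects a
        true null far above its nominal level."""
        rej = 0
        reps = 150
        for child in np.random.SeedSequence(55).spawn(reps):
            seed = int(child.generate_state(1)[0] % 2 ** 31)
            w = WorldConfig.confounded(n_per_deme=8, n_sites=300,
                                       beta_habitat=0.0, seed=seed)
            v = simulate_genotypes(w)
            s = simulate_traits(w, v)
            ratio = (s["tail_mm"] / s["body_mm"]).to_numpy()
            hab = (s["habitat"] == "forest").to_numpy(float)
            if ols_habitat_test(ratio, hab)[3] < 0.05:
                rej += 1
        assert rej / reps > 0.10

    def test_mismatched_individuals_rejected(self):
        w = WorldConfig.default(n_per_deme=5, n_sites=100, seed=1)
        v = simulate_genotypes(w)
        other = WorldConfig.default(n_per_deme=6, n_sites=100, seed=1)
        with pytest.raises(ValueError, match="match"):
            simulate_traits(other, v)


class TestColumns:
    def test_count_difference_by_construction(self):
        w = WorldConfig.default(n_per_deme=60, seed=4)
        cols = simulate_columns(w)
        counts = {}
        for hab in ("forest", "nonforest"):
            counts[hab] = np.mean([len(c.caudal) for c in cols
                                   if c.habitat == hab])
        assert counts["forest"] - counts["nonforest"] == pytest.approx(3.0,
                                                                       abs=0.4)

    def test_total_equals_sum_of_positions(self):
        w = WorldConfig.default(n_per_deme=5, measurement_sd_mm=0.0, seed=9)
        for c in simulate_columns(w):
            assert c.caudal.sum() == pytest.approx(c.lengths_mm[6:].sum(),
                                                   abs=1e-9)

    def test_profile_too_short_raises(self):
        with pytest.raises(ValueError, match="profile"):
            DemeConfig(label="x", clade="c", habitat="forest", mu_count=28,
                       sd_count=2.0)

    def test_determinism(self):
        w = WorldConfig.default(n_per_deme=5, seed=11)
        a = simulate_columns(w)
        b = simulate_columns(w)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.lengths_mm, cb.lengths_mm)


class TestIntercross:
    def test_exact_dominance_construction(self):
        spec = CrossSpec(mu_count_prairie=20, mu_count_forest=24,
                         env_sd_count=0.0, env_sd_len=0.0, seed=3)
        d = simulate_intercross(spec)
        assert set(d.generation("F1")["caudal_count"]) == {22}   # midparent
        assert set(d.generation("F1")["longest_caudal_mm"]) == {5.5}  # forest

    def test_generation_sizes(self):
        d = simulate_intercross(CrossSpec(seed=8))
        assert len(d.generation("P_prairie")) == 12
        assert len(d.generation("P_forest")) == 12
        assert len(d.generation("F1")) == 10
        assert len(d.generation("F2")) == 96

    def test_invalid_recombination_rejected(self):
        with pytest.raises(ValueError, match="recomb"):
            CrossSpec(recomb_fraction=0.7)

    def test_determinism(self):
        spec = CrossSpec(seed=21)
        a = simulate_intercross(spec).table
        b = simulate_intercross(spec).table
        pd.testing.assert_frame_equal(a, b)


class TestFixtures:
    def test_round_trip_and_truth_contract(self, tmp_path):
        w = WorldConfig.default(n_per_deme=4, n_sites=120, seed=13)
        v = simulate_genotypes(w)
        samples = simulate_traits(w, v)
        cols = simulate_columns(w)
        cross = simulate_intercross(CrossSpec(seed=13))
        written = write_fixtures(tmp_path, variants=v, samples=samples,
                                 columns=cols, cross=cross, config=w,
                                 cross_spec=CrossSpec(seed=13))
        back = VariantTable.from_vcf(written["vcf"])
        assert np.array_equal(back.dosage, v.dosage)
        assert back.ids == v.ids
        assert np.array_equal(back.gq, v.gq)

        truth = json.loads(open(written["truth"]).read())
        assert truth["seed"] == 13
        for key in ("n_sites", "F_clade", "F_deme", "beta_habitat",
                    "sigma_g", "sigma_e", "missing_rate", "demes"):
            assert key in truth["world"]

        vert = pd.read_csv(written["vertebrae"])
        assert vert["individual_id"].nunique() == len(cols)
        assert len(vert) == sum(len(c.lengths_mm) for c in cols)
        cols_back = columns_from_frame(vert)
        for ca, cb in zip(cols, cols_back):
            assert np.allclose(ca.lengths_mm, cb.lengths_mm, atol=1e-4)

        cross_back = pd.read_csv(written["cross"])
        assert (cross_back["generation"] == "F2").sum() == 96

    def test_columns_frame_round_trip(self):
        w = WorldConfig.default(n_per_deme=3, seed=2)
        cols = simulate_columns(w)
        back = columns_from_frame(columns_to_frame(cols))
        for ca, cb in zip(cols, back):
            assert ca.individual_id == cb.individual_id
            assert np.allclose(ca.lengths_mm, cb.lengths_mm)
            assert ca.habitat == cb.habitat
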