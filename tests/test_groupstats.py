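"""Mixed-model ANOVA, backward elimination, Waller-Duncan letters."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

import flockfit as ff
from flockfit.groupstats import significance_code


def two_way_layout(n=120, seed=0, breed_eff=0.0, sex_eff=0.0, inter_eff=0.0, sd=10.0):
    rng = np.random.default_rng(seed)
    breed = np.repeat(["BS", "BP"], n // 2)
    sex = np.tile(np.repeat(["F", "M"], n // 4), 2)
    y = rng.normal(100.0, sd, n)
    y += breed_eff * (breed == "BS") + sex_eff * (sex == "M")
    y += inter_eff * ((breed == "BS") & (sex == "M"))
    return y, breed, sex


class TestLm1Anova:
    def test_matches_statsmodels_without_relationship(self):
        y, breed, sex = two_way_layout(seed=1, sex_eff=15.0)
        res = ff.lm1_anova(ff.AnovaSpec(y, breed, sex))
        df = pd.DataFrame({"y": y, "breed": breed, "sex": sex})
        ref = anova_lm(smf.ols("y ~ C(breed) * C(sex)", df).fit(), typ=2)
        assert res.table.loc["breed", "F"] == pytest.approx(ref.loc["C(breed)", "F"], abs=1e-8)
        assert res.table.loc["sex", "F"] == pytest.approx(ref.loc["C(sex)", "F"], abs=1e-8)
        assert res.table.loc["breed:sex", "F"] == pytest.approx(
            ref.loc["C(breed):C(sex)", "F"], abs=1e-8
        )

    def test_identity_relationship_equals_plain_anova(self):
        y, breed, sex = two_way_layout(seed=2, breed_eff=8.0)
        plain = ff.lm1_anova(ff.AnovaSpec(y, breed, sex))
        ident = ff.lm1_anova(ff.AnovaSpec(y, breed, sex, relationship=np.eye(y.size)))
        for term in ("breed", "sex", "breed:sex"):
            assert ident.table.loc[term, "F"] == pytest.approx(
                plain.table.loc[term, "F"], abs=1e-8
            )

    def test_strong_sex_effect_detected(self):
        y, breed, sex = two_way_layout(n=200, seed=3, sex_eff=20.0, sd=10.0)  # 2 SD
        res = ff.lm1_anova(ff.AnovaSpec(y, breed, sex))
        assert res.table.loc["sex", "p"] < 1e-3
        assert res.table.loc["sex", "code"] == "***"

    def test_zero_variance_response_rejected(self):
        y = np.full(40, 100.0)
        breed = np.repeat(["BS", "BP"], 20)
        sex = np.tile(["F", "M"], 20)
        with pytest.raises(ValueError, match="zero variance"):
            ff.lm1_anova(ff.AnovaSpec(y, breed, sex))

    def test_relationship_validation(self):
        y, breed, sex = two_way_layout(n=8)
        bad = np.eye(8); bad[0, 1] = 0.5  # asymmetric
        with pytest.raises(ValueError, match="symmetric"):
            ff.AnovaSpec(y, breed, sex, relationship=bad)
        npsd = np.full((8, 8), 1.0); np.fill_diagonal(npsd, 1.0); npsd[0, 1] = npsd[1, 0] = -5
        with pytest.raises(ValueError):
            ff.AnovaSpec(y, breed, sex, relationship=npsd)

    def test_type_one_error_calibrated_under_null(self):
        """With no true effects each term rejects at ~alpha."""
        n_rep, n = 1000, 80
        rng = np.random.default_rng(42)
        breed = np.repeat(["BS", "BP"], n // 2)
        sex = np.tile(np.repeat(["F", "M"], n // 4), 2)
        hits = {"breed": 0, "sex": 0, "breed:sex": 0}
        for _ in range(n_rep):
            y = rng.normal(0.0, 1.0, n)
            res = ff.lm1_anova(ff.AnovaSpec(y, breed, sex))
            for term in hits:
                hits[term] += res.table.loc[term, "p"] < 0.05
        for term, h in hits.items():
            assert h / n_rep == pytest.approx(0.05, abs=0.02), term

    def test_structured_relationship_keeps_size_near_nominal(self):
        """Family structure in the response: the mixed model stays calibrated."""
        n_rep, n = 200, 60
        rng = np.random.default_rng(7)
        breed = np.repeat(["BS", "BP"], n // 2)
        sex = np.tile(np.repeat(["F", "M"], n // 4), 2)
        markers = ff.simulate_markers(n, 20, 4, seed=1, family_size=5)
        A = ff.relationship_from_markers(markers)
        L = np.linalg.cholesky(A + 1e-8 * np.eye(n))
        hits = 0
        for _ in range(n_rep):
            y = L @ rng.normal(0, 1, n) + rng.normal(0, 1, n)
            res = ff.lm1_anova(ff.AnovaSpec(y, breed, sex, relationship=A))
            hits += res.table.loc["breed", "p"] < 0.05
        assert hits / n_rep < 0.12  # nominal 5%, generous Monte-Carlo slack


class TestBackwardElimination:
    def test_null_effects_all_removed(self):
        removed_all = 0
        for seed in range(20):
            y, breed, sex = two_way_layout(seed=100 + seed)
            res = ff.backward_eliminate(ff.AnovaSpec(y, breed, sex))
            removed_all += not res.retained
        assert removed_all >= 15  # most null datasets drop every term

    def test_interaction_removed_mains_retained(self):
        y, breed, sex = two_way_layout(n=200, seed=5, breed_eff=10.0, sex_eff=10.0)
        res = ff.backward_eliminate(ff.AnovaSpec(y, breed, sex))
        assert "breed:sex" in res.eliminated
        assert set(res.retained) == {"breed", "sex"}

    def test_alpha_one_removes_nothing(self):
        y, breed, sex = two_way_layout(seed=6)
        res = ff.backward_eliminate(ff.AnovaSpec(y, breed, sex), alpha=1.0)
        assert res.retained == ["breed", "sex", "breed:sex"]
        assert not res.eliminated


class TestWallerDuncan:
    MSE, DF, N = 50 * 7.5**2, 196, 50  # SEM 7.5 at n=50 per group

    def test_equal_means_share_one_letter(self):
        letters = ff.waller_duncan([100.0] * 4, [self.N] * 4, self.MSE, self.DF, 1.5)
        assert len(set(letters.values())) == 1

    def test_widely_separated_means_all_distinct(self):
        se = np.sqrt(self.MSE / self.N)
        means = [100 + 10 * se * i for i in range(4)]
        f = self.N * np.var(means, ddof=1) / self.MSE
        letters = ff.waller_duncan(means, [self.N] * 4, self.MSE, self.DF, f)
        assert len(set(letters.values())) == 4

    def test_week_two_pattern(self):
        """Group means 138/159/186/184 with SEM 7.5: the two heavy groups
        share a letter, the two light ones are distinct from everything."""
        means = {"BS F": 138.0, "BS M": 159.0, "BP F": 186.0, "BP M": 184.0}
        f = self.N * np.var(list(means.values()), ddof=1) / self.MSE
        letters = ff.waller_duncan(means, {g: self.N for g in means}, self.MSE, self.DF, f)
        assert letters["BP F"] == letters["BP M"]
        assert letters["BS F"] != letters["BS M"]
        assert letters["BS F"] != letters["BP F"]

    def test_letter_assignment_invariant_to_ordering(self):
        means = {"a1": 186.0, "a2": 138.0, "a3": 184.0, "a4": 159.0}
        ns = {g: self.N for g in means}
        f = self.N * np.var(list(means.values()), ddof=1) / self.MSE
        l1 = ff.waller_duncan(means, ns, self.MSE, self.DF, f)
        rev = dict(reversed(list(means.items())))
        l2 = ff.waller_duncan(rev, ns, self.MSE, self.DF, f)
        assert l1 == l2

    def test_no_evidence_means_no_separation(self):
        # F <= 1: the k-ratio rule never declares a difference
        letters = ff.waller_duncan([100.0, 130.0], [10, 10], 400.0, 18, 0.8)
        assert len(set(letters.values())) == 1

    def test_critical_t_known_limit(self):
        # for k=100 and overwhelming F the rule approaches t ~ 1.72 (the
        # classic minimum of the published tables, at large error df)
        t = ff.waller_duncan_t(100.0, 1e12, 100000)
        assert t == pytest.approx(1.72, abs=0.03)

    def test_critical_t_increases_as_f_drops(self):
        ts = [ff.waller_duncan_t(100.0, f, 200) for f in (50.0, 10.0, 3.0, 1.5)]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_df_error_guard(self):
        with pytest.raises(ValueError):
            ff.waller_duncan([1.0, 2.0], [5, 5], 1.0, 0, 5.0)


class TestDimorphismDelta:
    @pytest.mark.parametrize(
        "f, m, expected",
        [(2184.0, 3074.0, 41), (1733.0, 2307.0, 33), (6401.0, 6949.0, 9), (86.0, 96.0, 12)],
    )
    def test_printed_values(self, f, m, expected):
        assert round(ff.dimorphism_delta(f, m)) == expected

    def test_equal_means_zero(self):
        assert ff.dimorphism_delta(5.0, 5.0) == 0.0

    def test_antisymmetry_identity(self):
        f, m = 1700.0, 2300.0
        assert ff.dimorphism_delta(f, m) == pytest.approx(
            -ff.dimorphism_delta(m, f) * m / f
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            ff.dimorphism_delta(0.0, 10.0)


class TestRelationshipFromMarkers:
    def test_identical_genotypes_full_similarity(self):
        g = np.tile(np.array([[0, 1], [2, 2], [3, 4]]), (2, 1, 1))
        sim = ff.relationship_from_markers(g)
        assert sim[0, 1] == 1.0

    def test_definition_on_single_locus(self):
        g = np.array([[[0, 1]], [[2, 3]], [[0, 2]], [[0, 0]]], dtype=float)
        sim = ff.relationship_from_markers(g)
        assert sim[0, 1] == 0.0  # AB vs CD
        assert sim[0, 2] == 0.5  # AB vs AC
        assert sim[0, 3] == 0.5  # AB vs AA (one shared copy)

    def test_mean_similarity_matches_expected_identity(self):
        # uniform alleles: P(two random birds share alleles) has a closed
        # brute-force expectation; check the mean off-diagonal against it
        n_alleles, n = 5, 80
        g = ff.simulate_markers(n, 30, n_alleles, seed=9)
        sim = ff.relationship_from_markers(g)
        off = sim[np.triu_indices(n, 1)]
        # expected shared fraction per locus for two random diploids:
        # enumerate all genotype pairs under uniform frequencies
        from itertools import product
        alleles = range(n_alleles)
        total, weight = 0.0, 0.0
        for a1, a2, b1, b2 in product(alleles, repeat=4):
            pa = (a1 == b1) + (a1 == b2), (a2 == b1) + (a2 == b2)
            ga, gb = tuple(sorted((a1, a2))), tuple(sorted((b1, b2)))
            shared = 2 if ga == gb else (1 if (pa[0] or pa[1]) else 0)
            total += shared / 2.0
            weight += 1
        assert off.mean() == pytest.approx(total / weight, abs=0.01)

    def test_symmetric_unit_diagonal(self):
        g = ff.simulate_markers(10, 5, 3, seed=2)
        sim = ff.relationship_from_markers(g)
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)


def test_significance_codes_match_legend():
    assert significance_code(0.2) == "n.s."
    assert significance_code(0.04) == "*"
    assert significance_code(0.009) == "**"
    assert significance_code(0.0009) == "***"
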