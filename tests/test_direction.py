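"""Direction statistics: classification, TDRed, KS symmetry, clumping, Vp."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mutpolar.direction import (
    class_summary,
    classify_effects,
    ks_direction_test,
    ld_clump,
    ma_direction_ratio,
    tdred,
    variance_explained,
)


def assoc_frame(p_values, betas, pos=None):
    m = len(p_values)
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "C",
            "beta_ma": betas,
            "p": p_values,
        }
    )


class TestClassification:
    @pytest.mark.parametrize(
        "p1,p2,b1,b2,expected",
        [
            (1e-9, 1e-10, -0.5, -0.3, "large"),
            (1e-6, 1e-7, 0.2, 0.4, "medium"),
            (1e-3, 1e-4, 0.2, 0.4, "small"),
            (1e-9, 1e-10, -0.5, 0.3, "unclassified"),   # discordant signs
            (1e-9, 1e-3, -0.5, -0.3, "unclassified"),   # windows differ
            (0.2, 0.3, 0.1, 0.1, "unclassified"),       # both non-significant
            (5e-8, 5e-8, 0.1, 0.1, "medium"),           # boundary inclusive
            (5e-5, 5e-5, 0.1, 0.1, "small"),
        ],
    )
    def test_rule_table(self, p1, p2, b1, b2, expected):
        bull = assoc_frame([p1], [b1])
        cow = assoc_frame([p2], [b2])
        out = classify_effects(bull, cow)
        assert out["effect_class"].iloc[0] == expected

    @given(
        p1=st.floats(1e-12, 0.999), p2=st.floats(1e-12, 0.999),
        b1=st.floats(-1, 1).filter(lambda x: x != 0),
        b2=st.floats(-1, 1).filter(lambda x: x != 0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_classification_is_a_partition(self, p1, p2, b1, b2):
        out = classify_effects(assoc_frame([p1], [b1]), assoc_frame([p2], [b2]))
        assert out["effect_class"].iloc[0] in {
            "large", "medium", "small", "unclassified"
        }


class TestTdred:
    def test_all_concordant_is_one(self):
        assert tdred([1, -1, 1], [0.5, -2, 3]) == 1.0

    def test_chance_level_is_zero(self):
        s1 = [1, 1, -1, -1]
        s2 = [1, -1, 1, -1]
        assert tdred(s1, s2) == 0.0

    def test_ninety_percent_concordance(self):
        s1 = np.ones(10)
        s2 = np.ones(10)
        s2[0] = -1
        assert tdred(s1, s2) == pytest.approx(0.8)

    def test_zero_signs_rejected(self):
        with pytest.raises(ValueError):
            tdred([1, 0], [1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tdred([], [])


class TestDirectionRatio:
    def test_thirty_twenty_gives_1_5(self):
        b = np.concatenate([np.ones(30), -np.ones(20)])
        out = ma_direction_ratio(b)
        assert out == {"n_plus": 30, "n_minus": 20, "ratio": 1.5}

    def test_equal_counts_give_one(self):
        assert ma_direction_ratio([1, -1, 2, -2])["ratio"] == 1.0

    def test_no_decreasing_reports_infinite(self):
        out = ma_direction_ratio([0.1, 0.2])
        assert np.isinf(out["ratio"]) and out["n_minus"] == 0

    def test_generated_fraction_recovered(self, rng):
        # 60% of mutant alleles trait-decreasing by construction
        signs = rng.choice([1.0, -1.0], p=[0.4, 0.6], size=5000)
        out = ma_direction_ratio(signs * rng.uniform(0.1, 1, 5000))
        assert out["ratio"] < 1
        assert out["n_minus"] / 5000 == pytest.approx(0.6, abs=0.03)


class TestKsDirection:
    def test_symmetric_effects_not_significant(self, rng):
        b = rng.normal(0, 1, 2000)
        b = np.concatenate([b, -b])  # exactly symmetric
        d, p = ks_direction_test(b)
        assert d < 0.05 and p > 0.2

    def test_all_negative_gives_d_one(self):
        d, _ = ks_direction_test(-np.abs(np.random.default_rng(0).normal(size=50)) - 0.01)
        assert d == 1.0

    def test_permutation_invariant(self, rng):
        b = rng.normal(0.2, 1, 500)
        d1, p1 = ks_direction_test(b)
        d2, p2 = ks_direction_test(rng.permutation(b))
        assert d1 == d2 and p1 == p2

    def test_signflip_mode_uniform_p_under_symmetric_null(self, rng):
        from scipy.stats import kstest

        ps = []
        for i in range(100):
            b = rng.normal(0, 1, 300)
            ps.append(ks_direction_test(b, mode="signflip", n_resample=200,
                                        seed=i)[1])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_asymptotic_mode_known_anticonservative(self, rng):
        # the printed-procedure comparison feeds dependent samples to the
        # two-sample null distribution; its type-I error runs about twice
        # nominal -- pin that behaviour down so it cannot silently change
        ps = []
        for _ in range(300):
            b = rng.normal(0, 1, 400)
            ps.append(ks_direction_test(b)[1])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.05 <= frac <= 0.2

    def test_too_few_effects_rejected(self):
        with pytest.raises(ValueError):
            ks_direction_test([0.3])


class TestLdClump:
    def test_perfect_ld_keeps_smallest_p(self, rng):
        x = rng.binomial(2, 0.5, 100).astype(float)
        g = np.column_stack([x, x, x])
        assoc = assoc_frame([0.5, 1e-6, 0.01], [1, 1, 1], pos=[1000, 2000, 3000])
        kept = ld_clump(assoc, g)
        assert kept.tolist() == [1]

    def test_distant_variants_all_retained(self, rng):
        x = rng.binomial(2, 0.5, 100).astype(float)
        g = np.column_stack([x, x, x])
        assoc = assoc_frame(
            [0.5, 1e-6, 0.01], [1, 1, 1], pos=[1, 2_000_000, 4_000_000]
        )
        kept = ld_clump(assoc, g)
        assert kept.tolist() == [0, 1, 2]

    def test_block_structure_keeps_one_per_block(self, rng):
        blocks = []
        for _ in range(5):
            x = rng.binomial(2, 0.5, 200).astype(float)
            blocks.extend([x, x, x])
        g = np.column_stack(blocks)
        assoc = assoc_frame(rng.uniform(size=15), np.ones(15))
        kept = ld_clump(assoc, g)
        assert len(kept) == 5
        assert sorted(k // 3 for k in kept) == [0, 1, 2, 3, 4]

    def test_clump_invariants_on_random_instances(self, rng):
        # 1) no two retained variants within the window have r^2 >= 0.3
        # 2) every removed variant is within the window of, and in LD with,
        #    a retained variant of smaller (or equal, by tie order) p
        for trial in range(5):
            n, m = 80, 40
            base = rng.binomial(2, 0.5, size=(n, 8)).astype(float)
            cols = base[:, rng.integers(0, 8, m)].copy()
            noise = rng.random(size=(n, m)) < 0.2
            cols[noise] = rng.integers(0, 3, size=noise.sum())
            pos = np.sort(rng.integers(1, 3_000_000, m))
            assoc = assoc_frame(rng.uniform(size=m), np.ones(m), pos=pos)
            kept = ld_clump(assoc, cols)
            kept_set = set(kept.tolist())

            def r2(i, j):
                return np.corrcoef(cols[:, i], cols[:, j])[0, 1] ** 2

            p = assoc["p"].to_numpy()
            for i in kept:
                for j in kept:
                    if i < j and abs(pos[i] - pos[j]) < 1_000_000:
                        assert r2(i, j) < 0.3
            for j in range(m):
                if j in kept_set:
                    continue
                partners = [
                    i for i in kept
                    if abs(pos[i] - pos[j]) < 1_000_000
                    and r2(i, j) >= 0.3 and p[i] <= p[j]
                ]
                assert partners, f"removed variant {j} has no claiming index"


class TestVarianceExplained:
    def test_direct_substitution(self):
        assert variance_explained(0.2, 0.05, 100) == pytest.approx(0.16)

    def test_zero_beta_gives_zero(self):
        assert variance_explained(0.0, 0.1, 50) == 0.0

    def test_agrees_with_frequency_formula_in_simulation(self, rng):
        # on a standardized trait, (b/se)^2/N ~= 2p(1-p) b^2
        n = 60_000
        p_freq = 0.3
        x = rng.binomial(2, p_freq, n).astype(float)
        b_true = 0.06
        y = b_true * x + rng.normal(0, 1, n)
        y = (y - y.mean()) / y.std()
        X = np.column_stack([np.ones(n), x])
        coef, res_ss = np.linalg.lstsq(X, y, rcond=None)[:2]
        se = float(np.sqrt(res_ss[0] / (n - 2) / np.sum((x - x.mean()) ** 2)))
        vp1 = variance_explained(coef[1], se, n)
        vp2 = 2 * p_freq * (1 - p_freq) * coef[1] ** 2
        assert vp1 == pytest.approx(vp2, rel=0.02)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.0, 10)


class TestClassSummary:
    def _inputs(self, rng, m=60):
        g = rng.binomial(2, 0.5, size=(100, m)).astype(float)
        eff = assoc_frame(rng.uniform(1e-10, 0.04, m), rng.normal(size=m))
        eff["se"] = rng.uniform(0.05, 0.1, m)
        eff["effect_class"] = "small"
        return eff, g

    def test_single_class_matches_direct_computation(self, rng):
        eff, g = self._inputs(rng)
        out = class_summary(eff, g, n_gwas=100, classes=("small",))
        row = out.iloc[0]
        direct = ma_direction_ratio(eff["beta_ma"])
        assert row["n_plus"] == direct["n_plus"]
        assert row["ratio"] == direct["ratio"]
        vp = variance_explained(eff["beta_ma"], eff["se"], 100)
        assert row["mean_vp"] == pytest.approx(np.mean(vp))

    def test_empty_class_reports_zero_counts_and_nan_stats(self, rng):
        eff, g = self._inputs(rng)
        out = class_summary(eff, g, n_gwas=100, classes=("large",))
        row = out.iloc[0]
        assert row["n"] == 0 and np.isnan(row["mean_vp"])

    def test_clumped_se_reflects_block_correlation(self, rng):
        # duplicated-column LD blocks: the SE over clumped representatives
        # must exceed the naive SE over all (correlated) variants
        x = rng.binomial(2, 0.5, size=(150, 10)).astype(float)
        g = np.repeat(x, 6, axis=1)  # 10 blocks x 6 copies
        m = 60
        block_vals = rng.normal(0.5, 0.3, 10)
        betas = np.repeat(block_vals, 6) + rng.normal(0, 0.01, m)
        eff = assoc_frame(rng.uniform(1e-4, 0.04, m), betas)
        eff["se"] = 0.1
        eff["effect_class"] = "small"
        out = class_summary(eff, g, n_gwas=150, classes=("small",))
        row = out.iloc[0]
        assert row["n_clumped"] == 10
        vp = variance_explained(eff["beta_ma"], eff["se"], 150)
        naive_se = np.std(vp, ddof=1) / np.sqrt(m)
        assert row["se_vp"] > naive_se
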