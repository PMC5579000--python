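import numpy as np
import pytest
from scipy import stats

from clock3.cohort import (CohortEffects, adjust_meq, allele_chronotype_table,
                           chi_square_independence, classify_chronotype,
                           cohort_to_frame, generate_synthetic_cohort,
                           genotype_score_summary, odds_ratio_ci)


@pytest.mark.parametrize("meq, age, expected", [
    (50, 39.212, 50.0),                 # reference age: adjustment vanishes
    (50, 19.212, 57.024),               # 0.3512 * 20 added
    (20, 39.212, 20.0),
])
def test_adjust_meq_printed_formula(meq, age, expected):
    assert adjust_meq(meq, age) == pytest.approx(expected, abs=1e-9)


def test_adjust_meq_affine_and_decreasing_in_age():
    ages = np.linspace(18, 80, 20)
    vals = [adjust_meq(50, a) for a in ages]
    assert all(b < a for a, b in zip(vals, vals[1:]))
    second_diff = np.diff(vals, 2)
    assert np.allclose(second_diff, 0.0, atol=1e-12)


def test_odds_ratio_examples():
    assert odds_ratio_ci([[10, 10], [10, 10]])["OR"] == pytest.approx(1.0)
    r = odds_ratio_ci([[20, 10], [10, 20]])
    assert r["OR"] == pytest.approx(4.0)
    assert r["CI_low"] < 4.0 < r["CI_high"]


def test_odds_ratio_row_swap_inverts():
    a = odds_ratio_ci([[20, 10], [10, 20]])["OR"]
    b = odds_ratio_ci([[10, 20], [20, 10]])["OR"]
    assert a * b == pytest.approx(1.0)


def test_odds_ratio_zero_cell_continuity_correction():
    r = odds_ratio_ci([[0, 10], [10, 10]])
    assert r["continuity_corrected"]
    assert np.isfinite(r["OR"]) and r["OR"] > 0


def test_odds_ratio_zero_margin_errors():
    with pytest.raises(ValueError, match="margin"):
        odds_ratio_ci([[0, 0], [10, 10]])


def test_chi_square_hand_computed_example():
    r = chi_square_independence([[10, 20], [20, 10]])
    assert r["statistic"] == pytest.approx(20.0 / 3.0, rel=1e-12)
    assert r["df"] == 1


def test_chi_square_proportional_table_is_zero():
    r = chi_square_independence([[10, 20], [20, 40]])
    assert r["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert r["p"] == pytest.approx(1.0)


def test_chi_square_df_for_2x3():
    assert chi_square_independence([[5, 6, 7], [8, 9, 10]])["df"] == 2


def test_chi_square_permutation_invariance():
    t = np.array([[12, 5, 9], [3, 14, 7]])
    base = chi_square_independence(t)["statistic"]
    rng = np.random.default_rng(0)
    for _ in range(5):
        tt = t[rng.permutation(2)][:, rng.permutation(3)]
        assert chi_square_independence(tt)["statistic"] == pytest.approx(base)


def test_genotype_summary_equal_scores():
    cohort = generate_synthetic_cohort(
        n=400, seed=5,
        effects=CohortEffects(meq_shift_per_g_allele=0.0,
                              meq_shift_per_4_allele=0.0,
                              stai_shift_per_g_allele=0.0,
                              stai_shift_per_4_allele=0.0))
    rep = genotype_score_summary(cohort, "STAI", "vntr")
    assert rep["anova"]["p"] > 0.01  # no planted effect to detect


def test_generator_rejects_bad_inputs():
    with pytest.raises(ValueError):
        generate_synthetic_cohort(n=0)
    with pytest.raises(ValueError):
        generate_synthetic_cohort(g_allele_freq=1.5)


def test_allele_frequency_one_gives_all_homozygotes():
    cohort = generate_synthetic_cohort(n=100, g_allele_freq=1.0, seed=1)
    assert all(r.snp_genotype == "GG" for r in cohort)


def test_generator_hardy_weinberg_and_reproducible():
    a = generate_synthetic_cohort(n=5000, four_allele_freq=0.45, seed=9)
    b = generate_synthetic_cohort(n=5000, four_allele_freq=0.45, seed=9)
    assert [r.vntr_genotype for r in a] == [r.vntr_genotype for r in b]
    counts = {g: sum(r.vntr_genotype == g for r in a)
              for g in ("4/4", "4/5", "5/5")}
    q = 0.45
    exp = {"4/4": q * q, "4/5": 2 * q * (1 - q), "5/5": (1 - q) ** 2}
    for g in counts:
        assert counts[g] / 5000 == pytest.approx(exp[g], abs=0.02)


def _implied_allele_or(effects: CohortEffects, q: float) -> float:
    """Closed-form oracle for the morning-vs-evening allele odds ratio implied
    by the Gaussian score mixture: class probabilities per genotype follow
    from the normal CDF at the MEQ cut-points."""
    morning, evening = {}, {}
    for copies, hw in ((0, (1 - q) ** 2), (1, 2 * q * (1 - q)), (2, q * q)):
        mu = effects.meq_mean + effects.meq_shift_per_4_allele * copies
        evening[copies] = hw * stats.norm.cdf((41.0 - mu) / effects.meq_sd)
        morning[copies] = hw * stats.norm.sf((59.0 - mu) / effects.meq_sd)
    def allele_counts(cls):
        four = sum(cls[c] * c for c in cls)
        five = sum(cls[c] * (2 - c) for c in cls)
        return four, five
    m4, m5 = allele_counts(morning)
    e4, e5 = allele_counts(evening)
    return (m5 * e4) / (m4 * e5)   # rows (5,4) x cols (morning, evening)


def test_generator_estimator_or_round_trip():
    """The allele-chronotype odds ratio measured on a large synthetic cohort
    matches the closed-form value implied by the planted effect sizes."""
    effects = CohortEffects(meq_shift_per_g_allele=0.0,
                            meq_shift_per_4_allele=-6.0,
                            stai_shift_per_g_allele=0.0,
                            stai_shift_per_4_allele=0.0)
    q = 0.45
    implied = _implied_allele_or(effects, q)
    assert implied > 1.5  # the planted effect is substantial
    cohort = generate_synthetic_cohort(n=100_000, four_allele_freq=q,
                                       effects=effects, seed=17)
    table = allele_chronotype_table(cohort, "vntr")
    measured = odds_ratio_ci(table)["OR"]
    assert measured == pytest.approx(implied, rel=0.10)


def test_planted_stai_effect_direction():
    cohort = generate_synthetic_cohort(
        n=20_000, seed=3,
        effects=CohortEffects(stai_shift_per_g_allele=4.0))
    rep = genotype_score_summary(cohort, "STAI", "snp")
    means = {g: v["mean"] for g, v in rep["groups"].items()}
    assert means["GG"] > means["CG"] > means["CC"]


def test_chronotype_classification_cutpoints():
    assert classify_chronotype(59.0) == "morning"
    assert classify_chronotype(41.0) == "evening"
    assert classify_chronotype(50.0) == "intermediate"


def test_cohort_frame_round_trip():
    cohort = generate_synthetic_cohort(n=50, seed=2)
    df = cohort_to_frame(cohort)
    assert len(df) == 50
    assert set(df["chronotype"]) <= {"morning", "intermediate", "evening"}
    assert (df["meq_raw"].between(20, 80)).all()
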