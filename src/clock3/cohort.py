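"""Genotype–phenotype cohort statistics on synthetic study populations.

Implements the human-data scoring used in chronotype association studies:
age adjustment of the Horne–Östberg Morningness–Eveningness Questionnaire
(MEQ, 20 = extreme morning to 80 = extreme evening), allele/genotype
contingency statistics (odds ratios with Wald confidence intervals, Pearson
chi-squared tests) and per-genotype score summaries (one-way ANOVA and
pairwise t-tests delegated to SciPy).

The synthetic cohort generator emulates the structure of a two-locus
(PER3 SNP rs228697 C/G; PER3 VNTR rs57875989 4/5-repeat) chronotype study:
Hardy–Weinberg genotypes, genotype-dependent shifts of the mean adjusted MEQ
score and trait-anxiety (STAI) score, chronotype classes assigned from the
adjusted MEQ by the standard banding (≥ 59 morning, ≤ 41 evening).  It
provides ground-truth effect sizes for estimator round-trip tests; it does
not reproduce any real cohort's counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortRecord",
    "CohortEffects",
    "adjust_meq",
    "classify_chronotype",
    "odds_ratio_ci",
    "chi_square_independence",
    "genotype_score_summary",
    "generate_synthetic_cohort",
    "cohort_to_frame",
    "allele_chronotype_table",
]

MEQ_MIN, MEQ_MAX = 20, 80
#: standard MEQ banding for chronotype classes
MEQ_MORNING_CUT = 59.0
MEQ_EVENING_CUT = 41.0

SNP_GENOTYPES = ("CC", "CG", "GG")
VNTR_GENOTYPES = ("4/4", "4/5", "5/5")


@dataclass(frozen=True)
class CohortRecord:
    participant_id: str
    age: float
    sex: str
    meq_raw: int
    stai_trait: int
    snp_genotype: str
    vntr_genotype: str
    chronotype: str = ""

    def __post_init__(self) -> None:
        if not (MEQ_MIN <= self.meq_raw <= MEQ_MAX):
            raise ValueError(f"MEQ score {self.meq_raw} outside [20, 80]")
        if self.snp_genotype not in SNP_GENOTYPES:
            raise ValueError(f"bad SNP genotype {self.snp_genotype!r}")
        if self.vntr_genotype not in VNTR_GENOTYPES:
            raise ValueError(f"bad VNTR genotype {self.vntr_genotype!r}")


def adjust_meq(meq_raw: float, age: float) -> float:
    """Age-adjusted MEQ score: ``meq_raw + 0.3512 * (39.212 - age)``.

    Affine and monotone decreasing in age; at the reference age 39.212 the
    adjustment vanishes.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    return meq_raw + 0.3512 * (39.212 - age)


def classify_chronotype(meq_adjusted: float) -> str:
    if meq_adjusted >= MEQ_MORNING_CUT:
        return "morning"
    if meq_adjusted <= MEQ_EVENING_CUT:
        return "evening"
    return "intermediate"


def odds_ratio_ci(table: Sequence[Sequence[float]], confidence: float = 0.95
                  ) -> dict:
    """Odds ratio ad/bc of a 2×2 count table with a Wald log-scale CI.

    Zero cells get the Haldane–Anscombe 0.5 continuity correction (flagged in
    the output); a zero margin is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: odds ratio undefined")
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    (a, b), (c, d) = t
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    return {
        "OR": float(or_),
        "CI_low": float(np.exp(np.log(or_) - z * se)),
        "CI_high": float(np.exp(np.log(or_) + z * se)),
        "confidence": confidence,
        "continuity_corrected": corrected,
    }


def chi_square_independence(table: Sequence[Sequence[float]]) -> dict:
    """Pearson chi-squared test of independence; df = (r−1)(c−1), always
    reported explicitly."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2 or np.any(t < 0):
        raise ValueError("need a nonnegative table with at least 2x2 cells")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: empty row or column")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    expected = row * col / t.sum()
    statistic = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return {"statistic": statistic, "df": df, "p": p}


def genotype_score_summary(cohort: Sequence[CohortRecord],
                           score: Literal["MEQ", "STAI"],
                           grouping: Literal["snp", "vntr"]) -> dict:
    """Per-genotype mean ± SD with one-way ANOVA and pairwise Welch t-tests."""
    df = cohort_to_frame(cohort)
    col = "meq_adjusted" if score == "MEQ" else "stai_trait"
    key = "snp_genotype" if grouping == "snp" else "vntr_genotype"
    groups = {g: sub[col].to_numpy() for g, sub in df.groupby(key)}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype groups with >= 2 members each")
    names = sorted(groups)
    f_stat, f_p = stats.f_oneway(*[groups[g] for g in names])
    pairwise = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            t_stat, t_p = stats.ttest_ind(groups[gi], groups[gj],
                                          equal_var=False)
            pairwise[f"{gi} vs {gj}"] = {"t": float(t_stat), "p": float(t_p)}
    return {
        "score": score,
        "groups": {g: {"n": int(len(v)), "mean": float(v.mean()),
                       "sd": float(v.std(ddof=1))} for g, v in groups.items()},
        "anova": {"F": float(f_stat), "p": float(f_p),
                  "df_between": len(names) - 1,
                  "df_within": int(sum(len(v) for v in groups.values()))
                  - len(names)},
        "pairwise": pairwise,
    }


@dataclass(frozen=True)
class CohortEffects:
    """Planted effect sizes for the generator (score-scale units: a genotype's
    shift of the mean adjusted MEQ / STAI score per risk allele copy)."""

    meq_shift_per_g_allele: float = -3.5   # G allele pushes toward eveningness
    meq_shift_per_4_allele: float = -3.0   # 4-repeat allele likewise
    stai_shift_per_g_allele: float = 2.0   # and both raise trait anxiety
    stai_shift_per_4_allele: float = 1.5
    meq_sd: float = 9.0
    stai_mean: float = 40.0
    stai_sd: float = 8.0
    meq_mean: float = 50.0


def generate_synthetic_cohort(n: int = 380,
                              g_allele_freq: float = 0.10,
                              four_allele_freq: float = 0.45,
                              effects: CohortEffects | None = None,
                              seed: int = 0,
                              age_range: tuple[float, float] = (18.0, 38.0),
                              ) -> list[CohortRecord]:
    """Draw a seeded synthetic genotype–phenotype cohort.

    Genotypes are Hardy–Weinberg at the stated allele frequencies; adjusted
    MEQ and STAI means shift additively per risk-allele copy; chronotype is
    assigned from the adjusted MEQ by the standard banding.  With zero effect
    sizes the genotype groups share one score distribution.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    for f in (g_allele_freq, four_allele_freq):
        if not 0.0 <= f <= 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")
    effects = effects or CohortEffects()
    rng = np.random.default_rng(seed)

    def hw_draw(q: float, labels: tuple[str, str, str]) -> np.ndarray:
        # q = risk-allele frequency; labels ordered (ref/ref, het, risk/risk)
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        return rng.choice(np.array(labels), size=n, p=probs)

    snp = hw_draw(g_allele_freq, SNP_GENOTYPES)
    vntr = hw_draw(four_allele_freq, ("5/5", "4/5", "4/4"))
    g_copies = np.char.count(snp.astype(str), "G")
    four_copies = np.char.count(vntr.astype(str), "4")

    ages = rng.uniform(*age_range, size=n)
    sexes = rng.choice(np.array(["F", "M"]), size=n, p=[0.64, 0.36])

    meq_adj_mean = (effects.meq_mean
                    + effects.meq_shift_per_g_allele * g_copies
                    + effects.meq_shift_per_4_allele * four_copies)
    meq_adj = rng.normal(meq_adj_mean, effects.meq_sd)
    # report the raw (un-adjusted) integer score the questionnaire would give
    meq_raw = np.clip(np.rint(meq_adj - 0.3512 * (39.212 - ages)),
                      MEQ_MIN, MEQ_MAX).astype(int)
    stai = np.clip(np.rint(rng.normal(
        effects.stai_mean
        + effects.stai_shift_per_g_allele * g_copies
        + effects.stai_shift_per_4_allele * four_copies,
        effects.stai_sd)), 20, 80).astype(int)

    out = []
    for i in range(n):
        rec = CohortRecord(
            participant_id=f"S{i:05d}", age=float(ages[i]), sex=str(sexes[i]),
            meq_raw=int(meq_raw[i]), stai_trait=int(stai[i]),
            snp_genotype=str(snp[i]), vntr_genotype=str(vntr[i]),
            chronotype=classify_chronotype(
                adjust_meq(float(meq_raw[i]), float(ages[i]))),
        )
        out.append(rec)
    return out


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in cohort])
    df["meq_adjusted"] = [adjust_meq(r.meq_raw, r.age) for r in cohort]
    if "chronotype" not in df or (df["chronotype"] == "").any():
        df["chronotype"] = [classify_chronotype(v) for v in df["meq_adjusted"]]
    return df


def allele_chronotype_table(cohort: Sequence[CohortRecord],
                            locus: Literal["snp", "vntr"] = "snp",
                            classes: tuple[str, str] = ("morning", "evening"),
                            ) -> np.ndarray:
    """2×2 allele-count table: rows = alleles, columns = chronotype classes."""
    df = cohort_to_frame(cohort)
    key = "snp_genotype" if locus == "snp" else "vntr_genotype"
    alleles = ("C", "G") if locus == "snp" else ("5", "4")
    sep = "" if locus == "snp" else "/"
    table = np.zeros((2, 2))
    for j, cls in enumerate(classes):
        sub = df[df["chronotype"] == cls]
        geno = sub[key].str.replace("/", "", regex=False)
        for i, allele in enumerate(alleles):
            table[i, j] = geno.str.count(allele).sum()
    return table
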