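"""Generator genetics: penetrance rule, transmission, coding, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zwscan.simdata import (
    NORMAL_ZZ,
    PSEUDOMALE_ZW,
    SimConfig,
    causal_marker_ids,
    inject_missingness,
    simulate_population,
    simulate_ztw_cohort,
)

SMALL = dict(marker_scale=0.01, n_offspring_per_family=20)


def test_reversal_follows_rule_exactly_without_noise(small_population):
    _, geno, pheno, truth = small_population
    merged = pheno.merge(truth, on="id")
    zw = merged[merged.genetic_sex == "ZW"]
    assert (zw.reversal == zw.rule_reversal).all()
    # the rule itself: T at locus1 AND >=1 A at locus2
    expect = (
        (zw.g1_allele == "T") & zw.g2_genotype.str.contains("A")
    ).astype(int)
    assert (zw.reversal.to_numpy() == expect.to_numpy()).all()
    # ZZ individuals are never reversed
    assert (merged.loc[merged.genetic_sex == "ZZ", "reversal"] == 0).all()


def test_no_reversal_without_unfavorable_alleles(small_population):
    _, _, pheno, truth = small_population
    merged = pheno.merge(truth, on="id")
    zw = merged[merged.genetic_sex == "ZW"]
    assert (zw.loc[zw.g1_allele == "A", "reversal"] == 0).all()
    assert (zw.loc[zw.g2_genotype == "GG", "reversal"] == 0).all()


def test_penetrance_noise_flips_at_configured_rate():
    cfg = SimConfig(**SMALL, n_families=9, penetrance_noise=0.1, seed=21)
    _, pheno, truth = simulate_population(cfg)
    merged = pheno.merge(truth, on="id")
    zw = merged[merged.genetic_sex == "ZW"]
    flipped = (zw.reversal != zw.rule_reversal).mean()
    n = len(zw)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.1) / n
    assert lo <= flipped <= hi


def test_hemizygous_z_coding_never_heterozygous(small_population):
    _, geno, pheno, _ = small_population
    z_cols = (geno.marker_map.chromosome == "Z").to_numpy()
    zw_rows = (pheno.genetic_sex == "ZW").to_numpy()
    vals = geno.values[np.ix_(zw_rows, np.flatnonzero(z_cols))]
    assert set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 2.0}
    # W markers are missing in ZZ individuals, hemizygous-coded in ZW
    w_cols = np.flatnonzero((geno.marker_map.chromosome == "W").to_numpy())
    assert np.isnan(geno.values[np.ix_(~zw_rows, w_cols)]).all()


def test_duplication_flag_allows_heterozygous_locus2():
    cfg = SimConfig(**SMALL, duplication_het_rate=0.2, seed=5)
    geno, pheno, truth = simulate_population(cfg)
    zw = truth.merge(pheno, on="id").query("genetic_sex == 'ZW'")
    assert (zw.g2_genotype == "AG").any()
    j = geno.marker_index(causal_marker_ids(cfg)[1])
    assert (geno.values[:, j] == 1.0).any()


def test_pseudomale_sire_gives_1to1_zw_zz_and_no_w_from_sire():
    cfg = SimConfig(
        marker_scale=0.01, n_families=4, n_offspring_per_family=250,
        sire_types=PSEUDOMALE_ZW, seed=7,
    )
    geno, pheno, truth = simulate_population(cfg)
    frac_zw = (pheno.genetic_sex == "ZW").mean()
    assert abs(frac_zw - 0.5) < 0.05  # ZW:ZZ ~ 1:1, never WW
    # every ZW offspring of a pseudomale carries the sire's intact T-A Z
    zw = truth.merge(pheno, on="id").query("genetic_sex == 'ZW'")
    assert (zw.g1_allele == "T").all()
    assert (zw.g2_genotype == "AA").all()
    assert (zw.reversal == 1).all()


def test_normal_sire_families_segregate():
    cfg = SimConfig(**SMALL, sire_types=NORMAL_ZZ, seed=3)
    _, pheno, _ = simulate_population(cfg)
    frac_zw = (pheno.genetic_sex == "ZW").mean()
    assert abs(frac_zw - 0.5) < 0.12


def test_founder_allele_frequencies_within_bounds():
    cfg = SimConfig(
        marker_scale=0.02, n_families=9, n_offspring_per_family=60,
        maf_low=0.2, maf_high=0.4, seed=9,
    )
    geno, pheno, _ = simulate_population(cfg)
    auto = ~geno.marker_map.chromosome.isin(["Z", "W"]).to_numpy()
    freqs = np.nanmean(geno.values[:, auto], axis=0) / 2
    # offspring frequencies drift around founder draws in [0.2, 0.4]
    assert freqs.mean() > 0.15 and freqs.mean() < 0.45
    assert (freqs > 0.02).all() and (freqs < 0.7).all()


def test_same_seed_is_bit_identical():
    cfg = SimConfig(**SMALL, seed=13)
    g1, p1, t1 = simulate_population(cfg)
    g2, p2, t2 = simulate_population(cfg)
    assert np.array_equal(g1.values, g2.values, equal_nan=True)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(t1, t2)
    assert g1.marker_ids == g2.marker_ids


def test_config_validation_errors():
    with pytest.raises(ValueError, match="Z chromosome"):
        SimConfig(marker_counts={"1": 10}).validate()
    with pytest.raises(ValueError, match="causal position"):
        SimConfig(causal_positions=(10, 10**9)).validate()
    with pytest.raises(ValueError, match="missing_rate|\\[0,1\\]"):
        SimConfig(missing_rate=1.5).validate()


def test_ztw_cohort_is_exact_size_and_all_carry_t():
    cfg = SimConfig(marker_scale=0.01, n_offspring_per_family=12, seed=2)
    geno, pheno, truth = simulate_ztw_cohort(60, cfg)
    assert geno.n_individuals == len(pheno) == len(truth) == 60
    assert (pheno.genetic_sex == "ZW").all()
    assert (truth.g1_allele == "T").all()


class TestInjectMissingness:
    def test_rate_zero_is_identity(self, small_population):
        _, geno, _, _ = small_population
        out = inject_missingness(geno, 0.0, seed=1)
        assert np.array_equal(out.values, geno.values, equal_nan=True)

    def test_rate_one_rejected(self, small_population):
        _, geno, _, _ = small_population
        with pytest.raises(ValueError):
            inject_missingness(geno, 1.0, seed=1)

    def test_missing_count_within_binomial_bounds(self, rng):
        from zwscan.io import GenotypeData
        import pandas as pd

        n_calls = 10_000
        mm = pd.DataFrame({
            "marker_id": [f"m{j}" for j in range(100)],
            "chromosome": "1",
            "position_bp": np.arange(1, 101) * 10,
            "alleles": "A/G",
        })
        geno = GenotypeData(
            rng.integers(0, 3, (100, 100)).astype(float),
            [f"i{k}" for k in range(100)], mm,
        )
        out = inject_missingness(geno, 0.1, seed=17)
        n_missing = int(np.isnan(out.values).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_calls, 0.1)
        assert lo <= n_missing <= hi

    def test_same_seed_same_mask(self, small_population):
        _, geno, _, _ = small_population
        a = inject_missingness(geno, 0.1, seed=3)
        b = inject_missingness(geno, 0.1, seed=3)
        assert np.array_equal(np.isnan(a.values), np.isnan(b.values))
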