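"""Synthetic cohort generator: determinism, pool granularity, count model,
compositional phenotypes and round-trip persistence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from linumpool import datasets, io
from linumpool.calling import vaf_matrix
from linumpool.simulate import (
    CohortConfig,
    CohortTruth,
    ConfigError,
    expected_lin,
    simulate_phenotypes,
    simulate_pool_counts,
    simulate_truth,
    write_cohort,
)

ACIDS = list(io.FATTY_ACIDS)


def small_config(**overrides):
    defaults = dict(
        n_cultivars=12,
        sites_per_gene={"SAD1": 1, "SAD2": 1, "FAD2A": 1, "FAD2B": 1,
                        "FAD3A": 4, "FAD3B": 2},
        n_monomorphic=2,
        n_both=2, n_fad3a_only=1, n_fad3b_only=1, n_alt_nonsense=1,
        n_alt_nonsense_trace=1,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def test_truth_is_deterministic_under_seed(models, references):
    config = small_config()
    a = simulate_truth(config, seed=5, models=models, references=references)
    b = simulate_truth(config, seed=5, models=models, references=references)
    assert [s.key for s in a.sites] == [s.key for s in b.sites]
    assert np.array_equal(a.true_freq, b.true_freq)
    assert list(a.strata) == list(b.strata)
    c = simulate_truth(config, seed=6, models=models, references=references)
    assert not np.array_equal(a.true_freq, c.true_freq)


def test_zero_heterogeneity_gives_fixed_background_frequencies(models, references):
    config = small_config(het_fraction=0.0)
    truth = simulate_truth(config, seed=3, models=models, references=references)
    key_rows = {truth.key_fad3a_index, truth.key_fad3b_index, truth.alt_nonsense_index}
    background = np.array(
        [truth.true_freq[i] for i in range(truth.n_sites) if i not in key_rows]
    )
    assert set(np.unique(background)) <= {0.0, 1.0}


def test_frequencies_snap_to_pool_granularity(models, references):
    config = small_config(pool_size=50)
    truth = simulate_truth(config, seed=3, models=models, references=references)
    copies = 2 * config.pool_size
    assert np.allclose(truth.true_freq * copies, np.round(truth.true_freq * copies))


def test_default_site_counts_skew_towards_fad3(default_cohort):
    truth, _counts, _phenotypes = default_cohort
    per_gene = pd.Series(truth.gene_ids).value_counts()
    assert per_gene["FAD3A"] > per_gene["FAD3B"]
    assert all(
        per_gene["FAD3B"] > per_gene[g] for g in ("SAD1", "SAD2", "FAD2A", "FAD2B")
    )


def test_strata_sizes_match_config(default_cohort):
    truth, _counts, _phenotypes = default_cohort
    strata = pd.Series(truth.strata).value_counts()
    assert strata["both"] == 9
    assert strata["fad3a_only"] == 2
    assert strata["fad3b_only"] == 2
    assert strata["alt_nonsense"] == 1


def _truth_with_freq(freq_row: np.ndarray, config: CohortConfig) -> CohortTruth:
    """Minimal single-site truth with an arbitrary frequency vector."""
    n = freq_row.size
    site = datasets.KEY_FAD3A_NONSENSE
    return CohortTruth(
        config=config, seed=0,
        cultivars=[f"P{i}" for i in range(n)],
        sites=[site, datasets.KEY_FAD3B_MISSENSE, datasets.ALT_FAD3A_NONSENSE],
        gene_ids=["FAD3A", "FAD3B", "FAD3A"],
        true_freq=np.vstack([freq_row, np.zeros(n), np.zeros(n)]),
        strata=np.array(["neither"] * n, dtype=object),
        key_fad3a_index=0, key_fad3b_index=1, alt_nonsense_index=2,
    )


def test_zero_frequency_zero_error_yields_no_alt_reads():
    truth = _truth_with_freq(np.zeros(50), CohortConfig())
    counts = simulate_pool_counts(truth, mean_coverage=400, error_rate=0.0, seed=1)
    assert counts.alt_count[0].sum() == 0


def test_intermediate_frequency_vaf_concentrates_within_3_binomial_sd():
    # f = 0.5 at depth ~400: |VAF - 0.5| <= 3*sqrt(0.25/400) = 0.075 for >=99%
    truth = _truth_with_freq(np.full(2000, 0.5), CohortConfig())
    counts = simulate_pool_counts(truth, mean_coverage=400, error_rate=0.0, seed=2)
    vaf = counts.alt_count[0] / counts.depth[0]
    assert (np.abs(vaf - 0.5) <= 0.075).mean() >= 0.99


def test_fixed_alt_with_error_gives_expected_alt_fraction():
    truth = _truth_with_freq(np.ones(4000), CohortConfig())
    counts = simulate_pool_counts(truth, mean_coverage=400, error_rate=0.005, seed=3)
    observed = counts.alt_count[0].sum() / counts.depth[0].sum()
    assert observed == pytest.approx(0.995, abs=0.001)


def test_vaf_recovery_mean_absolute_error(default_cohort):
    truth, _counts, _phenotypes = default_cohort
    counts = simulate_pool_counts(truth, error_rate=0.0, seed=21)
    vaf = vaf_matrix(counts, min_depth=8)
    assert truth.true_freq.size >= 1000
    mae = np.nanmean(np.abs(vaf - truth.true_freq))
    assert mae <= 0.02


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def test_noise_free_lin_follows_the_key_variant_map(models, references):
    config = small_config(noise_sd=0.0)
    truth = simulate_truth(config, seed=9, models=models, references=references)
    phenotypes = simulate_phenotypes(truth, noise_sd=0.0, seed=9)
    fa = truth.true_freq[truth.key_fad3a_index]
    fb = truth.true_freq[truth.key_fad3b_index]
    falt = truth.true_freq[truth.alt_nonsense_index]
    for j, cultivar in enumerate(truth.cultivars):
        assert phenotypes.loc[cultivar, "LIN"] == pytest.approx(
            expected_lin(config, fa[j], fb[j], falt[j])
        )


def test_lin_lio_subtotal_is_conserved_across_genotypes(models, references):
    # two truths differing only at the key sites share PAL/STE/OLE draws,
    # so LIN + LIO is identical: LIO absorbs the genotype-driven LIN change
    config = small_config(noise_sd=0.0, sad_ole_effect=0.0)
    truth = simulate_truth(config, seed=4, models=models, references=references)
    flipped = CohortTruth(
        **{**truth.__dict__, "true_freq": truth.true_freq.copy()}
    )
    flipped.true_freq[truth.key_fad3a_index] = 1.0
    flipped.true_freq[truth.key_fad3b_index] = 1.0
    a = simulate_phenotypes(truth, noise_sd=0.0, seed=4)
    b = simulate_phenotypes(flipped, noise_sd=0.0, seed=4)
    assert np.allclose(a[["PAL", "STE", "OLE"]], b[["PAL", "STE", "OLE"]])
    assert np.allclose(a["LIN"] + a["LIO"], b["LIN"] + b["LIO"])
    assert (b["LIN"] <= a["LIN"] + 1e-12).all()


def test_composition_closes_to_configured_total(default_cohort):
    _truth, _counts, phenotypes = default_cohort
    assert np.allclose(phenotypes.sum(axis=1), 97.0, atol=1e-9)


def test_phenotypes_fall_inside_observed_ranges(default_cohort):
    _truth, _counts, phenotypes = default_cohort
    ranges = datasets.load_background_ranges()
    for acid in ACIDS:
        assert (phenotypes[acid] > 0).all()
        assert (phenotypes[acid] >= ranges.loc[acid, "min_pct"]).all()
        assert (phenotypes[acid] <= ranges.loc[acid, "max_pct"]).all()


def test_lin_class_means_are_separated(default_cohort):
    truth, _counts, phenotypes = default_cohort
    config = truth.config
    fa = truth.true_freq[truth.key_fad3a_index]
    fb = truth.true_freq[truth.key_fad3b_index]
    falt = truth.true_freq[truth.alt_nonsense_index]
    classes = pd.Series(
        [
            "low" if ((fa[j] >= 0.4 and fb[j] >= 0.4) or falt[j] >= 0.4)
            else "mid" if (fa[j] >= 0.4 or fb[j] >= 0.4)
            else "high"
            for j in range(len(truth.cultivars))
        ],
        index=phenotypes.index,
    )
    stats = phenotypes.groupby(classes)["LIN"].agg(["mean", "std"])
    assert stats.loc["low", "mean"] < stats.loc["mid", "mean"] < stats.loc["high", "mean"]
    for lower, upper in [("low", "mid"), ("mid", "high")]:
        assert (
            stats.loc[lower, "mean"] + 2 * stats.loc[lower, "std"]
            < stats.loc[upper, "mean"] - 2 * stats.loc[upper, "std"]
        )


def test_out_of_range_settings_raise_config_error(models, references):
    config = small_config(pal_range=(0.1, 0.2))
    truth = simulate_truth(config, seed=1, models=models, references=references)
    with pytest.raises(ConfigError, match="PAL"):
        simulate_phenotypes(truth, seed=1)
    with pytest.raises(ConfigError):
        CohortConfig(het_fraction=1.5)
    with pytest.raises(ConfigError):
        CohortConfig(n_monomorphic=-1)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_written_cohort_round_trips_exactly(tmp_path, models, references):
    config = small_config()
    truth = simulate_truth(config, seed=8, models=models, references=references)
    counts = simulate_pool_counts(truth, seed=8)
    phenotypes = simulate_phenotypes(truth, seed=8)
    paths = write_cohort(truth, counts, phenotypes, tmp_path)

    from_tsv = io.read_counts_tsv(paths["counts_tsv"])
    assert [s.key for s in from_tsv.sites] == [s.key for s in counts.sites]
    assert np.array_equal(from_tsv.ref_count, counts.ref_count)
    assert np.array_equal(from_tsv.alt_count, counts.alt_count)

    from_vcf = io.read_counts_vcf(paths["counts_vcf"])
    key_order = {s.key: i for i, s in enumerate(counts.sites)}
    for i, site in enumerate(from_vcf.sites):
        j = key_order[site.key]
        assert np.array_equal(from_vcf.ref_count[i], counts.ref_count[j])
        assert np.array_equal(from_vcf.alt_count[i], counts.alt_count[j])

    pheno_back = io.read_phenotypes(paths["phenotypes"])
    pd.testing.assert_frame_equal(pheno_back, phenotypes, check_exact=False, rtol=0, atol=1e-12)

    truth_back = io.read_table(paths["truth"])
    freq_back = truth_back[truth.cultivars].to_numpy()
    assert np.array_equal(freq_back, truth.true_freq)
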