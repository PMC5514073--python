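import numpy as np
import pytest

from mutdna import (
    CloneSpec,
    CnaEvent,
    SamplingModel,
    default_scenario,
    expected_bin_factor,
    expected_counts,
    simulate_cohort,
    simulate_counts,
    simulate_variant_reads,
)
from mutdna.simulate import build_clone

from conftest import uniform_genome


@pytest.mark.parametrize(
    "cn,tf,expected",
    [(2, 0.8, 1.0), (4, 1.0, 2.0), (3, 0.05, 1.025), (0, 1.0, 0.0), (1, 0.5, 0.75)],
)
def test_expected_bin_factor(cn, tf, expected):
    assert expected_bin_factor(cn, tf) == pytest.approx(expected)


@pytest.mark.parametrize("cn,tf", [(-1, 0.5), (2, -0.1), (2, 1.5)])
def test_expected_bin_factor_rejects_invalid(cn, tf):
    with pytest.raises(ValueError):
        expected_bin_factor(cn, tf)


def test_zero_tumour_fraction_matches_germline_expectation():
    g = uniform_genome(40)
    model = SamplingModel()
    clone = build_clone(g, CloneSpec("c", events=(CnaEvent("chr1", 5, 10, 4),)))
    mu_tumour_free = expected_counts(g, [(clone, 0.0)], model)
    mu_germline = expected_counts(g, [], model)
    np.testing.assert_allclose(mu_tumour_free, mu_germline)
    # an everywhere-neutral clone is indistinguishable from germline
    neutral = build_clone(g, CloneSpec("n"))
    np.testing.assert_allclose(
        expected_counts(g, [(neutral, 0.7)], model), mu_germline
    )


def test_copy_number_gain_shifts_counts_by_expected_ratio():
    """Monte-Carlo: cn=4 region at tf=0.5 raises counts 1.5x (within 1%)."""
    g = uniform_genome(40)
    clone = build_clone(g, CloneSpec("c", events=(CnaEvent("chr1", 10, 10, 4),)))
    model = SamplingModel(total_reads=4e7, overdispersion=0.0)
    rng = np.random.default_rng(123)
    in_region = np.zeros(40, bool)
    in_region[10:20] = True
    ratios = []
    for _ in range(50):
        counts = simulate_counts(g, [(clone, 0.5)], model, rng)
        ratios.append(counts[in_region].mean() / counts[~in_region].mean())
    assert np.mean(ratios) == pytest.approx(1.5, rel=0.01)


def test_count_means_match_analytic_expectation_within_3se():
    g = uniform_genome(30)
    clone = build_clone(g, CloneSpec("c", events=(CnaEvent("chr1", 0, 10, 3),)))
    model = SamplingModel(total_reads=3e6, overdispersion=5e-4)
    mu = expected_counts(g, [(clone, 0.3)], model)
    rng = np.random.default_rng(5)
    reps = 200
    draws = np.vstack([simulate_counts(g, [(clone, 0.3)], model, rng)
                       for _ in range(reps)])
    var = mu + model.overdispersion * mu**2
    se = np.sqrt(var / reps)
    assert (np.abs(draws.mean(axis=0) - mu) < 3.5 * se).all()


def test_simulate_counts_rejects_bad_weights():
    g = uniform_genome(10)
    clone = build_clone(g, CloneSpec("c"))
    model = SamplingModel()
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        simulate_counts(g, [(clone, -0.1)], model, rng)
    with pytest.raises(ValueError):
        simulate_counts(g, [(clone, 0.7), (clone, 0.6)], model, rng)


def test_variant_reads_no_signal_no_error_is_clean():
    model = SamplingModel(error_rate=0.0)
    obs = simulate_variant_reads(0.0, model, np.random.default_rng(0))
    assert obs.alt_reads == 0


def test_molecular_bottleneck_dropout_rate():
    """P(no mutant molecule) at GE=10, AF=1% is 0.99^10 ~ 0.904."""
    model = SamplingModel(genomic_equivalents=10, error_rate=0.0)
    rng = np.random.default_rng(77)
    zeros = sum(
        simulate_variant_reads(0.01, model, rng).alt_reads == 0 for _ in range(1000)
    )
    assert zeros / 1000 == pytest.approx(0.99**10, abs=0.03)


def test_observed_af_is_unbiased_at_high_input():
    model = SamplingModel(
        genomic_equivalents=10_000, variant_depth=10_000, error_rate=1e-4
    )
    rng = np.random.default_rng(42)
    afs = [simulate_variant_reads(0.10, model, rng).af for _ in range(1000)]
    assert np.mean(afs) == pytest.approx(0.100, abs=0.003)


def test_variant_reads_input_validation():
    with pytest.raises(ValueError):
        simulate_variant_reads(1.5, SamplingModel(), np.random.default_rng(0))
    with pytest.raises(ValueError):
        SamplingModel(genomic_equivalents=0)
    with pytest.raises(ValueError):
        SamplingModel(variant_depth=0)


# -- cohort-level behaviour ----------------------------------------------


def test_cohort_is_hash_stable():
    a = simulate_cohort(default_scenario(3))
    b = simulate_cohort(default_scenario(3))
    assert a.content_hash() == b.content_hash()
    c = simulate_cohort(default_scenario(4))
    assert a.content_hash() != c.content_hash()


def test_default_cohort_design(cohort):
    sheet = cohort.sample_sheet
    assert sheet["patient"].nunique() == 17
    fluids = sheet[sheet["sample_type"].isin(["PLS", "UCP", "USN"])]
    # 17 patients x 6 timepoints x 3 fluid types
    assert len(fluids) == 17 * 6 * 3
    assert fluids.groupby(["patient", "timepoint"])["sample_type"].count().eq(3).all()
    per_patient = sheet.drop_duplicates("patient")
    assert per_patient["recurred"].sum() == 8
    times = per_patient.loc[per_patient["recurred"], "recurrence_days"]
    assert times.min() > 0


def test_responder_tumour_fraction_strictly_decays(cohort):
    truth = cohort.truth
    responders = [
        p for p, d in truth["patients"].items()
        if d["trajectory"] == "responder-decay"
    ]
    assert responders
    for pid in responders:
        tfs = [
            truth["samples"][f"{pid}_T{tp}_USN"]["tumour_fraction"]
            for tp in range(1, 7)
        ]
        assert all(a > b for a, b in zip(tfs, tfs[1:]))


def test_clonal_switch_crosses_once(cohort):
    switches = [
        (p, d) for p, d in cohort.truth["patients"].items()
        if d["trajectory"] == "clonal-switch"
    ]
    assert len(switches) == 1
    _, d = switches[0]
    (fa, fb) = [np.array(c["fractions"]) for c in d["clones"].values()]
    assert (np.diff(fa) < 0).all() and (np.diff(fb) > 0).all()
    crossings = np.sum(np.diff(np.sign(fa - fb)) != 0)
    assert crossings == 1


def test_urine_carries_more_tumour_dna_than_plasma(cohort):
    samples = cohort.truth["samples"]
    by_type = {"PLS": [], "UCP": [], "USN": []}
    for sid, d in samples.items():
        if d["sample_type"] in by_type:
            by_type[d["sample_type"]].append(d["tumour_fraction"])
    assert np.mean(by_type["USN"]) > np.mean(by_type["PLS"])
    assert np.mean(by_type["UCP"]) > np.mean(by_type["PLS"])


def test_cohort_files_round_trip(tmp_path, cohort):
    cohort.write(tmp_path)
    from mutdna import GenomeBins
    from mutdna.io import read_counts_dir, read_sample_sheet, read_variants_tsv

    genome = GenomeBins.from_tsv(tmp_path / "genome_bins.tsv")
    assert genome.n_bins == cohort.genome.n_bins
    sheet = read_sample_sheet(tmp_path / "sample_sheet.tsv")
    assert len(sheet) == len(cohort.sample_sheet)
    variants = read_variants_tsv(tmp_path / "variants.tsv")
    assert len(variants) == len(cohort.variants)
    counts = read_counts_dir(tmp_path / "counts", genome)
    assert set(counts) == set(cohort.bin_counts)
    sid = sorted(counts)[0]
    np.testing.assert_array_equal(counts[sid], cohort.bin_counts[sid])
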