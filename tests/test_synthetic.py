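"""Cohort generator and multinomial sequencing sampler: determinism,
distributional sanity, mass conservation, and convergence with depth."""

import math

import numpy as np
import pytest

from ilama.mass_action import InvalidParameterError
from ilama.simulate import PPM, WITH_COMPETITION, WITHOUT_COMPETITION
from ilama.synthetic import (
    CAT_NONSPECIFIC,
    CAT_RESTRICTED_LOW,
    CAT_UPREGULATED,
    SyntheticCohortSpec,
    expected_frequencies,
    generate_cohort,
    sample_counts,
)


@pytest.fixture(scope="module")
def small_spec():
    return SyntheticCohortSpec(
        clones_per_category={
            "gt_1M": 5, "100k_to_1M": 5, CAT_RESTRICTED_LOW: 5,
            CAT_UPREGULATED: 5, "similar": 5, CAT_NONSPECIFIC: 20,
        },
        seed=11,
    )


@pytest.fixture(scope="module")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="module")
def protocols(protocol_with, protocol_without):
    return {WITH_COMPETITION: protocol_with, WITHOUT_COMPETITION: protocol_without}


@pytest.fixture(scope="module")
def small_freqs(small_cohort, protocols):
    clones, _ = small_cohort
    return expected_frequencies(clones, protocols)


class TestGenerateCohort:
    def test_deterministic_given_seed(self, small_spec, small_cohort):
        again = generate_cohort(small_spec)
        assert again == small_cohort

    def test_category_sizes_and_truth_agree(self, small_spec, small_cohort):
        clones, truth = small_cohort
        assert len(clones) == sum(small_spec.clones_per_category.values())
        for cat, n in small_spec.clones_per_category.items():
            assert sum(1 for c in clones if c.category == cat) == n
        assert truth == {c.clone_id: c.category for c in clones}

    def test_clone_ids_are_unique_peptides(self, small_cohort):
        clones, _ = small_cohort
        ids = [c.clone_id for c in clones]
        assert len(set(ids)) == len(ids)
        assert all(8 <= len(i) <= 18 and i.isalpha() and i.isupper() for i in ids)

    def test_nonspecific_clones_lack_receptor(self, small_cohort):
        clones, _ = small_cohort
        for c in clones:
            assert (c.receptor is None) == (c.category == CAT_NONSPECIFIC)

    def test_kd_median_matches_spec_in_large_draw(self):
        spec = SyntheticCohortSpec(clones_per_category={"gt_1M": 10_000}, seed=3)
        clones, _ = generate_cohort(spec)
        kds = np.array([c.kd for c in clones])
        med = np.median(kds)
        assert spec.kd_median / 1.05 < med < spec.kd_median * 1.05
        # log-normal spread: sd of ln(kd) near the configured sigma
        assert np.std(np.log(kds)) == pytest.approx(spec.kd_sigma_ln, rel=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidParameterError):
            SyntheticCohortSpec(clones_per_category={})
        with pytest.raises(InvalidParameterError):
            SyntheticCohortSpec(clones_per_category={"gt_1M": -1})
        with pytest.raises(InvalidParameterError):
            SyntheticCohortSpec(clones_per_category={"made_up_category": 3})


class TestExpectedFrequencies:
    def test_each_round_sums_to_one_million_ppm(self, small_freqs, protocols):
        for arm in protocols:
            freq = np.array([s.frequencies_ppm for s in small_freqs if s.arm == arm])
            assert np.allclose(freq.sum(axis=0), PPM, rtol=1e-9)

    def test_specific_mass_equals_hit_rate(self, small_cohort, protocols, small_freqs):
        clones, truth = small_cohort
        specific_ids = {c.clone_id for c in clones if c.receptor is not None}
        proto = protocols[WITH_COMPETITION]
        freq = np.array([
            s.frequencies_ppm for s in small_freqs
            if s.arm == WITH_COMPETITION and s.clone_id in specific_ids])
        assert np.allclose(
            freq.sum(axis=0), np.array(proto.hit_rates) * PPM, rtol=1e-9)

    def test_upregulated_clone_suppressed_by_competition(
            self, small_cohort, small_freqs):
        clones, _ = small_cohort
        up_ids = {c.clone_id for c in clones if c.category == CAT_UPREGULATED}
        by_key = {(s.clone_id, s.arm): s.frequencies_ppm for s in small_freqs}
        for cid in up_ids:
            f_with = by_key[(cid, WITH_COMPETITION)][-1]
            f_without = by_key[(cid, WITHOUT_COMPETITION)][-1]
            assert f_without > f_with

    def test_jitter_preserves_nonspecific_mass(self, small_cohort, protocols):
        clones, _ = small_cohort
        rng = np.random.default_rng(7)
        sigs = expected_frequencies(clones, protocols, rng=rng,
                                    nonspecific_jitter_sigma=0.5)
        nonspec_ids = {c.clone_id for c in clones if c.receptor is None}
        proto = protocols[WITH_COMPETITION]
        freq = np.array([s.frequencies_ppm for s in sigs
                         if s.arm == WITH_COMPETITION and s.clone_id in nonspec_ids])
        want = (1.0 - np.array(proto.hit_rates)) * PPM
        assert np.allclose(freq.sum(axis=0), want, rtol=1e-9)
        # jitter actually varies the shares
        assert freq[:, 0].std() > 0

    def test_jitter_without_rng_rejected(self, small_cohort, protocols):
        clones, _ = small_cohort
        with pytest.raises(InvalidParameterError):
            expected_frequencies(clones, protocols, nonspecific_jitter_sigma=0.5)


class TestSampleCounts:
    def test_deterministic_given_seed(self, small_freqs):
        a = sample_counts(small_freqs, 100_000, seed=5)
        b = sample_counts(small_freqs, 100_000, seed=5)
        assert a.counts.equals(b.counts) and a.totals == b.totals

    def test_reads_sum_to_depth_per_round(self, small_freqs):
        depth = 50_000
        table = sample_counts(small_freqs, depth, seed=5)
        sums = table.counts.groupby(["arm", "round"])["reads"].sum()
        assert (sums == depth).all()
        assert all(v == depth for v in table.totals.values())

    def test_zero_frequency_clone_gets_zero_reads(self, small_cohort, small_freqs):
        clones, _ = small_cohort
        low = next(c.clone_id for c in clones if c.category == CAT_RESTRICTED_LOW)
        by_key = {(s.clone_id, s.arm): s.frequencies_ppm for s in small_freqs}
        # with competition, low restricted binders go extinct by round 4
        zero_rounds = [r + 1 for r, f in
                       enumerate(by_key[(low, WITH_COMPETITION)]) if f == 0.0]
        table = sample_counts(small_freqs, 10_000_000, seed=5)
        hits = table.counts[
            (table.counts.clone_id == low)
            & (table.counts.arm == WITH_COMPETITION)
            & (table.counts["round"].isin(zero_rounds))]
        assert hits.empty

    def test_unnormalized_frequencies_rejected(self, small_freqs):
        broken = small_freqs[:5]  # sums nowhere near 1e6 ppm
        with pytest.raises(InvalidParameterError):
            sample_counts(broken, 1000, seed=5)

    def test_sampled_frequency_converges_to_expectation(self, small_freqs):
        """At depth 1e7 the round-1 read share of a clone is within 3 binomial
        standard errors of its expected frequency."""
        depth = 10_000_000
        table = sample_counts(small_freqs, depth, seed=5)
        sig = max((s for s in small_freqs if s.arm == WITH_COMPETITION),
                  key=lambda s: s.frequencies_ppm[0])
        p = sig.frequencies_ppm[0] / PPM
        row = table.counts[
            (table.counts.clone_id == sig.clone_id)
            & (table.counts.arm == WITH_COMPETITION)
            & (table.counts["round"] == 1)]
        got = int(row["reads"].iloc[0])
        se = math.sqrt(depth * p * (1 - p))
        assert abs(got - depth * p) < 3 * se
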