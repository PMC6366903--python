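import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from helpers_oracle import brute_force_calls, random_locus_records
from suppscreen.sitecounts import BaseCountMatrix, GroupDesign
from suppscreen.snvcall import (
    FILTER_IN_CONTROL,
    FILTER_MULTIALLELIC,
    FILTER_PASS,
    ThresholdConfig,
    call_experiment,
    call_site,
    pass_set,
)

PAIRWISE = ThresholdConfig.preset("pairwise")
BATCH95 = ThresholdConfig.preset("batch95")


def record(ref="A", **counts):
    base = {"contig": "chr1", "pos": 100, "ref": ref, "sample": "s1",
            "nA": 0, "nC": 0, "nG": 0, "nT": 0}
    base.update({f"n{k}": v for k, v in counts.items()})
    return base


def matrix(rows):
    return BaseCountMatrix(pd.DataFrame(rows))


class TestThresholdConfig:
    def test_presets_match_published_values(self):
        assert (PAIRWISE.min_alt_count, PAIRWISE.min_af) == (5, 0.25)
        assert (BATCH95.min_alt_count, BATCH95.min_af) == (20, 0.40)
        assert PAIRWISE.control_af_cutoff == 0.1

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(0, 0.5)
        with pytest.raises(ValueError):
            ThresholdConfig(5, 0.0)
        with pytest.raises(ValueError, match="unknown preset"):
            ThresholdConfig.preset("nope")


class TestCallSite:
    def test_pairwise_calls_what_batch_rejects(self):
        rec = record(A=150, T=60)  # AF(T) = 60/210 ≈ 0.2857
        assert call_site(rec, PAIRWISE) == [("T", 60, pytest.approx(60 / 210))]
        assert call_site(rec, BATCH95) == []

    def test_no_alt_evidence(self):
        assert call_site(record(A=200), PAIRWISE) == []

    def test_boundaries_are_inclusive(self):
        # exactly count 5 and AF 0.25
        rec = record(A=15, T=5)
        assert [a for a, *_ in call_site(rec, PAIRWISE)] == ["T"]
        # one read fewer on the alt fails both the count or the AF rule
        assert call_site(record(A=16, T=4), PAIRWISE) == []
        # count above 5 but AF a hair below 0.25 fails
        assert call_site(record(A=16, T=5), PAIRWISE) == []

    def test_zero_depth_never_calls(self):
        assert call_site(record(), PAIRWISE) == []


def two_sample_design():
    return GroupDesign("e1", {"c1": "control", "s1": "suppressor",
                              "s2": "suppressor"}, "pairwise")


class TestMultiallelicDiscard:
    def test_two_passing_alts_in_different_strains_discard_locus(self):
        rows = [
            record(A=100, T=60) | {"sample": "s1"},
            record(A=100, G=60) | {"sample": "s2"},
            record(A=100) | {"sample": "c1"},
        ]
        calls = call_experiment(matrix(rows), two_sample_design(), PAIRWISE)
        assert set(calls["filter"]) == {FILTER_MULTIALLELIC}
        assert len(pass_set(calls)) == 0

    def test_second_alt_below_threshold_keeps_locus(self):
        rows = [
            record(A=100, T=60, G=4) | {"sample": "s1"},  # G below count threshold
            record(A=100) | {"sample": "s2"},
            record(A=100) | {"sample": "c1"},
        ]
        calls = call_experiment(matrix(rows), two_sample_design(), PAIRWISE)
        ps = pass_set(calls)
        assert list(ps["alt"]) == ["T"] and list(ps["sample"]) == ["s1"]

    def test_single_allele_locus_unchanged(self):
        rows = [
            record(A=100, T=60) | {"sample": "s1"},
            record(A=100) | {"sample": "c1"},
        ]
        design = GroupDesign("e1", {"c1": "control", "s1": "suppressor"})
        assert len(pass_set(call_experiment(matrix(rows), design, PAIRWISE))) == 1


class TestControlSubtraction:
    def make(self, ctrl_t_counts):
        rows = [record(A=100, T=60) | {"sample": "s1"}]
        for i, t in enumerate(ctrl_t_counts):
            rows.append(record(A=100 - t, T=t) | {"sample": f"c{i + 1}"})
        roles = {"s1": "suppressor"}
        roles.update({f"c{i + 1}": "control" for i in range(len(ctrl_t_counts))})
        return matrix(rows), GroupDesign("e1", roles)

    def test_af_exactly_point_one_discards(self):
        m, d = self.make([10, 0])  # AF 0.10 in one control: "0.1 or above"
        calls = call_experiment(m, d, PAIRWISE)
        assert list(calls["filter"]) == [FILTER_IN_CONTROL]

    def test_af_below_point_one_retains(self):
        m, d = self.make([9, 9])  # AF 0.09 in both controls
        calls = call_experiment(m, d, PAIRWISE)
        assert list(calls["filter"]) == [FILTER_PASS]

    def test_control_comparison_is_allele_specific(self):
        # control carries a different alt (G) at the same locus, below threshold
        rows = [
            record(A=100, T=60) | {"sample": "s1"},
            record(A=80, G=20) | {"sample": "c1"},
        ]
        design = GroupDesign("e1", {"c1": "control", "s1": "suppressor"})
        calls = call_experiment(matrix(rows), design, PAIRWISE)
        assert list(calls["filter"]) == [FILTER_PASS]

    def test_absent_control_record_is_af_zero(self):
        rows = [record(A=100, T=60) | {"sample": "s1"}]
        design = GroupDesign("e1", {"c1": "control", "s1": "suppressor"})
        calls = call_experiment(matrix(rows), design, PAIRWISE)
        assert list(calls["filter"]) == [FILTER_PASS]


class TestCallExperiment:
    def test_empty_counts_empty_calls(self):
        m = BaseCountMatrix(pd.DataFrame(
            columns=["contig", "pos", "ref", "sample", "nA", "nC", "nG", "nT"]))
        calls = call_experiment(m, two_sample_design(), PAIRWISE)
        assert calls.empty

    def test_noise_free_screen_recovers_truth_minus_ancestral(self):
        from suppscreen.simscreen import SimConfig, simulate_screen
        cfg = SimConfig(seed=3, n_suppressor_strains=4, n_other_genes=40,
                        genome_length=20_000, ancestral_variant_count=6,
                        error_rate=0.0, background_nonsilent_mean=0.0,
                        background_silent_mean=0.0, multiallelic_noise_rate=0.0,
                        af_beta_a=1e9)  # AF exactly 1
        fx = simulate_screen(cfg)
        calls = call_experiment(fx.counts, fx.design, BATCH95)
        ps = pass_set(calls)
        truth = fx.truth.variants
        private = truth[truth["role"] != "ancestral"]
        expected = set(zip(private["pos"], private["alt"], private["sample"]))
        assert set(zip(ps["pos"], ps["alt"], ps["sample"])) == expected
        anc = calls[calls["filter"] == FILTER_IN_CONTROL]
        assert len(anc) == len(fx.truth.ancestral) * len(fx.design.suppressors)

    def test_stricter_preset_calls_are_a_subset(self, small_screen):
        loose = pass_set(call_experiment(small_screen.counts, small_screen.design, PAIRWISE))
        strict = pass_set(call_experiment(small_screen.counts, small_screen.design, BATCH95))
        loose_keys = set(zip(loose["pos"], loose["alt"], loose["sample"]))
        strict_keys = set(zip(strict["pos"], strict["alt"], strict["sample"]))
        assert strict_keys <= loose_keys

    def test_idempotent_on_its_own_pass_loci(self, small_screen):
        calls = call_experiment(small_screen.counts, small_screen.design, BATCH95)
        ps = pass_set(calls)
        sub = small_screen.counts.subset_positions(ps)
        again = pass_set(call_experiment(sub, small_screen.design, BATCH95))
        key = lambda df: set(zip(df["pos"], df["alt"], df["sample"]))
        assert key(again) == key(ps)

    def test_per_sample_multiallelic_scope_escape_hatch(self):
        rows = [
            record(A=100, T=60) | {"sample": "s1"},
            record(A=100, G=60) | {"sample": "s2"},
            record(A=100) | {"sample": "c1"},
        ]
        calls = call_experiment(matrix(rows), two_sample_design(), PAIRWISE,
                                multiallelic_scope="sample")
        assert set(calls["filter"]) == {FILTER_PASS}


class TestAgainstBruteForceOracle:
    def test_random_loci_match_oracle(self):
        rng = np.random.default_rng(42)
        samples = ["c1", "c2", "s1", "s2", "s3"]
        roles = {"c1": "control", "c2": "control",
                 "s1": "suppressor", "s2": "suppressor", "s3": "suppressor"}
        design = GroupDesign("e1", roles)
        rows = []
        for i in range(300):
            rows.extend(random_locus_records(rng, "chr1", 10 + i, samples))
        m = matrix(rows)
        for th in (PAIRWISE, BATCH95):
            got = pass_set(call_experiment(m, design, th))
            got_keys = set(zip(got["contig"], got["pos"], got["alt"], got["sample"]))
            want = brute_force_calls(rows, {"s1", "s2", "s3"}, {"c1", "c2"},
                                     th.min_alt_count, th.min_af, th.control_af_cutoff)
            assert got_keys == want


count_strategy = st.integers(0, 80)


@given(st.lists(st.tuples(count_strategy, count_strategy, count_strategy,
                          count_strategy), min_size=1, max_size=12),
       st.integers(1, 30), st.floats(0.05, 0.9),
       st.integers(0, 10), st.floats(0.0, 0.5))
def test_threshold_monotonicity_property(rows, mac, maf, d_mac, d_maf):
    """Raising either threshold component never adds a threshold candidate,
    and never adds a pass call at a locus free of multiallelic conflict."""
    from suppscreen.snvcall import threshold_candidates

    samples = ["c1", "s1", "s2"]
    recs = []
    for i, counts in enumerate(rows):
        s = samples[i % 3]
        recs.append({"contig": "chr1", "pos": 10 + i // 3, "ref": "A", "sample": s,
                     "nA": counts[0], "nC": counts[1], "nG": counts[2], "nT": counts[3]})
    design = GroupDesign("e1", {"c1": "control", "s1": "suppressor", "s2": "suppressor"})
    m = BaseCountMatrix(pd.DataFrame(recs))
    t1 = ThresholdConfig(mac, maf)
    t2 = ThresholdConfig(mac + d_mac, min(maf + d_maf, 1.0))
    k = lambda df: set(zip(df["pos"], df["alt"], df["sample"]))
    assert k(threshold_candidates(m, t2)) <= k(threshold_candidates(m, t1))

    loose_calls = call_experiment(m, design, t1)
    strict_calls = call_experiment(m, design, t2)
    multi_loose = set(loose_calls.loc[loose_calls["filter"] == FILTER_MULTIALLELIC, "pos"])
    strict_ok = {key for key in k(pass_set(strict_calls)) if key[0] not in multi_loose}
    assert strict_ok <= k(pass_set(loose_calls))
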