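"""Allele presence rule, allelism classes, fraction and sharing spectra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strainsieve import (PrimitiveVariant, Thresholds, allele_accounting,
                         build_sample_table, call_alleles, classify_allelism,
                         fraction_spectrum, is_present, sharing_accounting,
                         sharing_spectrum, simulate_read_counts)
from strainsieve.alleles import SampleAlleleTable


def _prims(pos, ref_obs, alt_obs, depth, alt="T", ref="A"):
    return [PrimitiveVariant("ref", pos, ref, alt, "snp", ref_obs, alt_obs, depth)]


class TestPresenceRule:
    @pytest.mark.parametrize(
        "obs,depth,expected",
        [
            (3, 30, True),   # both thresholds exactly at boundary
            (2, 10, False),  # 20% but below 3 reads
            (3, 100, False),  # 3 reads but 3% of depth
            (3, 10, True),
            (10, 100, True),  # exactly 10%
            (9, 100, False),
        ],
    )
    def test_boundaries(self, obs, depth, expected, thresholds):
        assert is_present(obs, depth, thresholds) is expected

    def test_call_evaluates_ref_and_alt_independently(self, thresholds):
        calls = call_alleles(_prims(5, ref_obs=20, alt_obs=10, depth=30), thresholds)
        by = {c.allele: c for c in calls}
        assert by["A"].present and by["A"].is_reference
        assert by["T"].present and not by["T"].is_reference
        assert by["T"].fraction == pytest.approx(1 / 3)

    @given(st.integers(0, 60), st.integers(0, 60))
    @settings(max_examples=200)
    def test_presence_matches_brute_force_rules(self, ref_obs, alt_obs):
        depth = ref_obs + alt_obs + 5
        thr = Thresholds()
        calls = call_alleles(_prims(1, ref_obs, alt_obs, depth), thr)
        for c in calls:
            expected = c.obs >= 3 and round(c.obs / c.depth, 12) >= 0.10
            assert c.present == expected

    def test_presence_monotone_in_depth(self, thresholds):
        # raising depth at fixed fraction never flips present -> absent once obs >= 3
        for depth in (30, 300, 3000):
            obs = depth // 5  # fixed 20% fraction
            assert is_present(obs, depth, thresholds)


class TestAllelism:
    def _table(self, calls_by_pos, mapped=None):
        t = SampleAlleleTable("S", frozenset(mapped or calls_by_pos))
        t.calls = calls_by_pos
        return t

    def test_fixed_alt_is_monoallelic(self, thresholds):
        t = self._table({5: call_alleles(_prims(5, 0, 100, 100), thresholds)})
        s = classify_allelism(t)
        assert (s.n_variant_positions, s.n_mono, s.n_bi) == (1, 1, 0)

    def test_ref_alt_split_is_biallelic(self, thresholds):
        t = self._table({5: call_alleles(_prims(5, 60, 40, 100), thresholds)})
        s = classify_allelism(t)
        assert (s.n_mono, s.n_bi) == (0, 1)

    def test_monoallelic_proportion_recovered_on_planted_mix(self, thresholds):
        # 75% of planted sites fixed (fraction 1.0), 25% polymorphic at 0.5
        calls = {}
        for i in range(200):
            frac_fixed = i % 4 != 3
            alt = 1000 if frac_fixed else 500
            calls[i + 1] = call_alleles(_prims(i + 1, 1000 - alt, alt, 1000),
                                        thresholds)
        s = classify_allelism(self._table(calls))
        assert s.prop_mono == pytest.approx(0.75)

    def test_multiallelic_presence_is_representable(self, thresholds):
        prims = (_prims(9, 30, 40, 100, alt="T") +
                 _prims(9, 30, 30, 100, alt="G"))
        calls = {9: call_alleles(prims, thresholds)}
        s = classify_allelism(self._table(calls))
        assert s.n_multi == 1  # ref + two alts all present


class TestFractionSpectrum:
    def _table_with_fracs(self, fracs, thresholds, depth=1000):
        calls = {}
        for i, f in enumerate(fracs):
            alt = int(round(f * depth))
            calls[i + 1] = call_alleles(_prims(i + 1, depth - alt, alt, depth),
                                        thresholds)
        t = SampleAlleleTable("S", frozenset(calls))
        t.calls = calls
        return t

    def test_bin_conventions(self, thresholds):
        t = self._table_with_fracs([1.0, 0.9, 0.15], thresholds)
        spec = fraction_spectrum(t)
        total_per_bin = spec.sum(axis=1)
        assert total_per_bin.loc[1.0] == 1  # fraction 1.0 -> (0.9, 1.0]
        assert total_per_bin.loc[0.9] == 1  # fraction 0.9 -> (0.8, 0.9]
        assert total_per_bin.loc[0.2] == 1

    def test_exact_threshold_fraction_in_first_bin(self, thresholds):
        # exactly 10% is present (rule is >=) and is the only occupant of (0, 0.1]
        t = self._table_with_fracs([0.10], thresholds)
        spec = fraction_spectrum(t)
        assert spec.sum(axis=1).loc[0.1] == 1

    def test_total_conserved_and_stratified(self, thresholds):
        t = self._table_with_fracs([1.0, 0.5, 0.4, 0.3], thresholds)
        spec = fraction_spectrum(t)
        # one mono-allelic (fraction 1.0) and three bi-allelic alleles
        assert int(spec.to_numpy().sum()) == 4
        assert int(spec[1].sum()) == 1 and int(spec[2].sum()) == 3

    def test_bad_bin_width_rejected(self, thresholds):
        t = self._table_with_fracs([0.5], thresholds)
        with pytest.raises(Exception):
            fraction_spectrum(t, bin_width=0.3)


class TestSharingSpectrum:
    def test_planted_design_recovered(self, small_sim, thresholds):
        cfg, _ref, truth, records = small_sim
        tables = []
        for s in truth.sample_ids:
            prims = [
                PrimitiveVariant("ref", r.pos, r.ref_allele, r.alt_alleles[0],
                                 "snp", r.ref_obs, r.alt_obs[0], r.depth)
                for r in records[s]
            ]
            tables.append(build_sample_table(s, prims, truth.mapped[s], thresholds))
        spec = sharing_spectrum(tables)
        assert spec.histogram == dict(cfg.sharing_spec)
        assert spec.n_alleles == sum(cfg.sharing_spec.values())
        # conservation: histogram totals match the distinct entries
        assert sum(spec.histogram.values()) == len(spec.entries)
        # matrix sorted by samples-present descending
        order = [spec.entries[k] for k in spec.fraction_matrix.index]
        assert order == sorted(order, reverse=True)

    def test_allele_on_position_unmapped_in_one_sample_excluded(self, thresholds):
        t1 = SampleAlleleTable("S1", frozenset({1, 2}))
        t1.calls = {1: call_alleles(_prims(1, 0, 50, 50), thresholds)}
        t2 = SampleAlleleTable("S2", frozenset({2}))  # position 1 unmapped here
        spec = sharing_spectrum([t1, t2])
        assert spec.n_alleles == 0 and spec.histogram == {}

    def test_allele_present_everywhere(self, thresholds):
        tables = []
        for s in ("S1", "S2", "S3"):
            t = SampleAlleleTable(s, frozenset({4}))
            t.calls = {4: call_alleles(_prims(4, 10, 40, 50), thresholds)}
            tables.append(t)
        spec = sharing_spectrum(tables)
        assert spec.histogram == {3: 1}


class TestAccounting:
    def test_allele_accounting_printed_example(self):
        # 207 positions with one non-reference allele + 3 with two -> 210 / 213
        assert allele_accounting({1: 207, 2: 3}) == (210, 213)

    def test_sharing_accounting_printed_example(self):
        assert sharing_accounting(213, {4: 6, 3: 7, 2: 24}) == 176

    def test_invalid_inputs(self):
        with pytest.raises(Exception):
            sharing_accounting(5, {2: 10})
        with pytest.raises(Exception):
            allele_accounting({0: 3})


def test_fraction_recovery_at_high_depth(small_sim, thresholds):
    """Estimated fractions track planted truth within +-0.05 at depth 500."""
    cfg, _ref, truth, records = small_sim
    ok = n = 0
    for s in truth.sample_ids:
        for r in records[s]:
            true_frac = truth.planted[s][r.pos][1]
            n += 1
            ok += abs(r.alt_obs[0] / r.depth - true_frac) <= 0.05
    assert ok / n >= 0.95
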