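"""Filtering criteria, median roll-up and the occupancy arithmetic."""

import math
import statistics
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parstoich import quantify
from parstoich.io_model import GT_ONE, SINGLE_MIX, MixPoint, ProteinRecord, SiteAnnotation
from parstoich.quantify import (
    combine_across_mixes,
    compute_mix_ratio,
    estimate_stoichiometries,
    filter_peptides,
    merge_replicates,
    passes_sn,
    protein_median_ratio,
    stoich_at_mix,
    summarize,
)

from conftest import make_pair

positive = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestPassesSN:
    @pytest.mark.parametrize(
        "light_sn,heavy_sn,expected",
        [(6, 6, True), (5, 10, False), (100, 4.9, False), (5.0001, 5.0001, True)],
    )
    def test_both_channels_strictly_above_threshold(self, light_sn, heavy_sn, expected):
        pair = make_pair(light_sn=light_sn, heavy_sn=heavy_sn)
        assert passes_sn(pair, 5.0) is expected

    def test_either_mode(self):
        pair = make_pair(light_sn=100, heavy_sn=1)
        assert passes_sn(pair, 5.0, mode="either")

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            passes_sn(make_pair(), 0.0)


class TestMixRatio:
    @pytest.mark.parametrize(
        "heavy,light,expected",
        [
            (5, 10_000, 1 / 2000),
            (200, 10_000, 1 / 50),
            (12.5, 10_000, 1 / 800),
            (100, 20_000, 1 / 200),
            (7.0, 7.0, 1.0),
        ],
    )
    def test_titration_table_arithmetic(self, heavy, light, expected):
        assert compute_mix_ratio(heavy, light) == pytest.approx(expected)

    def test_nonpositive_mass_is_error(self):
        with pytest.raises(ValueError):
            compute_mix_ratio(-1, 10)


class TestMedianRollup:
    def test_odd_even_and_single_counts(self):
        def pairs_with(ratios):
            return [
                make_pair(light_area=100.0, heavy_area=100.0 * r) for r in ratios
            ]

        assert protein_median_ratio(pairs_with([0.1, 0.2, 0.4])) == (
            pytest.approx(0.2),
            3,
        )
        assert protein_median_ratio(pairs_with([0.3]))[0] == pytest.approx(0.3)
        assert protein_median_ratio(pairs_with([0.1, 0.3]))[0] == pytest.approx(
            0.2
        )

    def test_no_eligible_pairs_is_error(self):
        with pytest.raises(ValueError):
            protein_median_ratio(
                [make_pair(light_area=0.0, heavy_area=1.0)]
            )

    @given(
        ratios=st.lists(positive, min_size=3, max_size=9),
        factor=st.floats(1e3, 1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_median_robust_to_minority_corruption(self, ratios, factor):
        """Corrupting fewer than half the peptides leaves the estimate within
        the range of the uncorrupted ratios."""
        n_corrupt = (len(ratios) - 1) // 2
        corrupted = [r * factor for r in ratios[:n_corrupt]] + ratios[n_corrupt:]
        pairs = [
            make_pair(light_area=1.0, heavy_area=r) for r in corrupted
        ]
        med, _ = protein_median_ratio(pairs)
        clean = ratios[n_corrupt:]
        assert min(clean) * (1 - 1e-9) <= med <= max(clean) * (1 + 1e-9)


class TestStoichAtMix:
    @pytest.mark.parametrize(
        "rho,median,expected",
        [
            (1 / 2000, 1 / 2000, 1.0),
            (0.02, 2.0, 0.01),
            (1 / 800, 0.25, 0.005),
        ],
    )
    def test_formula(self, rho, median, expected):
        assert stoich_at_mix(rho, median) == pytest.approx(expected)

    def test_nonpositive_median_is_error(self):
        with pytest.raises(ValueError):
            stoich_at_mix(0.01, 0.0)

    @given(rho=positive, s=positive)
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, rho, s):
        """stoich_at_mix(rho, rho/s) = s for all positive rho, s."""
        assert stoich_at_mix(rho, rho / s) == pytest.approx(s, rel=1e-12)

    @given(rho=positive, m1=positive, m2=positive)
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_median_ratio(self, rho, m1, m2):
        if m1 == m2:
            return
        lo, hi = sorted([m1, m2])
        assert stoich_at_mix(rho, lo) > stoich_at_mix(rho, hi)


class TestCombineAcrossMixes:
    def test_median_of_available_mixes(self):
        s, flags = combine_across_mixes(
            {"a": 0.005, "b": 0.006, "c": 0.007, "d": 0.008}
        )
        assert s == pytest.approx(0.0065)
        assert flags == set()

    def test_single_mix_flagged(self):
        s, flags = combine_across_mixes({"a": 0.01})
        assert s == pytest.approx(0.01)
        assert flags == {SINGLE_MIX}

    def test_gt_one_flagged_never_capped(self):
        s, flags = combine_across_mixes({"a": 1.5, "b": 2.5})
        assert s == pytest.approx(2.0)
        assert GT_ONE in flags

    @given(values=st.lists(positive, min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_order_invariance(self, values):
        fwd = {f"m{i}": v for i, v in enumerate(values)}
        rev = {f"m{i}": v for i, v in enumerate(reversed(values))}
        assert combine_across_mixes(fwd)[0] == pytest.approx(
            combine_across_mixes(rev)[0]
        )


class TestFilterPeptides:
    @pytest.fixture
    def universe(self):
        records = [
            ProteinRecord("REF1", "MKPAKRCDEFGHIK"),
            ProteinRecord("REF2", "AAAKWWWKYYYK"),
            ProteinRecord("OTHER", "GGGKCCCK"),
            # REF1 and SHARED both contain the Lys-C peptide "WWWK"
            ProteinRecord("SHARED", "WWWKPPPK"),
        ]
        sites = [SiteAnnotation("REF1", 7, "C")]
        reference = {"REF1", "REF2", "SHARED"}
        return records, sites, reference

    def test_each_rule_attributed_once(self, universe):
        records, sites, reference = universe
        pairs = [
            make_pair(sequence="MKPAK"),                      # pass (REF1, 1 missed)
            make_pair(sequence="PAK", light_sn=4.0),          # fail S/N
            make_pair(sequence="CCCK"),                       # fail reference (OTHER)
            make_pair(sequence="TTTQQQTTT"),                  # fail reference (unmapped)
            make_pair(sequence="RCDEFGHIK"),                  # fail site (spans REF1:7)
            make_pair(sequence="WWWK"),                       # fail shared (REF2+SHARED)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, report = filter_peptides(
                pairs, reference, sites=sites, protein_records=records
            )
        assert report.n_input == 6
        assert report.n_pass == 1
        assert report.n_fail_sn == 1
        assert report.n_fail_reference == 2
        assert report.n_fail_site == 1
        assert report.n_fail_shared == 1
        report.check()
        assert [p.sequence for p in retained] == ["MKPAK"]
        assert retained[0].protein_ids == frozenset({"REF1"})

    def test_assign_to_all_duplicates_shared_peptide(self, universe):
        records, sites, reference = universe
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained, report = filter_peptides(
                [make_pair(sequence="WWWK")],
                reference,
                sites=sites,
                protein_records=records,
                shared_policy="assign-to-all",
            )
        assert report.n_pass == 1 and report.n_fail_shared == 0
        assert sorted(p.protein_ids for p in retained) == [
            frozenset({"REF2"}),
            frozenset({"SHARED"}),
        ]

    def test_site_check_skipped_without_records(self):
        with pytest.warns(UserWarning, match="site exclusion skipped"):
            retained, report = filter_peptides(
                [make_pair(sequence="PAK", protein_ids=("REF1",))], {"REF1"}
            )
        assert report.n_pass == 1

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            filter_peptides([make_pair()], set())


class TestEstimateAndMerge:
    def test_missing_mix_points_use_available_median(self, mix_points):
        # protein seen at two of four mix points only
        pairs = [
            make_pair(sequence="AK", protein_ids=("P1",), mix_id="1:2000",
                      light_area=100, heavy_area=100 * (1 / 2000) / 0.01),
            make_pair(sequence="CK", protein_ids=("P1",), mix_id="1:50",
                      light_area=100, heavy_area=100 * (1 / 50) / 0.01),
        ]
        ests = estimate_stoichiometries(pairs, mix_points, "R1")
        assert len(ests) == 1
        assert ests[0].stoich == pytest.approx(0.01)
        assert set(ests[0].per_mix_stoich) == {"1:2000", "1:50"}

    def test_input_order_invariance(self, noisy_run):
        tables = noisy_run["tables"]
        records = noisy_run["records"]
        reference = {r.id for r in records}
        pairs = tables["R1"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kept_fwd, _ = filter_peptides(pairs, reference, protein_records=records, sites=[])
            kept_rev, _ = filter_peptides(pairs[::-1], reference, protein_records=records, sites=[])
        from parstoich.simulate import DEFAULT_MIX_POINTS

        e1 = estimate_stoichiometries(kept_fwd, DEFAULT_MIX_POINTS, "R1")
        e2 = estimate_stoichiometries(kept_rev, DEFAULT_MIX_POINTS, "R1")
        assert {x.protein_id: x.stoich for x in e1} == pytest.approx(
            {x.protein_id: x.stoich for x in e2}
        )

    def _est(self, pid, rep, stoich):
        from parstoich.io_model import StoichEstimate

        return StoichEstimate(protein_id=pid, replicate_id=rep, stoich=stoich)

    def test_identical_replicates_r_is_one(self):
        ests = [self._est(f"P{i}", "R1", s) for i, s in enumerate([0.01, 0.1, 0.002])]
        ests2 = [self._est(e.protein_id, "R2", e.stoich) for e in ests]
        table, overlap, r = merge_replicates({"R1": ests, "R2": ests2})
        assert overlap == {"P0", "P1", "P2"}
        assert r == pytest.approx(1.0)
        assert table.loc["P1", "stoich"] == pytest.approx(0.1)

    def test_scaled_replicates_r_is_one_on_log_scale(self):
        ests = [self._est(f"P{i}", "R1", s) for i, s in enumerate([0.01, 0.1, 0.002, 0.3])]
        ests2 = [self._est(e.protein_id, "R2", e.stoich * 3.7) for e in ests]
        table, _, r = merge_replicates({"R1": ests, "R2": ests2})
        assert r == pytest.approx(1.0)

    def test_disjoint_replicates_have_no_correlation(self):
        table, overlap, r = merge_replicates(
            {
                "R1": [self._est("A", "R1", 0.1)],
                "R2": [self._est("B", "R2", 0.2)],
            }
        )
        assert overlap == set()
        assert r is None
        assert len(table) == 2

    def test_single_replicate_warns_identity(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            table, overlap, r = merge_replicates(
                {"R1": [self._est("A", "R1", 0.1)]}
            )
        assert table.loc["A", "stoich"] == pytest.approx(0.1)
        assert r is None


class TestSummarize:
    def test_small_example(self):
        s = summarize([0.0005, 0.005, 0.06])  # 0.05%, 0.5%, 6%
        assert s.median_pct == pytest.approx(0.5)
        assert s.mean_pct == pytest.approx((0.05 + 0.5 + 6.0) / 3)
        assert s.n_gt_5pct == 1
        assert s.n_lt_1pct == 2
        assert s.bin_counts == {"<0.1%": 1, "0.1–0.5%": 0, "0.5–1%": 1, ">1%": 1}

    def test_single_protein_all_stats_equal(self):
        s = summarize([0.02])
        assert s.median_pct == s.mean_pct == s.min_pct == s.max_pct == pytest.approx(2.0)

    def test_matches_independent_recomputation_on_simulation(self, noisy_run):
        merged = noisy_run["merged"]
        s = summarize(merged)
        # independent recomputation straight from the raw vector
        raw = np.sort(merged["stoich"].dropna().to_numpy()) * 100.0
        n = raw.size
        assert s.n_proteins == n
        med = (raw[n // 2] if n % 2 else (raw[n // 2 - 1] + raw[n // 2]) / 2)
        assert s.median_pct == pytest.approx(med)
        assert s.mean_pct == pytest.approx(raw.sum() / n)
        assert s.min_pct == pytest.approx(raw[0])
        assert s.max_pct == pytest.approx(raw[-1])
        assert s.n_gt_5pct == int((raw > 5).sum())
        assert s.n_lt_1pct == int((raw < 1).sum())
        assert sum(s.bin_counts.values()) == n

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            summarize([])
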