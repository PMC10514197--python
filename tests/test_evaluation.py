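"""Representation reports, accumulation curves, kappa, gap analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import sparse

from mangroveprio import (
    ProblemInstance,
    RankMap,
    Selection,
    cohens_kappa,
    gap_report,
    representation_report,
    service_accumulation,
)
from conftest import point_units, three_unit_problem


def two_feature_problem():
    return ProblemInstance(
        sparse.csr_matrix(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])),
        np.array([1.0, 2.0]),
        np.ones(2),
        np.ones(3),
        np.arange(3),
        ["f0", "f1"],
        frozenset(),
        3.0,
    )


class TestRepresentationReport:
    def test_full_selection_meets_everything(self):
        rep = representation_report(two_feature_problem(), {0, 1, 2})
        assert rep.percent_met == 100.0

    def test_empty_selection_meets_nothing(self):
        rep = representation_report(two_feature_problem(), set())
        assert rep.n_met == 0
        assert rep.per_feature["shortfall"].tolist() == pytest.approx([1.0, 2.0])

    def test_half_met_hand_example(self):
        rep = representation_report(two_feature_problem(), {0, 1})
        assert rep.percent_met == pytest.approx(50.0)
        assert rep.per_feature.loc[0, "met"]
        assert not rep.per_feature.loc[1, "met"]


class TestServiceAccumulation:
    def _rank_map(self, ranks, grid):
        return RankMap(rank_by_unit=ranks, budget_grid=grid)

    def test_single_step_captures_everything(self):
        rm = self._rank_map({0: 1, 1: 1, 2: 1}, [1.0])
        curve = service_accumulation(rm, {"svc": {0: 10.0, 1: 5.0, 2: 5.0}})
        assert curve["svc_percent"].tolist() == [100.0]

    def test_concentrated_service_saturates_immediately(self):
        rm = self._rank_map({0: 1, 1: 2, 2: 3}, [1 / 3, 2 / 3, 1.0])
        curve = service_accumulation(rm, {"svc": {0: 10.0, 1: 0.0, 2: 0.0}})
        assert curve["svc_percent"].tolist() == [100.0, 100.0, 100.0]

    def test_uniform_service_accumulates_linearly(self):
        n = 10
        rm = self._rank_map({i: i + 1 for i in range(n)}, [(i + 1) / n for i in range(n)])
        curve = service_accumulation(rm, {"svc": {i: 3.0 for i in range(n)}})
        assert curve["svc_percent"].tolist() == pytest.approx(
            [100.0 * (i + 1) / n for i in range(n)]
        )

    def test_curves_non_decreasing_and_end_at_total(self):
        rm = self._rank_map({0: 2, 1: 1, 2: 3, 3: 0}, [0.3, 0.6, 1.0])
        curve = service_accumulation(rm, {"svc": {0: 1.0, 1: 2.0, 2: 3.0, 3: 4.0}})
        pct = curve["svc_percent"].to_numpy()
        assert (np.diff(pct) >= -1e-12).all()
        assert pct[-1] == pytest.approx(100.0)

    def test_inconsistent_selections_rejected(self):
        rm = RankMap(
            rank_by_unit={0: 1, 1: 2},
            budget_grid=[0.5, 1.0],
            selections=[
                Selection(frozenset({1}), 0.0, 1.0, "exact"),  # step 1 should contain unit 0
                Selection(frozenset({0, 1}), 0.0, 2.0, "exact"),
            ],
        )
        with pytest.raises(AssertionError, match="nested"):
            service_accumulation(rm, {"svc": {0: 1.0, 1: 1.0}})


class TestCohensKappa:
    def test_identical_selections(self):
        assert cohens_kappa({1, 2, 3}, {1, 2, 3}, range(10)) == pytest.approx(1.0)

    def test_partial_overlap_hand_example(self):
        # A={1..5}, B={4..8} over 10 units: p_o=0.4, p_e=0.5
        kappa = cohens_kappa(set(range(1, 6)), set(range(4, 9)), range(1, 11))
        assert kappa == pytest.approx(-0.2)

    def test_disjoint_halves(self):
        kappa = cohens_kappa(set(range(1, 6)), set(range(6, 11)), range(1, 11))
        assert kappa == pytest.approx(-1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cohens_kappa(set(), set(), [])

    def test_degenerate_identical_full_selections(self):
        assert cohens_kappa({0, 1}, {0, 1}, [0, 1]) == 1.0
        assert cohens_kappa(set(), set(), [0, 1]) == 1.0

    def test_total_disagreement_with_degenerate_marginals(self):
        # p_A=1, p_B=0 gives p_e=0, so kappa reduces to p_o = 0
        assert cohens_kappa({0, 1}, set(), [0, 1]) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 14)),
        b=st.sets(st.integers(0, 14)),
    )
    def test_symmetric_and_bounded(self, a, b):
        universe = range(15)
        k1 = cohens_kappa(a, b, universe)
        k2 = cohens_kappa(b, a, universe)
        if math.isnan(k1):
            assert math.isnan(k2)
        else:
            assert k1 == pytest.approx(k2)
            assert -1 - 1e-12 <= k1 <= 1 + 1e-12

    def test_area_weighted_variant(self):
        areas = {0: 10.0, 1: 1.0}
        kappa = cohens_kappa({0}, {0}, [0, 1], area_by_unit=areas)
        assert kappa == pytest.approx(1.0)


class TestGapReport:
    def _units(self, strict, any_frac, areas, zones=None):
        n = len(areas)
        return point_units(
            range(n),
            areas=areas,
            strict_protected_fraction=strict,
            any_protected_fraction=any_frac,
            zone_id=zones if zones is not None else [0] * n,
        )

    def test_all_protected_covers_everything(self):
        units = self._units([0.9, 0.8], [0.9, 0.8], [2.0, 3.0])
        rep = gap_report(units, {"svc": {0: 1.0, 1: 2.0}})
        assert rep.percent_area_protected_strict == pytest.approx(100.0)
        assert rep.service_totals_protected["svc"] == pytest.approx(3.0)
        assert rep.service_percent_protected["svc"] == pytest.approx(100.0)

    def test_equal_area_half_protected(self):
        units = self._units([0.9, 0.1], [0.9, 0.1], [5.0, 5.0])
        rep = gap_report(units, {})
        assert rep.percent_area_protected_strict == pytest.approx(50.0)

    def test_mean_area_ratio_hand_example(self):
        units = self._units([0.9, 0.9, 0.1, 0.1], [0.9, 0.9, 0.1, 0.1], [3.0, 3.0, 2.0, 2.0])
        rep = gap_report(units, {})
        assert rep.mean_area_ratio_protected_vs_unprotected == pytest.approx(1.5)

    def test_zone_coverage_weighted_by_area(self):
        units = self._units(
            [0.9, 0.1, 0.9, 0.1], [0.9, 0.1, 0.9, 0.1], [1.0, 3.0, 2.0, 2.0], zones=[0, 0, 1, 1]
        )
        rep = gap_report(units, {})
        zone = rep.coverage_by_zone.set_index("zone_id")["percent_area_protected"]
        assert zone[0] == pytest.approx(25.0)
        assert zone[1] == pytest.approx(50.0)

    def test_random_coverage_tracks_uniform_services(self):
        # a random ~30% of area carries ≈30% of a uniform service on average
        rng = np.random.default_rng(0)
        shares = []
        for _ in range(30):
            strict = np.where(rng.random(50) < 0.3, 0.9, 0.1)
            units = self._units(strict, strict, np.ones(50))
            rep = gap_report(units, {"svc": {i: 1.0 for i in range(50)}})
            shares.append(rep.service_percent_protected["svc"])
        assert np.mean(shares) == pytest.approx(30.0, abs=5.0)

    def test_prioritised_class_excludes_protected(self):
        units = self._units([0.9, 0.1, 0.1], [0.9, 0.9, 0.1], [1.0, 1.0, 1.0])
        rep = gap_report(units, {"svc": {0: 1.0, 1: 2.0, 2: 4.0}}, prioritised={0, 1, 2})
        classes = rep.class_mean_services.set_index("class")
        assert classes.loc["prioritised_not_pa", "n_units"] == 1
        assert classes.loc["prioritised_not_pa", "svc_mean"] == pytest.approx(4.0)
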