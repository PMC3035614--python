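"""Parameter-plane ASS maps and the heterogeneous multistability search."""

import dataclasses

import numpy as np
import pytest

from ontoshift.examples import heterogeneous_search_base
from ontoshift.models import (
    AdditionalResourcesParams,
    default_params,
)
from ontoshift.scans import (
    AxisSpec,
    ScanSpec,
    heterogeneous_multistability_search,
    scan_ass_region,
    subsidy_variant_scan,
    with_param,
)


class TestWithParam:
    def test_scalar_field(self, multiple_baseline):
        p = with_param(multiple_baseline, "n_J", 3.0)
        assert p.n_J == 3.0 and p.n_A == multiple_baseline.n_A

    def test_indexed_field(self, additional_baseline):
        p = with_param(additional_baseline, "K_J[1]", 25.0)
        assert p.K_J[1] == 25.0 and p.K_J[0] == additional_baseline.K_J[0]
        assert additional_baseline.K_J[1] == 10.0  # original untouched

    def test_unknown_field_rejected(self, additional_baseline):
        with pytest.raises(ValueError, match="no parameter"):
            with_param(additional_baseline, "K_X", 1.0)

    def test_out_of_range_index_rejected(self, additional_baseline):
        with pytest.raises(ValueError, match="out of range"):
            with_param(additional_baseline, "K_J[5]", 1.0)


class TestScenarioMaps:
    def test_additional_map_requires_balanced_availability(self, additional_baseline):
        """ASS hold near the balanced diagonal and fail when one stage's
        total resource availability is far below the other's."""
        spec = ScanSpec(
            additional_baseline,
            AxisSpec("K_J[1]", 0.5, 30.0, 7),
            AxisSpec("K_A[1]", 0.5, 30.0, 7),
        )
        res = scan_ass_region(spec)
        assert not res.failures
        assert res.ass[2, 2]  # balanced mid-plane cell
        assert not res.ass[6, 0]  # adult availability far too low
        # juvenile-deficit direction: the fixed first resource (K_J,1 = 10)
        # keeps juvenile availability up inside this panel, so demonstrate
        # the balance requirement by starving the whole juvenile side
        poor_juv = with_param(
            with_param(
                with_param(additional_baseline, "K_J[0]", 1.0), "K_J[1]", 1.0
            ),
            "K_A[1]", 30.0,
        )
        from ontoshift.equilibria import ass_condition

        assert not ass_condition(poor_juv).ass_exists

    def test_multiple_map_confined_to_comparable_habitat_numbers(
        self, multiple_baseline
    ):
        spec = ScanSpec(
            multiple_baseline,
            AxisSpec("n_J", 1.0, 4.0, 13),
            AxisSpec("n_A", 1.0, 4.0, 13),
        )
        res = scan_ass_region(spec)
        assert res.ass.any()
        ratios = [
            res.x[i] / res.y[j]
            for i in range(13)
            for j in range(13)
            if res.ass[i, j]
        ]
        assert all(0.4 < r < 1.2 for r in ratios)  # a band along the diagonal
        assert not res.ass[12, 0] and not res.ass[0, 12]

    def test_sharing_map_suppression_and_redevelopment(self, sharing_baseline):
        """Counting sign-definite cubic candidates: cross-feeding destroys
        the three-candidate region, which reappears when both cross rates
        are very large (stages effectively exchange their major resources)."""
        spec = ScanSpec(
            sharing_baseline,
            AxisSpec("a_JA", 0.0, 0.6, 13),
            AxisSpec("a_AJ", 0.0, 0.6, 13),
            analytic_options={"require_resource_positivity": False},
        )
        res = scan_ass_region(spec)
        assert res.ass[0, 0]  # stage-specific diets
        assert not res.ass[6, 0] and not res.ass[0, 6]  # one-sided sharing
        assert res.ass[9, 9]  # both very large: major resources swapped
        # under strict resource positivity the redeveloped candidates map to
        # states with the nominal juvenile resource excluded
        strict = scan_ass_region(dataclasses.replace(spec, analytic_options={}))
        assert not strict.ass[9, 9]

    def test_grid_refinement_keeps_area_fraction(self, multiple_baseline):
        coarse = scan_ass_region(
            ScanSpec(
                multiple_baseline,
                AxisSpec("n_J", 1.0, 4.0, 16),
                AxisSpec("n_A", 1.0, 4.0, 16),
            )
        )
        fine = scan_ass_region(
            ScanSpec(
                multiple_baseline,
                AxisSpec("n_J", 1.0, 4.0, 31),
                AxisSpec("n_A", 1.0, 4.0, 31),
            )
        )
        assert abs(coarse.ass_fraction - fine.ass_fraction) < 0.05

    def test_result_dataframe_roundtrip(self, multiple_baseline, tmp_path):
        spec = ScanSpec(
            multiple_baseline,
            AxisSpec("n_J", 1.0, 3.0, 3),
            AxisSpec("n_A", 1.0, 3.0, 3),
        )
        res = scan_ass_region(spec)
        df = res.to_dataframe()
        assert list(df.columns) == ["x", "y", "ass", "boundary", "n_equilibria"]
        assert len(df) == 9
        res.save(str(tmp_path / "map"))
        assert (tmp_path / "map.csv").exists() and (tmp_path / "map.json").exists()


class TestSubsidyScan:
    @staticmethod
    def _base(bistable):
        """Bistable core plus one subsidized (donor-controlled) resource per stage."""
        return AdditionalResourcesParams(
            r_J=[2.4, 1.0], K_J=[10.0, 1.0], a_J=[0.05, 0.05], b_J=[0.9, 0.9],
            r_A=[2.8, 1.0], K_A=[28.0, 1.0], a_A=[0.1, 0.1], b_A=[1.0, 1.0],
            d_J=0.4, d_A=0.23,
            subsidized_J=[False, True], input_J=[0.0, 0.0], loss_J=[0.0, 0.5],
            subsidized_A=[False, True], input_A=[0.0, 0.0], loss_A=[0.0, 0.5],
        )

    def test_zero_input_reduces_to_core_model(self, bistable_params):
        from ontoshift.equilibria import ass_condition, coexistence_equilibria

        sub = self._base(bistable_params)
        core = coexistence_equilibria(bistable_params, classify=False)
        with_sub = coexistence_equilibria(sub, classify=False)
        assert len(core) == len(with_sub) == 3
        np.testing.assert_allclose(
            [r.C_J for r in with_sub], [r.C_J for r in core], rtol=1e-6
        )
        assert ass_condition(sub).ass_exists

    def test_balanced_inputs_keep_ass_one_sided_inputs_destroy_it(
        self, bistable_params
    ):
        spec = ScanSpec(
            self._base(bistable_params),
            AxisSpec("input_J[1]", 0.0, 6.0, 5),
            AxisSpec("input_A[1]", 0.0, 6.0, 5),
        )
        res = subsidy_variant_scan(spec)
        assert not res.failures
        assert res.ass[1, 1]  # balanced moderate subsidies
        assert not res.ass[4, 0] and not res.ass[0, 4]  # strongly one-sided

    def test_requires_subsidy_flags(self, bistable_params):
        spec = ScanSpec(
            bistable_params,
            AxisSpec("K_J[0]", 5.0, 15.0, 3),
            AxisSpec("K_A[0]", 20.0, 30.0, 3),
        )
        with pytest.raises(ValueError, match="subsid"):
            subsidy_variant_scan(spec)


class TestHeterogeneousSearch:
    def test_finds_three_attractors_with_mirrored_dominance(self):
        base = heterogeneous_search_base()
        res = heterogeneous_multistability_search(base, [3.7])
        assert res.max_count >= 3
        reps = res.descriptors[0]
        juv_dominated = [
            r for r in reps if r.mean[4] + r.mean[5] > r.mean[6] + r.mean[7]
        ]
        assert len(juv_dominated) == 2
        first, second = juv_dominated
        assert (first.mean[4] > first.mean[5]) != (second.mean[4] > second.mean[5])

    def test_zero_offset_matches_symmetric_model_census(self):
        from ontoshift.dynamics import count_attractors
        from ontoshift.scans import _heterogeneity_probe_set
        from ontoshift.equilibria import coexistence_equilibria

        base = heterogeneous_search_base()
        res = heterogeneous_multistability_search(base, [0.0])
        recs = coexistence_equilibria(base, classify=False)
        n, reps, _ = count_attractors(base, _heterogeneity_probe_set(base, recs))
        assert res.counts[0] == sum(1 for r in reps if r.kind != "boundary")

    def test_requires_two_by_two_homogeneous_base(self, multiple_baseline):
        bad = dataclasses.replace(multiple_baseline, n_J=3)
        with pytest.raises(ValueError, match="n_J = n_A = 2"):
            heterogeneous_multistability_search(bad, [1.0])
        het = dataclasses.replace(
            multiple_baseline, K_J_override=np.array([12.0, 8.0])
        )
        with pytest.raises(ValueError, match="homogeneous"):
            heterogeneous_multistability_search(het, [1.0])
        with pytest.raises(ValueError, match="positive"):
            heterogeneous_multistability_search(multiple_baseline, [20.0])
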