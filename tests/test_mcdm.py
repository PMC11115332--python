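"""F-ARAS, F-VIKOR and F-WASPAS rankers over fuzzy decision matrices."""

import numpy as np
import pytest

from fuzzrisk.errors import DegenerateCriterionError, ZeroEntryError
from fuzzrisk.fuzzy import TFN
from fuzzrisk.mcdm import (
    Criterion,
    FuzzyDecisionMatrix,
    aras_rank,
    build_matrix_from_register,
    vikor_rank,
    waspas_rank,
)


def crisp_matrix(rows, weights=None, directions=None):
    """Matrix of crisp entries: rows = {alt: [v1, v2, ...]}."""
    alts = list(rows)
    n = len(next(iter(rows.values())))
    weights = weights or [1.0 / n] * n
    directions = directions or ["benefit"] * n
    criteria = [Criterion(f"c{j}", directions[j], weights[j]) for j in range(n)]
    entries = {
        (a, f"c{j}"): TFN.crisp(v) for a, vals in rows.items() for j, v in enumerate(vals)
    }
    return FuzzyDecisionMatrix(alts, criteria, entries)


def fuzzy_matrix(rows, weights=None):
    alts = list(rows)
    n = len(next(iter(rows.values())))
    weights = weights or [1.0 / n] * n
    criteria = [Criterion(f"c{j}", "benefit", weights[j]) for j in range(n)]
    entries = {
        (a, f"c{j}"): TFN(*v) for a, vals in rows.items() for j, v in enumerate(vals)
    }
    return FuzzyDecisionMatrix(alts, criteria, entries)


class TestMatrixValidation:
    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="missing entry"):
            FuzzyDecisionMatrix(
                ["A"], [Criterion("c0", "benefit", 1.0)], {}
            )

    def test_crisp_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            crisp_matrix({"A": [1, 1], "B": [1, 1]}, weights=[0.9, 0.9])

    def test_fuzzy_weight_sum_warns(self):
        alts = {"A": [1.0], "B": [0.5]}
        criteria = [Criterion("c0", "benefit", TFN(0.5, 0.6, 0.7))]
        entries = {(a, "c0"): TFN.crisp(v[0]) for a, v in alts.items()}
        with pytest.warns(UserWarning, match="weights sum"):
            FuzzyDecisionMatrix(list(alts), criteria, entries)


class TestAras:
    def test_two_alternative_hand_computation(self):
        """Ideal (1,1); column sums 2.5 each; S0=SA=0.4, SB=0.2 -> K=(1.0, 0.5)."""
        res = aras_rank(crisp_matrix({"A": [1.0, 1.0], "B": [0.5, 0.5]}, weights=[0.5, 0.5]))
        assert res.k["A"] == pytest.approx(1.0, abs=1e-12)
        assert res.k["B"] == pytest.approx(0.5, abs=1e-12)
        assert res.rank == {"A": 1, "B": 2}

    def test_k_bounded_by_ideal(self, rng):
        for _ in range(20):
            rows = {f"A{i}": list(rng.uniform(0.1, 1, 3)) for i in range(5)}
            res = aras_rank(crisp_matrix(rows))
            for a, k in res.k.items():
                assert 0 < k <= 1 + 1e-12

    def test_cost_criterion_prefers_smaller(self):
        res = aras_rank(
            crisp_matrix({"A": [1.0], "B": [2.0]}, weights=[1.0], directions=["cost"])
        )
        assert res.rank["A"] == 1

    def test_scale_invariance_of_ranking(self, rng):
        rows = {f"A{i}": list(rng.uniform(0.1, 1, 3)) for i in range(6)}
        base = aras_rank(crisp_matrix(rows))
        scaled_rows = {a: [v[0] * 7.3, v[1], v[2]] for a, v in rows.items()}
        scaled = aras_rank(crisp_matrix(scaled_rows))
        assert base.rank == scaled.rank


class TestVikor:
    def test_best_on_every_criterion_has_zero_scores(self):
        res = vikor_rank(crisp_matrix({"A": [1.0, 1.0], "B": [0.4, 0.6], "C": [0.2, 0.2]}))
        assert res.s["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.r["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.q["A"] == pytest.approx(0.0, abs=1e-12)
        assert res.rank["A"] == 1

    def test_worse_on_all_gets_q_one(self):
        res = vikor_rank(crisp_matrix({"A": [1.0, 1.0], "B": [0.5, 0.5]}))
        assert res.q["B"] == pytest.approx(1.0, abs=1e-12)

    def test_q_within_unit_interval(self, rng):
        for _ in range(20):
            rows = {f"A{i}": list(rng.uniform(0, 1, 3)) for i in range(6)}
            res = vikor_rank(crisp_matrix(rows))
            assert all(-1e-9 <= q <= 1 + 1e-9 for q in res.q.values())

    def test_constant_criterion_contributes_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            res = vikor_rank(crisp_matrix({"A": [1.0, 0.5], "B": [1.0, 0.2]}))
        assert res.rank["A"] == 1

    def test_all_constant_criteria_rejected(self):
        with pytest.warns(UserWarning, match="constant"):
            with pytest.raises(DegenerateCriterionError):
                vikor_rank(crisp_matrix({"A": [1.0, 0.5], "B": [1.0, 0.5]}))

    def test_conditions_and_compromise_set(self):
        # clear winner: both conditions met, singleton compromise set
        res = vikor_rank(crisp_matrix({"A": [1.0, 1.0], "B": [0.2, 0.2], "C": [0.1, 0.1]}))
        assert res.condition1_met and res.condition2_met
        assert res.compromise_set == ["A"]
        # near-tie at the top: condition 1 fails, compromise set grows
        res2 = vikor_rank(
            crisp_matrix({"A": [1.0, 0.99], "B": [0.99, 1.0], "C": [0.1, 0.1]})
        )
        assert not res2.condition1_met
        assert set(res2.compromise_set) >= {"A", "B"}

    def test_v_weighting_endpoints(self):
        rows = {"A": [1.0, 0.0], "B": [0.0, 0.8], "C": [0.6, 0.6]}
        m = crisp_matrix(rows)
        res_s = vikor_rank(m, v=1.0)  # pure group utility
        res_r = vikor_rank(m, v=0.0)  # pure individual regret
        s_vals, r_vals = res_s.s, res_s.r
        s_lo, s_hi = min(s_vals.values()), max(s_vals.values())
        r_lo, r_hi = min(r_vals.values()), max(r_vals.values())
        for a in rows:
            assert res_s.q[a] == pytest.approx((s_vals[a] - s_lo) / (s_hi - s_lo), abs=1e-9)
            assert res_r.q[a] == pytest.approx((r_vals[a] - r_lo) / (r_hi - r_lo), abs=1e-9)


class TestWaspas:
    def test_column_maximum_row_scores_one(self):
        res = waspas_rank(crisp_matrix({"A": [1.0, 2.0], "B": [0.5, 1.0]}))
        assert res.q_wsm["A"] == pytest.approx(1.0)
        assert res.p_wpm["A"] == pytest.approx(1.0)
        assert res.k_prime["A"] == pytest.approx(1.0)

    def test_lambda_endpoints_select_pure_models(self):
        m = crisp_matrix({"A": [1.0, 0.25], "B": [0.5, 1.0]})
        res1 = waspas_rank(m, lam=1.0)
        res0 = waspas_rank(m, lam=0.0)
        assert res1.k_prime == pytest.approx(res1.q_wsm)
        assert res0.k_prime == pytest.approx(res0.p_wpm)

    def test_hand_computation(self):
        """Normalized row (1, 0.25): Q=0.625, P=0.5, K'(0.5)=0.5625."""
        res = waspas_rank(crisp_matrix({"A": [1.0, 0.25], "B": [1.0, 1.0]}, weights=[0.5, 0.5]))
        assert res.q_wsm["A"] == pytest.approx(0.625, abs=1e-12)
        assert res.p_wpm["A"] == pytest.approx(0.5, abs=1e-12)
        assert res.k_prime["A"] == pytest.approx(0.5625, abs=1e-12)

    def test_auto_lambda_matches_formula(self):
        m = crisp_matrix({"A": [1.0, 0.25], "B": [0.5, 1.0]})
        res = waspas_rank(m, lam="auto")
        lam = sum(res.p_wpm.values()) / (sum(res.q_wsm.values()) + sum(res.p_wpm.values()))
        assert res.lam == pytest.approx(lam)
        for a in m.alternatives:
            assert res.k_prime[a] == pytest.approx(lam * res.q_wsm[a] + (1 - lam) * res.p_wpm[a])

    def test_wpm_never_exceeds_wsm(self, rng):
        for _ in range(20):
            rows = {f"A{i}": list(rng.uniform(0.05, 1, 4)) for i in range(5)}
            res = waspas_rank(crisp_matrix(rows))
            for a in rows:
                assert res.p_wpm[a] <= res.q_wsm[a] + 1e-12

    def test_zero_entry_rejected_for_wpm(self):
        with pytest.raises(ZeroEntryError):
            waspas_rank(crisp_matrix({"A": [0.0, 1.0], "B": [1.0, 1.0]}))

    def test_scale_invariance_of_ranking(self, rng):
        rows = {f"A{i}": list(rng.uniform(0.1, 1, 3)) for i in range(6)}
        base = waspas_rank(crisp_matrix(rows))
        scaled_rows = {a: [v[0] * 11.0, v[1], v[2]] for a, v in rows.items()}
        assert base.rank == waspas_rank(crisp_matrix(scaled_rows)).rank


class TestCrossMethod:
    def test_dominant_alternative_ranks_first_everywhere(self):
        rows = {
            "top": [(7, 8, 9), (9, 10, 10), (5, 7, 9)],
            "mid": [(5, 6, 7), (7, 8, 9), (3, 5, 7)],
            "low": [(1, 2, 3), (2, 3, 4), (1, 3, 5)],
        }
        m = fuzzy_matrix(rows)
        assert aras_rank(m).rank["top"] == 1
        assert vikor_rank(m).rank["top"] == 1
        assert waspas_rank(m).rank["top"] == 1

    def test_transplant_matrix_puts_fm1_first_in_all_methods(self, transplant_register):
        m = build_matrix_from_register(transplant_register)
        assert aras_rank(m).rank["FM1"] == 1
        assert vikor_rank(m, v=0.5).rank["FM1"] == 1
        assert waspas_rank(m, lam=0.5).rank["FM1"] == 1


class TestBuildMatrix:
    def test_shape_and_weights(self, transplant_register):
        m = build_matrix_from_register(transplant_register)
        assert len(m.alternatives) == 10  # only fully rated modes
        assert [c.name for c in m.criteria] == ["occurrence", "severity", "detection"]
        assert all(c.crisp_weight() == pytest.approx(1 / 3) for c in m.criteria)

    def test_fm1_row_maps_through_scales(self, transplant_register, scales):
        m = build_matrix_from_register(transplant_register)
        assert m.entries[("FM1", "occurrence")] == TFN(7, 8, 9)
        assert m.entries[("FM1", "severity")] == TFN(9, 10, 10)
        assert m.entries[("FM1", "detection")] == TFN(5, 7, 9)

    def test_identical_modes_give_identical_rows(self, transplant_register):
        m = build_matrix_from_register(transplant_register)
        for f in ("occurrence", "severity", "detection"):
            assert m.entries[("FM2", f)] == m.entries[("FM3", f)]
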