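"""Tests for the sixteen missing-data strategies."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

from raschmiss import impute, rasch_mml, simgen
from raschmiss.types import ResponseData, SimulationConfig

nan = np.nan


@pytest.fixture(scope="module")
def incomplete_rasch():
    cfg = SimulationConfig(n_persons=250, seed=301, pi=0.3)
    _, incomplete, _, _ = simgen.simulate_incomplete(cfg, 0)
    return incomplete


class TestEligibility:
    def test_strict_majority_rule(self):
        data = ResponseData(np.array([
            [1, 0, 1, nan, nan],      # 3 observed of 5: eligible
            [1, 0, nan, nan, nan],    # 2 observed of 5: not
        ], dtype=float))
        np.testing.assert_array_equal(
            impute.eligible_rows(data), [True, False]
        )

    def test_even_item_count_needs_more_than_half(self):
        data = ResponseData(np.array([[1, 0, nan, nan], [1, 0, 1, nan]], dtype=float))
        # 2 of 4 observed is not a strict majority
        np.testing.assert_array_equal(impute.eligible_rows(data), [False, True])


class TestMethodInvariants:
    @pytest.mark.parametrize("name", impute.METHOD_NAMES)
    def test_observed_cells_never_altered(self, incomplete_rasch, name):
        rng = np.random.default_rng(7)
        with np.errstate(all="ignore"):
            result = impute.apply_method(name, incomplete_rasch, rng=rng)
        if name == "LD":
            keep = incomplete_rasch.complete_rows()
            np.testing.assert_array_equal(
                result.data.values, incomplete_rasch.values[keep]
            )
            return
        obs = ~np.isnan(incomplete_rasch.values)
        np.testing.assert_array_equal(
            result.data.values[obs], incomplete_rasch.values[obs]
        )
        filled = result.imputed_mask.astype(bool)
        assert np.isin(result.data.values[filled], (0.0, 1.0)).all()
        # methods only fill cells that were missing, in eligible rows
        assert not (filled & obs).any()
        assert not (filled & ~impute.eligible_rows(incomplete_rasch)[:, None]).any()
        assert not (filled & result.residual_missing).any()

    @pytest.mark.parametrize("name", ["WORST", "PMS", "IMS", "CIM", "RAS", "RAI"])
    def test_deterministic_methods_idempotent(self, incomplete_rasch, name):
        # these methods leave missing cells only in ineligible rows, which a
        # second pass must not touch
        first = impute.apply_method(name, incomplete_rasch)
        second = impute.apply_method(name, first.data)
        np.testing.assert_array_equal(
            np.nan_to_num(first.data.values, nan=-9),
            np.nan_to_num(second.data.values, nan=-9),
        )

    @pytest.mark.parametrize("name", ["ICS", "LOG"])
    def test_donor_cascade_methods_never_alter_previous_fills(
        self, incomplete_rasch, name
    ):
        # ICS/LOG may leave donor-dependent cells missing; a second pass may
        # fill those but must keep every pass-1 value
        first = impute.apply_method(name, incomplete_rasch)
        second = impute.apply_method(name, first.data)
        done = ~np.isnan(first.data.values)
        np.testing.assert_array_equal(
            second.data.values[done], first.data.values[done]
        )

    def test_deterministic_fill_is_mode_of_randomized(self, incomplete_rasch):
        # wherever p != 0.5, rounding equals the majority draw
        for fn in (impute.impute_pms, impute.impute_ims, impute.impute_cim):
            det = fn(incomplete_rasch, randomized=False)
            cells = det.imputed_mask.astype(bool)
            p = det.probabilities[cells]
            noties = p != 0.5
            assert np.array_equal(
                det.data.values[cells][noties], (p[noties] > 0.5).astype(float)
            )


class TestWorst:
    def test_fills_zero_and_respects_eligibility(self):
        data = ResponseData(np.array([
            [1, nan, 1, 1, 0],
            [1, 1, 0, 1, 0],
            [1, nan, nan, nan, nan],
        ], dtype=float))
        out = impute.impute_worst(data)
        np.testing.assert_array_equal(out.data.values[0], [1, 0, 1, 1, 0])
        np.testing.assert_array_equal(out.data.values[1], [1, 1, 0, 1, 0])
        assert np.isnan(out.data.values[2, 1:]).all()


class TestPMS:
    def test_rounding_and_tie_rule(self):
        data = ResponseData(np.array([
            [1, 1, 0, 1, nan],   # p = 0.75 -> 1
            [1, 0, nan, 0, 1],   # p = 0.5 -> 1 under half-up ties
            [0, 0, 1, 0, nan],   # p = 0.25 -> 0
        ], dtype=float))
        out = impute.impute_pms(data)
        assert out.data.values[0, 4] == 1.0
        assert out.data.values[1, 2] == 1.0
        assert out.data.values[2, 4] == 0.0

    def test_randomized_fill_frequency(self):
        rows = np.tile([1.0, 1.0, 0.0, 1.0, nan], (100_000, 1))
        out = impute.impute_pms(ResponseData(rows), randomized=True,
                                rng=np.random.default_rng(5))
        freq = out.data.values[:, 4].mean()
        assert abs(freq - 0.75) < 0.005


class TestIMS:
    def test_fills_item_means_rounded(self):
        # item observed positive rates 0.8, 0.6, 0.5, 0.4, 0.2
        base = np.zeros((10, 5))
        for j, k in enumerate((8, 6, 5, 4, 2)):
            base[:k, j] = 1.0
        data = ResponseData(np.vstack([base, np.array([[1, nan, nan, 1, 1]])]))
        out = impute.impute_ims(data)
        # observed rates incl. the probe row: item2 6/10, item3 5/10 -> both 1
        np.testing.assert_array_equal(out.data.values[-1], [1, 1, 1, 1, 1])

    def test_item_means_tie_goes_up(self):
        base = np.zeros((10, 5))
        for j, k in enumerate((8, 6, 5, 4, 2)):
            base[:k, j] = 1.0
        data = ResponseData(np.vstack([base, np.array([[1, 1, nan, nan, 0]])]))
        out = impute.impute_ims(data)
        # item3 observed rate is exactly 0.5 -> ties go up; item4 is 0.4 -> 0
        np.testing.assert_array_equal(out.data.values[-1, 2:4], [1.0, 0.0])

    def test_fully_missing_item_left_missing(self):
        data = ResponseData(np.array([
            [1, 0, 1, 1, nan],
            [1, 1, 0, 1, nan],
        ], dtype=float))
        with pytest.warns(UserWarning, match="no observed"):
            out = impute.impute_ims(data)
        assert np.isnan(out.data.values[:, 4]).all()
        assert out.residual_missing[:, 4].all()

    def test_randomized_fill_frequency(self):
        obs = np.tile([1.0, 0.0, 1.0, 0.0, 1.0], (3000, 1))
        obs[:1200, 4] = 0.0  # item5 observed rate 0.6
        probe = np.tile([1.0, 0.0, 1.0, 0.0, nan], (100_000, 1))
        data = ResponseData(np.vstack([obs, probe]))
        out = impute.impute_ims(data, randomized=True, rng=np.random.default_rng(6))
        freq = out.data.values[3000:, 4].mean()
        assert abs(freq - 0.6) < 0.005


class TestCIM:
    def test_hand_computed_fixture(self):
        data = ResponseData(np.array([
            [1, nan, 0],
            [1, 1, 1],
            [0, 1, nan],
            [1, 0, 0],
        ], dtype=float))
        out = impute.impute_cim(data)
        # item means: 3/4, 2/3, 1/3
        q12 = (1 / (3 / 4 + 1 / 3)) * (2 / 3)
        q33 = (1 / (3 / 4 + 2 / 3)) * (1 / 3)
        assert out.probabilities[0, 1] == pytest.approx(q12, abs=1e-12)
        assert out.probabilities[2, 2] == pytest.approx(q33, abs=1e-12)
        assert out.data.values[0, 1] == 1.0   # 8/13 rounds up
        assert out.data.values[2, 2] == 0.0   # 4/17 rounds down

    def test_clipping_and_zero_score(self):
        data = ResponseData(np.array([
            [1, 1, 1, 1, nan],   # top scorer: q clipped at 1 -> fill 1
            [0, 0, 0, 0, nan],   # zero score: q = 0 -> fill 0
            [1, 0, 1, 0, 1],
            [0, 1, 0, 1, 0],
        ], dtype=float))
        out = impute.impute_cim(data)
        assert out.probabilities[0, 4] == 1.0
        assert out.data.values[0, 4] == 1.0
        assert out.probabilities[1, 4] == 0.0
        assert out.data.values[1, 4] == 0.0


class TestICS:
    def test_perfectly_correlated_donor(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, size=(60, 1)).astype(float)
        noise = rng.integers(0, 2, size=(60, 3)).astype(float)
        values = np.hstack([x, x.copy(), noise])
        values[5, 1] = nan
        data = ResponseData(values)
        out = impute.impute_ics(data)
        assert out.data.values[5, 1] == values[5, 0]

    def test_missing_donor_leaves_cell_missing(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, size=(60, 1)).astype(float)
        noise = rng.integers(0, 2, size=(60, 3)).astype(float)
        values = np.hstack([x, x.copy(), noise])
        values[5, 1] = nan
        values[5, 0] = nan  # donor missing too; row still has 3 observed
        out = impute.impute_ics(ResponseData(values))
        assert np.isnan(out.data.values[5, 1])
        assert out.residual_missing[5, 1]

    def test_donor_map_matches_pandas_oracle(self, incomplete_rasch):
        corr = impute.item_correlations(incomplete_rasch)
        oracle = pd.DataFrame(incomplete_rasch.values).corr(min_periods=2).to_numpy()
        np.fill_diagonal(oracle, np.nan)
        np.testing.assert_allclose(corr, oracle, atol=1e-12)
        for j in range(5):
            assert np.nanargmax(corr[j]) == np.nanargmax(oracle[j])


class TestLOG:
    def test_perfect_predictor_is_copied(self):
        cfg = SimulationConfig(n_persons=400, seed=77)
        complete, _, _, _ = simgen.simulate_incomplete(cfg, 0)
        values = complete.values.copy()
        values[:, 1] = values[:, 0]              # item2 duplicates item1
        miss = np.random.default_rng(3).choice(400, size=60, replace=False)
        values[miss, 1] = nan
        data = ResponseData(values)
        out = impute.impute_log(data)
        np.testing.assert_array_equal(
            out.data.values[miss, 1], data.values[miss, 0]
        )

    def test_strongly_related_item_predicts_fills(self):
        # fills for an item driven by one covariate agree with that covariate
        cfg = SimulationConfig(n_persons=600, seed=78)
        complete, _, _, _ = simgen.simulate_incomplete(cfg, 0)
        values = complete.values.copy()
        rng = np.random.default_rng(4)
        flip = rng.random(600) < 0.05
        values[:, 4] = np.where(flip, 1 - values[:, 0], values[:, 0])
        miss = rng.choice(600, size=80, replace=False)
        values[miss, 4] = nan
        out = impute.impute_log(ResponseData(values))
        agree = (out.data.values[miss, 4] == values[miss, 0]).mean()
        assert agree > 0.9


class TestMOK:
    @pytest.fixture()
    def mok_data(self):
        # base rows force item order 1 (easiest) .. 5 (hardest)
        base = np.zeros((12, 5))
        for j, k in enumerate((12, 10, 8, 6, 4)):
            base[:k, j] = 1.0
        probes = np.array([
            [1, nan, 1, 0, 0],    # (a): positive at a harder position -> 1
            [1, 0, nan, 0, 0],    # (b): negative at an easier position -> 0
            [0, 1, 1, nan, nan],  # (b) for both cells (negative at easiest)
            [1, 1, nan, nan, nan],  # only 2 observed: ineligible
            [nan, 1, 1, 1, nan],  # pos 1 -> (a); pos 5 -> (d)
            [1, nan, 0, 0, 0],    # (e): random draw
        ], dtype=float)
        return ResponseData(np.vstack([base, probes]))

    def test_rule_traces(self, mok_data):
        out = impute.impute_mok(mok_data, rng=np.random.default_rng(11))
        v = out.data.values
        assert v[12, 1] == 1.0            # rule (a)
        assert v[13, 2] == 0.0            # rule (b)
        assert v[14, 3] == 0.0 and v[14, 4] == 0.0
        assert np.isnan(v[15, 2:]).all()  # ineligible row untouched
        assert v[16, 0] == 1.0            # rule (a)
        assert v[16, 4] == 1.0            # rule (d)

    def test_random_rule_uses_item_rate(self, mok_data):
        # rule (e) cell: empirical fill rate over reruns near the item rate
        fills = []
        for s in range(400):
            out = impute.impute_mok(mok_data, rng=np.random.default_rng(s))
            fills.append(out.data.values[17, 1])
        rate = np.mean(fills)
        # item2 observed positive proportion in the fixture
        expected = mok_data.item_positive[1] / mok_data.item_observed[1]
        assert abs(rate - expected) < 0.08


class TestRasch:
    def test_fill_probabilities_match_formula(self, incomplete_rasch):
        prob, fit, persons = impute.rasch_fill_probabilities(
            incomplete_rasch, estimator="wle"
        )
        oracle = expit(persons.theta_hat[:, None] - fit.delta_hat[None, :])
        np.testing.assert_allclose(prob, oracle, atol=1e-12)
        out = impute.impute_rasch(incomplete_rasch, estimator="wle")
        cells = out.imputed_mask.astype(bool)
        np.testing.assert_array_equal(
            out.data.values[cells], (out.probabilities[cells] >= 0.5).astype(float)
        )

    def test_low_scorer_fills_zero_on_hard_items(self):
        cfg = SimulationConfig(n_persons=300, seed=88, pi=0.2)
        _, incomplete, _, _ = simgen.simulate_incomplete(cfg, 0)
        out = impute.impute_rasch(incomplete)
        scores = incomplete.person_scores
        lows = (scores == 0) & (incomplete.person_observed >= 3)
        cells = out.imputed_mask.astype(bool) & lows[:, None]
        # hardest item fills for zero-scorers are all 0
        assert cells[:, 4].sum() == 0 or (out.data.values[cells[:, 4], 4] == 0).all()

    def test_iterative_stops_and_matches_replay(self):
        cfg = SimulationConfig(n_persons=100, seed=89, pi=0.3)
        _, incomplete, _, _ = simgen.simulate_incomplete(cfg, 0)
        out = impute.impute_rasch_iterative(incomplete)
        assert out.n_iterations <= 10
        # independent replay of the fit/fill loop
        first = impute.impute_rasch(incomplete)
        cells = first.imputed_mask.astype(bool)
        current = first.data.values.copy()
        for _ in range(9):
            fit = rasch_mml.fit_mml(ResponseData(current))
            pers = rasch_mml.estimate_persons(fit, ResponseData(current), "eap")
            p = expit(pers.theta_hat[:, None] - fit.delta_hat[None, :])
            new = current.copy()
            new[cells] = (p[cells] >= 0.5).astype(float)
            if np.array_equal(np.nan_to_num(new, nan=-9), np.nan_to_num(current, nan=-9)):
                break
            current = new
        np.testing.assert_array_equal(
            np.nan_to_num(out.data.values, nan=-9), np.nan_to_num(current, nan=-9)
        )


class TestListwise:
    def test_complete_data_identity(self, bank):
        lat = simgen.draw_latents(30, rho=0.0, seed=90)
        data = simgen.simulate_responses(lat, bank, seed=91)
        out = impute.listwise_delete(data)
        np.testing.assert_array_equal(out.values, data.values)

    def test_empty_result_rejected(self):
        data = ResponseData(np.array([[1, nan], [nan, 0]], dtype=float))
        with pytest.raises(impute.ImputationError, match="empty"):
            impute.listwise_delete(data)

    def test_mcar_retention_matches_quadrature_oracle(self, bank):
        cfg = SimulationConfig(n_persons=100_000, seed=92, pi=0.3)
        _, incomplete, _, _ = simgen.simulate_incomplete(cfg, 0)
        retained = impute.listwise_delete(incomplete).n_persons
        z, w = hermgauss(201)
        xi = np.sqrt(2.0) * z
        pn = np.clip(0.3 * (1 + 0.4 * xi), 0.01, 1.0)
        expected = 100_000 * float(np.sum(w * (1 - pn) ** 5) / np.sqrt(np.pi))
        assert abs(retained - expected) / expected < 0.02
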