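"""Round chaining, panel construction, signature normalization and the
affinity/expression sensitivity scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ilama.mass_action import (
    AVOGADRO,
    CellInput,
    InvalidParameterError,
    ReceptorProfile,
    RecoveryFactors,
)
from ilama.simulate import (
    PPM,
    CloneModel,
    DegenerateRoundError,
    SelectionProtocol,
    SelectionRoundParams,
    Trajectory,
    build_panel,
    initial_copies,
    predict_signatures,
    sensitivity_scan,
    simulate_protocol,
)
from tests.test_mass_action import bisection_bound


class TestInitialCopies:
    def test_library_copy_number_times_display_level(self):
        assert initial_copies(2000, 0.10) == 200.0
        assert initial_copies(2000, 1.0) == 2000.0
        assert initial_copies(1, 0.5) == 0.5

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            initial_copies(0, 0.1)
        with pytest.raises(InvalidParameterError):
            initial_copies(2000, 0.0)
        with pytest.raises(InvalidParameterError):
            initial_copies(2000, 1.5)


class TestSimulateProtocol:
    def test_amplification_chains_rounds(self, protocol_with):
        clone = CloneModel("c", 1e-8, ReceptorProfile("r", 1e6, 0.0))
        traj = simulate_protocol(clone, protocol_with)
        assert traj.input_copies[0] == protocol_with.initial_copies
        for r in range(protocol_with.n_rounds - 1):
            amp = protocol_with.rounds[r].amplification_into_next
            assert traj.input_copies[r + 1] == pytest.approx(traj.recovered[r] * amp)

    def test_absent_receptor_recovers_nothing(self, protocol_with):
        clone = CloneModel("c", 1e-8, ReceptorProfile("r", 0.0, 0.0))
        traj = simulate_protocol(clone, protocol_with)
        assert all(x == 0.0 for x in traj.recovered)

    def test_higher_affinity_dominates_every_round(self, protocol_with):
        r = ReceptorProfile("r", 1e5, 0.0)
        tight = simulate_protocol(CloneModel("t", 1e-9, r), protocol_with)
        loose = simulate_protocol(CloneModel("l", 1e-7, r), protocol_with)
        assert all(a >= b for a, b in zip(tight.recovered, loose.recovered))
        assert tight.recovered[-1] > loose.recovered[-1]

    def test_truncating_then_readding_final_round_reproduces_trajectory(self, protocol_with):
        clone = CloneModel("c", 1e-8, ReceptorProfile("r", 3e5, 3e4))
        full = simulate_protocol(clone, protocol_with)
        head = simulate_protocol(clone, protocol_with.truncated(3))
        assert full.input_copies[:3] == head.input_copies
        assert full.recovered[:3] == head.recovered

    def test_matches_independent_round_by_round_reimplementation(self, protocol_with):
        # independent oracle: explicit loop over the equilibrium balance
        clone = CloneModel("c", 1e-8, ReceptorProfile("r", 3e5, 3e4))
        a = protocol_with.initial_copies
        expected = []
        for rnd in protocol_with.rounds:
            bt = 3e5 * rnd.cells.n_target
            bn = 3e4 * rnd.cells.n_nontarget
            bound = bisection_bound(a, bt + bn, 1e-8, rnd.volume)
            r_at = bound * bt / (bt + bn) * rnd.recovery.elution * rnd.recovery.cell_recovery
            expected.append(r_at)
            a = r_at * rnd.amplification_into_next
        got = simulate_protocol(clone, protocol_with)
        assert got.recovered == pytest.approx(expected, rel=1e-9)


class TestBuildPanel:
    def test_five_fold_grid_with_capped_top_level(self):
        panel = build_panel(5e3, 1e6, 5.0, [None])
        levels = [p.copies_target for p in panel]
        assert levels == [5e3, 2.5e4, 1.25e5, 6.25e5, 1e6]
        assert all(p.copies_nontarget == 0.0 for p in panel)

    def test_degenerate_single_level(self):
        panel = build_panel(7e4, 7e4, 5.0, [None])
        assert len(panel) == 1 and panel[0].copies_target == 7e4

    def test_size_is_levels_times_categories(self):
        panel = build_panel(5e3, 4e6, 5.0, [None, 2.0, 4.0, 10.0])
        assert len(panel) == 6 * 4

    def test_upregulation_ratio_sets_nontarget_copies(self):
        panel = build_panel(1e5, 1e5, 5.0, [10.0])
        assert panel[0].copies_nontarget == pytest.approx(1e4)

    def test_empty_category_spec_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_panel(5e3, 1e6, 5.0, [])


class TestPredictSignatures:
    def _traj(self, clone_id, recovered):
        n = len(recovered)
        return Trajectory(clone_id, tuple([1.0] * n), tuple(recovered))

    def test_single_member_full_hit_rate_gets_all_mass(self):
        sigs = predict_signatures([self._traj("a", [3.0, 7.0])], [1.0, 1.0])
        assert sigs[0].frequencies_ppm == (PPM, PPM)

    def test_equal_members_split_hit_rate(self):
        sigs = predict_signatures(
            [self._traj("a", [4.0]), self._traj("b", [4.0])], [0.5])
        assert sigs[0].frequencies_ppm == (250_000.0,)
        assert sigs[1].frequencies_ppm == (250_000.0,)

    def test_degenerate_round_raises(self):
        with pytest.raises(DegenerateRoundError):
            predict_signatures([self._traj("a", [1.0, 0.0])], [1.0, 1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        rec=st.lists(
            st.lists(st.floats(0.01, 1e9), min_size=3, max_size=3),
            min_size=1, max_size=8),
        hrs=st.lists(st.floats(0.001, 1.0), min_size=3, max_size=3),
    )
    def test_panel_frequencies_sum_to_hit_rate_each_round(self, rec, hrs):
        trajs = [self._traj(str(i), r) for i, r in enumerate(rec)]
        sigs = predict_signatures(trajs, hrs)
        for r in range(3):
            total = sum(s.frequencies_ppm[r] for s in sigs)
            assert total == pytest.approx(hrs[r] * PPM, rel=1e-12)

    def test_full_default_run_matches_oracle_recomputation(self, protocol_with, panel):
        trajs = [simulate_protocol(CloneModel(p.name, 1e-8, p), protocol_with)
                 for p in panel]
        sigs = predict_signatures(trajs, protocol_with.hit_rates)
        # independent recomputation of the frequency normalization
        rec = np.array([t.recovered for t in trajs])
        want = rec / rec.sum(axis=0, keepdims=True) * np.array(protocol_with.hit_rates) * PPM
        got = np.array([s.frequencies_ppm for s in sigs])
        assert np.allclose(got, want, rtol=1e-12)


class TestCompetitionContrast:
    def test_upregulated_suppressed_and_restricted_favored_by_competition(
            self, protocol_with, protocol_without, panel):
        """Competition lowers the round-4 frequency of a 10x-upregulated
        3e5-copy binder but raises that of a restricted 1e4-copy binder."""
        extra = [ReceptorProfile("up10x_probe", 3e5, 3e4),
                 ReceptorProfile("restricted_probe", 1e4, 0.0)]
        out = {}
        for proto in (protocol_with, protocol_without):
            trajs = [simulate_protocol(CloneModel(p.name, 1e-8, p), proto)
                     for p in [*panel, *extra]]
            sigs = predict_signatures(trajs, proto.hit_rates, proto.arm)
            out[proto.arm] = {s.clone_id: s.frequencies_ppm for s in sigs}
        up_with = out["with_competition"]["up10x_probe"][3]
        up_without = out["without_competition"]["up10x_probe"][3]
        lo_with = out["with_competition"]["restricted_probe"][3]
        lo_without = out["without_competition"]["restricted_probe"][3]
        assert up_with < up_without
        assert lo_with >= lo_without


@pytest.fixture(scope="module")
def scan(protocol_with, panel):
    clone = CloneModel("probe", 1e-8, ReceptorProfile("up10x", 3e5, 3e4))
    return sensitivity_scan(clone, protocol_with, panel)


class TestSensitivityScan:
    def _freqs(self, df, kf, ef):
        sel = df[(df.kd_factor == kf) & (df.expression_factor == ef)]
        return sel.sort_values("round")["frequency_ppm"].to_numpy()

    def test_identity_factors_reproduce_base_signature(self, scan, protocol_with, panel):
        clone = CloneModel("probe", 1e-8, ReceptorProfile("up10x", 3e5, 3e4))
        trajs = [simulate_protocol(CloneModel(p.name, 1e-8, p), protocol_with)
                 for p in panel]
        trajs.append(simulate_protocol(clone, protocol_with))
        base = predict_signatures(trajs, protocol_with.hit_rates)[-1].frequencies_ppm
        assert self._freqs(scan, 1.0, 1.0) == pytest.approx(base, rel=1e-12)

    def test_frequency_increases_with_affinity(self, scan):
        tight = self._freqs(scan, 0.1, 1.0)
        base = self._freqs(scan, 1.0, 1.0)
        loose = self._freqs(scan, 10.0, 1.0)
        assert np.all(tight >= base) and np.all(base >= loose)

    def test_expression_error_hits_upregulated_harder_than_restricted(
            self, protocol_with, panel):
        def rel_l1(clone):
            df = sensitivity_scan(clone, protocol_with, panel)
            base = self._freqs(df, 1.0, 1.0)
            var = self._freqs(df, 1.0, 2.0)
            return np.abs(var - base).sum() / base.sum()

        up = CloneModel("u", 1e-8, ReceptorProfile("up10x", 3e5, 3e4))
        restr = CloneModel("r", 1e-8, ReceptorProfile("restr", 1e6, 0.0))
        assert rel_l1(up) > rel_l1(restr)
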