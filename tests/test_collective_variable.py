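"""Switching function, reference modes and CV time series."""

import math

import numpy as np
import pytest

from foldcv.collective_variable import (
    HELICALITY,
    SegmentDefinition,
    SwitchingParams,
    cv_timeseries,
    ideal_motif_table,
    make_reference,
    rcs_rel,
    scs_rel,
)
from foldcv.errors import SegmentError
from foldcv.fixtures import (
    EXTENDED_STATE,
    HELIX_STATE,
    StateParams,
    dihedral_records,
    two_state_cv_trajectory,
)
from foldcv.folding_degree import rcs_block, rcs_profile, rcs_profile_from_records


class TestSwitchingParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"rcs_tol": 0.0},
            {"rcs_tol": -1.0},
            {"m": 3, "n": 4},
            {"m": 2, "n": 5},
            {"m": 4, "n": 2},
            {"m": 2, "n": 2},
            {"m": 0, "n": 4},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            SwitchingParams(**kw)

    def test_defaults_are_helicality_preset(self):
        assert HELICALITY.rcs_ref == 7.273
        assert HELICALITY.rcs_tol == 0.421
        assert (HELICALITY.m, HELICALITY.n) == (2, 4)


class TestRcsRel:
    def test_maximum_at_reference(self):
        assert rcs_rel(7.273) == 1.0

    def test_value_at_tolerance_is_limit(self):
        """|x| = 1 is a removable singularity with limit m/n = 0.5."""
        assert rcs_rel(7.273 + 0.421) == pytest.approx(0.5, abs=1e-12)
        assert rcs_rel(7.273 - 0.421) == pytest.approx(0.5, abs=1e-12)

    def test_published_worked_examples(self):
        # pi-helix mean under the helicality reference
        assert round(rcs_rel(6.516), 2) == 0.24
        # 3-10 helix mean
        assert round(rcs_rel(7.523), 2) == 0.74

    def test_simplification_identity(self):
        """(1-x^2)/(1-x^4) == 1/(1+x^2), continuous through |x|=1."""
        x = np.linspace(-3, 3, 1201)
        x = x[np.abs(np.abs(x) - 1) > 1e-4]
        rcs = 7.273 + 0.421 * x
        fast = rcs_rel(rcs)  # m=2, n=4 shortcut
        explicit = (1 - x**2) / (1 - x**4)
        assert np.max(np.abs(fast - explicit)) < 1e-12
        # continuity through the removable singularity
        for eps in (1e-9, -1e-9):
            assert rcs_rel(7.273 + 0.421 * (1 + eps)) == pytest.approx(0.5, abs=1e-8)
        # general-path limit at |x|=1 for other exponents
        assert rcs_rel(7.273 + 0.421, SwitchingParams(m=2, n=6)) == pytest.approx(1 / 3)

    def test_range_and_monotonicity(self):
        rcs = np.linspace(-5, 20, 2001)
        v = rcs_rel(rcs)
        assert np.all(v > 0) and np.all(v <= 1)
        x = np.abs((rcs - 7.273) / 0.421)
        order = np.argsort(x)
        assert np.all(np.diff(v[order]) <= 1e-15)

    def test_larger_tolerance_raises_value(self):
        """A looser tolerance gives a broader, pointwise larger switch."""
        for rcs in (5.0, 6.9, 7.5, 9.0):
            narrow = rcs_rel(rcs, SwitchingParams(rcs_tol=0.421))
            wide = rcs_rel(rcs, SwitchingParams(rcs_tol=1.0))
            assert wide > narrow


class TestIdealMotifs:
    def test_helix_reference_is_exactly_one(self):
        table = ideal_motif_table()
        assert table["H"] == 1.0

    def test_values_bounded(self):
        table = ideal_motif_table()
        assert ((table > 0) & (table <= 1)).all()
        # helical/turn categories score high, extended ones near zero
        assert table["G"] > 0.5 and table["T"] > 0.5
        assert table["E"] < 0.05 and table["P"] < 0.05


def profile_with(rcs_values, start_resnum=1):
    """Minimal profile carrying given RCS values."""
    from foldcv.folding_degree import FoldingProfile

    n = len(rcs_values)
    return FoldingProfile(
        resnums=np.arange(start_resnum, start_resnum + n),
        resnames=["ALA"] * n,
        rcs=np.asarray(rcs_values, dtype=float),
        method="block",
        chain_id="A",
    )


class TestScsRel:
    def test_mean_of_two(self):
        # choose RCS giving rcs_rel 0.2 and 0.8: x = sqrt(1/v - 1)
        r = [7.273 + 0.421 * math.sqrt(1 / v - 1) for v in (0.2, 0.8)]
        prof = profile_with(r)
        seg = SegmentDefinition("s", "A", 1, 2)
        assert scs_rel(prof, seg) == pytest.approx(0.5, abs=1e-12)

    def test_uniform_segment_equals_residue_value(self):
        prof = profile_with([6.923] * 5)
        seg = SegmentDefinition("s", "A", 1, 5)
        assert round(scs_rel(prof, seg), 2) == 0.59  # ideal turn motif

    def test_undefined_rcs_raises(self):
        prof = profile_with([7.0, math.nan, 7.0])
        with pytest.raises(SegmentError):
            scs_rel(prof, SegmentDefinition("s", "A", 1, 3))

    def test_missing_residue_raises(self):
        prof = profile_with([7.0, 7.0])
        with pytest.raises(SegmentError):
            scs_rel(prof, SegmentDefinition("s", "A", 1, 5))

    def test_per_residue_params_length_checked(self):
        prof = profile_with([7.0, 7.0, 7.0])
        with pytest.raises(SegmentError):
            scs_rel(prof, SegmentDefinition("s", "A", 1, 3), [HELICALITY] * 2)


class TestMakeReference:
    def test_segment_mean_shares_one_reference(self):
        prof = profile_with([7.0, 7.2, 7.4, 7.6])
        seg = SegmentDefinition("s", "A", 1, 4)
        params = make_reference("segment_mean", seg, reference_profile=prof)
        assert len(params) == 4
        refs = [p.rcs_ref for p in params]
        assert refs == pytest.approx([7.3] * 4)
        assert all(p.rcs_tol == 1.0 for p in params)

    def test_per_residue_reference_scores_one_on_itself(self):
        rcs = [7.1, 6.2, 3.3, 5.4]
        prof = profile_with(rcs)
        seg = SegmentDefinition("s", "A", 1, 4)
        params = make_reference("per_residue", seg, reference_profile=prof)
        assert scs_rel(prof, seg, params) == pytest.approx(1.0)

    def test_category_mode_uses_table(self):
        seg = SegmentDefinition("s", "A", 1, 2)
        params = make_reference(
            "category", seg, labels={1: "H", 2: "E"}, use_category_sd=True
        )
        assert params[0].rcs_ref == 7.273 and params[0].rcs_tol == 0.421
        assert params[1].rcs_ref == 2.730 and params[1].rcs_tol == 0.966

    def test_category_mode_fixed_tolerance(self):
        seg = SegmentDefinition("s", "A", 1, 1)
        (p,) = make_reference("category", seg, labels={1: "T"}, tol=0.7)
        assert p.rcs_tol == 0.7

    def test_category_mode_requires_labels(self):
        seg = SegmentDefinition("s", "A", 1, 2)
        with pytest.raises(SegmentError):
            make_reference("category", seg)
        with pytest.raises(SegmentError):
            make_reference("category", seg, labels={1: "H"})

    def test_undefined_reference_rcs_raises(self):
        prof = profile_with([math.nan, 7.0])
        seg = SegmentDefinition("s", "A", 1, 2)
        with pytest.raises(SegmentError):
            make_reference("per_residue", seg, reference_profile=prof)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            make_reference("nearest", SegmentDefinition("s", "A", 1, 2))


def state_expected_scs(state, n_draws=4000, seed=1):
    """Independent oracle: E[rcs_rel] of one residue under a state's noise.

    Draws every dihedral entering the local window iid from the state's
    Gaussian distribution, mirroring how trajectory frames are sampled; by
    the law of large numbers a segment-mean SCS concentrates at this value.
    """
    rng = np.random.default_rng(seed)

    def draw(mean, sd, n):
        return rng.normal(mean, sd, n)

    n = n_draws
    vals = np.empty(n)
    psi_prev = draw(state.psi_mean, state.psi_sd, n)
    om_prev = draw(state.omega_mean, state.omega_sd, n)
    phi = draw(state.phi_mean, state.phi_sd, n)
    psi = draw(state.psi_mean, state.psi_sd, n)
    om_next = draw(state.omega_mean, state.omega_sd, n)
    phi_next = draw(state.phi_mean, state.phi_sd, n)
    for i in range(n):
        rcs = rcs_block(
            phi[i], psi[i], om_prev[i], om_next[i],
            psi_prev=psi_prev[i], phi_next=phi_next[i],
        )
        vals[i] = rcs_rel(rcs)
    return float(vals.mean())


class TestCvTimeseries:
    def test_reference_trajectory_scores_constant_one(self):
        recs = dihedral_records([0, -57, -57, -57, 0], [-47, -47, -47, 0, 0], [180.0] * 5)
        prof = rcs_profile_from_records(recs, "block")
        seg = SegmentDefinition("s", "", 2, 4)
        params = make_reference("per_residue", seg, reference_profile=prof)
        series = cv_timeseries([recs] * 4, [seg], {"s": params})
        assert np.allclose(series.values["s"], 1.0)
        assert not series.flagged.any().any()

    def test_single_frame(self):
        frames, _ = two_state_cv_trajectory(1, seed=4)
        seg = SegmentDefinition("s", "", 2, 11)
        series = cv_timeseries(frames, [seg], {"s": HELICALITY})
        assert len(series) == 1

    def test_terminal_segment_flagged(self):
        frames, _ = two_state_cv_trajectory(3, seed=4)
        seg = SegmentDefinition("s", "", 1, 5)  # residue 1 has no RCS
        series = cv_timeseries(frames, [seg], {"s": HELICALITY})
        assert series.flagged["s"].all()
        assert series.values["s"].isna().all()

    def test_missing_reference_rejected(self):
        frames, _ = two_state_cv_trajectory(1, seed=4)
        seg = SegmentDefinition("s", "", 2, 11)
        with pytest.raises(SegmentError):
            cv_timeseries(frames, [seg], {})

    def test_two_state_trajectory_is_bimodal(self):
        """SCS histogram shows two modes at the states' theoretical values."""
        state_a = StateParams(-64.70, -39.56, 5.0, 5.0)
        state_b = StateParams(-110.89, 122.38, 5.0, 5.0)
        frames, states = two_state_cv_trajectory(
            400, state_a=state_a, state_b=state_b,
            switch_prob=0.1, n_res=12, seed=99,
        )
        seg = SegmentDefinition("s", "", 2, 11)
        series = cv_timeseries(frames, [seg], {"s": HELICALITY})
        v = series.values["s"].to_numpy()
        th_a = state_expected_scs(state_a)
        th_b = state_expected_scs(state_b)
        assert (states == 0).any() and (states == 1).any()
        assert abs(v[states == 0].mean() - th_a) < 0.05
        assert abs(v[states == 1].mean() - th_b) < 0.05
        # well-separated modes -> the midpoint region is sparsely populated
        mid = (th_a + th_b) / 2
        assert np.mean(np.abs(v - mid) < 0.05) < 0.05

    def test_library_and_chain_frames_agree(self, helix_chain):
        seg = SegmentDefinition("s", "A", 3, 10)
        series = cv_timeseries([helix_chain], [seg], {"s": HELICALITY})
        prof = rcs_profile(helix_chain, "block")
        assert series.values.loc[0, "s"] == pytest.approx(
            scs_rel(prof, seg, HELICALITY)
        )
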