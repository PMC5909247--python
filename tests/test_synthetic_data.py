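"""Oddball session generator: trial sequences, behavior, forward-modelled EEG."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oddball_stda.forward_model import build_source_grid, compute_leadfield
from oddball_stda.synthetic_data import (
    ComponentSpec,
    InvalidConfigError,
    NoiseModel,
    ParadigmConfig,
    component_topography,
    default_components,
    generate_trial_sequence,
    simulate_behavior,
    simulate_epochs,
    synthesize_session,
    tangentialize,
)

QUIET = NoiseModel(sensor_white_sd_uV=0.0, background_n_dipoles=0,
                   background_sd_nAm=0.0)


def small_cfg(**kw):
    defaults = dict(n_trials=20, n_deviants=5, isi_ms=950.0)
    defaults.update(kw)
    return ParadigmConfig(**defaults)


class TestTrialSequence:
    def test_study_counts(self):
        seq = generate_trial_sequence(ParadigmConfig(), seed=0)
        assert len(seq) == 400
        assert np.sum(seq == "deviant") == 75
        assert np.sum(seq == "standard") == 325

    def test_zero_deviants_all_standard(self):
        seq = generate_trial_sequence(small_cfg(n_trials=10, n_deviants=0), 3)
        assert np.all(seq == "standard")

    def test_spacing_constraint_bruteforce(self):
        """With 6 trials, 2 deviants, min spacing 2, every emitted sequence
        is one of the brute-force-enumerated admissible placements."""
        cfg = small_cfg(n_trials=6, n_deviants=2, min_deviant_spacing=2)
        admissible = set()
        for a, b in itertools.combinations(range(6), 2):
            if b - a >= 3:  # 2 intervening standards
                admissible.add((a, b))
        seen = set()
        for seed in range(300):
            seq = generate_trial_sequence(cfg, seed)
            pos = tuple(np.flatnonzero(seq == "deviant"))
            assert pos in admissible
            seen.add(pos)
        assert seen == admissible  # all placements reachable

    def test_no_adjacent_deviants_at_default_spacing(self):
        for seed in range(20):
            seq = generate_trial_sequence(ParadigmConfig(), seed)
            dev = seq == "deviant"
            assert not np.any(dev[:-1] & dev[1:])

    def test_deterministic_under_seed(self):
        a = generate_trial_sequence(ParadigmConfig(), 7)
        b = generate_trial_sequence(ParadigmConfig(), 7)
        assert np.array_equal(a, b)

    def test_too_many_deviants_rejected(self):
        with pytest.raises(InvalidConfigError):
            ParadigmConfig(n_trials=10, n_deviants=11)

    @given(st.integers(2, 30), st.integers(0, 8), st.integers(0, 2),
           st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_counts_always_exact(self, n, k, s, seed):
        if k > n or (k > 0 and n - (k - 1) * s < k):
            return
        seq = generate_trial_sequence(
            small_cfg(n_trials=n, n_deviants=k, min_deviant_spacing=s), seed)
        assert np.sum(seq == "deviant") == k


class TestBehavior:
    def test_mc_mean_matches_truncated_normal_oracle(self):
        cfg = ParadigmConfig(n_trials=10000, n_deviants=10000,
                             min_deviant_spacing=0)
        res = simulate_behavior(cfg, seed=0)
        a = (223 - 285.6) / 38.5
        b = (379 - 285.6) / 38.5
        oracle_mean = stats.truncnorm.mean(a, b, loc=285.6, scale=38.5)
        assert abs(res.rt_ms.mean() - oracle_mean) < 1.0

    def test_zero_sd_gives_constant_rts(self):
        res = simulate_behavior(ParadigmConfig(), seed=1, rt_sd_ms=0.0)
        assert np.all(res.rt_ms == 285.6)

    def test_rts_never_leave_bounds(self):
        cfg = ParadigmConfig(n_trials=5000, n_deviants=5000,
                             min_deviant_spacing=0)
        res = simulate_behavior(cfg, seed=2)
        assert res.rt_ms.min() >= 223.0 and res.rt_ms.max() <= 379.0

    def test_one_record_per_deviant(self):
        res = simulate_behavior(ParadigmConfig(), seed=3)
        assert len(res.rt_ms) == 75 == len(res.trial_indices)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_behavior(ParadigmConfig(), 0, rt_bounds_ms=(300.0, 280.0))


class TestComponents:
    def test_amplitude_map_must_cover_all_cells(self):
        with pytest.raises(InvalidConfigError):
            ComponentSpec("N1", 95, 15, (5, 0, 3),
                          tangentialize((5, 0, 3), (0, 0, -1)),
                          {("deviant", "passive"): 1.0})

    def test_orientation_must_be_unit(self):
        with pytest.raises(InvalidConfigError):
            ComponentSpec("N1", 95, 15, (5, 0, 3), (0, 0, -2),
                          {(c, t): 0.0 for c in ("standard", "deviant")
                           for t in ("passive", "active")})

    def test_source_outside_space_rejected(self, montage, leadfield_car):
        comp = default_components()[0]
        bad = ComponentSpec("N1", 95, 15, (9.0, 0.0, 0.0), comp.orientation,
                            comp.amplitude)
        with pytest.raises(InvalidConfigError):
            component_topography(bad, montage, leadfield_car)

    def test_topography_equals_leadfield_column_on_voxel(self, montage,
                                                         leadfield_car):
        grid = leadfield_car.grid
        v = grid.nearest_voxel((5.0, 1.0, 3.0))
        pos = tuple(grid.positions[v])
        ori = tangentialize(pos, (0.0, 0.0, -1.0))
        comp = ComponentSpec("MMN", 100, 18, pos, ori,
                             {(c, t): 1.0 for c in ("standard", "deviant")
                              for t in ("passive", "active")})
        topo = component_topography(comp, montage, leadfield_car)
        np.testing.assert_allclose(topo, leadfield_car.column(v, ori),
                                   atol=1e-12)


class TestSessionSynthesis:
    def test_zero_noise_no_components_all_zero(self, montage, leadfield_car):
        cfg = small_cfg()
        out = synthesize_session(cfg, [], QUIET, montage, leadfield_car,
                                 n_subjects=1, seed=0, srate_hz=512.0)
        assert len(out) == 2  # one per task
        for _, _, data, events in out:
            assert np.all(data == 0)
            assert len(events) == cfg.n_trials

    def test_forward_model_is_linear_in_amplitude(self, montage, leadfield_car):
        cfg = small_cfg()
        comp = default_components()[1]  # MMN
        double = ComponentSpec(comp.name, comp.peak_latency_ms,
                               comp.temporal_sd_ms, comp.source_position,
                               comp.orientation,
                               {k: 2 * v for k, v in comp.amplitude.items()})
        kw = dict(n_subjects=1, seed=0, srate_hz=512.0, subject_gain_sd=0.0)
        a = synthesize_session(cfg, [comp], QUIET, montage, leadfield_car, **kw)
        b = synthesize_session(cfg, [double], QUIET, montage, leadfield_car, **kw)
        for (_, _, da, _), (_, _, db, _) in zip(a, b):
            np.testing.assert_allclose(db, 2 * da, atol=1e-12)

    def test_mmn_only_topography_collinear_with_leadfield_column(
            self, montage, leadfield_car):
        """Deviant-minus-standard average at the peak latency reproduces the
        implanted source's lead-field topography (zero noise)."""
        grid = leadfield_car.grid
        v = grid.nearest_voxel((5.0, 1.0, 3.0))
        pos = tuple(grid.positions[v])
        ori = tangentialize(pos, (0.0, 0.0, -1.0))
        comp = ComponentSpec("MMN", 100, 18, pos, ori,
                             {("standard", "passive"): 0.0,
                              ("standard", "active"): 0.0,
                              ("deviant", "passive"): 25.0,
                              ("deviant", "active"): 25.0})
        cfg = small_cfg(n_trials=12, n_deviants=3)
        ep = simulate_epochs(cfg, [comp], QUIET, montage, leadfield_car,
                             "passive", "S00", np.ones(1), seed=0)
        dev = ep.data[ep.conditions == "deviant"].mean(axis=0)
        std = ep.data[ep.conditions == "standard"].mean(axis=0)
        diff = dev - std
        k = np.argmin(np.abs(ep.times_ms - 100.0))
        col = leadfield_car.column(v, ori)
        r = np.corrcoef(diff[:, k], col)[0, 1]
        assert abs(r) > 0.999

    def test_label_bookkeeping_per_block(self, montage, leadfield_car):
        cfg = small_cfg(n_trials=30, n_deviants=6)
        for _, task, _, events in synthesize_session(
                cfg, [], QUIET, montage, leadfield_car, n_subjects=2, seed=4,
                srate_hz=512.0):
            assert (events["condition"] == "deviant").sum() == 6
            assert (events["condition"] == "standard").sum() == 24
            assert (events["task"] == task).all()

    def test_byte_identical_under_seed(self, montage, leadfield_car):
        cfg = small_cfg(n_trials=8, n_deviants=2)
        noise = NoiseModel(background_n_dipoles=20)
        kw = dict(n_subjects=1, seed=9, srate_hz=512.0)
        a = synthesize_session(cfg, default_components(), noise, montage,
                               leadfield_car, **kw)
        b = synthesize_session(cfg, default_components(), noise, montage,
                               leadfield_car, **kw)
        for (_, _, da, ea), (_, _, db, eb) in zip(a, b):
            assert np.array_equal(da, db)
            assert ea.equals(eb)

    def test_epoch_fast_path_baseline_and_labels(self, montage, leadfield_car):
        cfg = small_cfg(n_trials=10, n_deviants=2)
        ep = simulate_epochs(cfg, default_components(), NoiseModel(), montage,
                             leadfield_car, "active", "S01", np.ones(3), seed=1)
        assert ep.n_trials == 10
        assert np.sum(ep.conditions == "deviant") == 2
        bmask = ep.time_mask(-100.0, 0.0)
        base = ep.data[:, :, bmask].mean(axis=2)
        assert np.abs(base).max() < 1e-9
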