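import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitkit.events import extract_events
from gaitkit.params import parameters_from_events
from gaitkit.simulate import (
    AGE_GROUPS,
    GaitProfile,
    draw_profile,
    generate_cohort,
    generate_recording,
    generate_task_pair,
)
from gaitkit.types import EventKind

INFORMATIVE = ("Ax", "Ay", "Gy", "Gz", "Yaw", "Roll")
QUIET = ("Az", "Gx", "Pitch")


class TestGenerateRecording:
    def test_noise_free_construction(self, clean_recording):
        rec = clean_recording
        assert rec.n_samples == 360  # 6 cycles x 1.2 s x 50 Hz
        hs = [e for e in rec.true_events if e.kind == EventKind.HEEL_STRIKE]
        to = [e for e in rec.true_events if e.kind == EventKind.TOE_OFF]
        assert len(hs) == 6 and len(to) == 6
        assert hs[1].time_s - hs[0].time_s == pytest.approx(1.2)
        assert rec.stance_ref.mean() == pytest.approx(0.6, abs=0.01)

    def test_stance_phase_matches_reported_single_task_mean(self):
        # cadence/stance set to a published healthy-elderly mean: the phase
        # computed from the generated cycles must reproduce it
        profile = GaitProfile(cadence_spm=100.08, stance_fraction=0.6419,
                              n_cycles=6, noise_sd=0.0, seed=2)
        rec = generate_recording(profile)
        params = parameters_from_events(rec.true_events)
        assert params.stance_phase_pct == pytest.approx(64.19, abs=0.01)
        assert params.cadence_spm == pytest.approx(100.08, abs=0.01)

    def test_seeded_determinism_is_bitwise(self):
        profile = GaitProfile(seed=42)
        a, b = generate_recording(profile), generate_recording(profile)
        for name in a.channel_names:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])
        np.testing.assert_array_equal(a.stance_ref, b.stance_ref)

    def test_events_alternate_starting_with_heel_strike(self, noisy_recording):
        kinds = [e.kind for e in noisy_recording.true_events]
        assert kinds[0] == EventKind.HEEL_STRIKE
        assert all(k1 != k2 for k1, k2 in zip(kinds, kinds[1:]))
        times = [e.time_s for e in noisy_recording.true_events]
        assert times == sorted(times)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_stance_trace_reconstructs_true_events(self, seed):
        # the binary insole-style trace and the real-valued events must agree
        # to within one sample of quantization
        profile = GaitProfile(cadence_spm=105, lead_in_s=0.3, seed=seed,
                              asymmetry=0.02)
        rec = generate_recording(profile)
        recovered = extract_events(rec.stance_ref, rec.fs_hz)
        assert len(recovered) == len(rec.true_events)
        for got, want in zip(recovered, rec.true_events):
            assert got.kind == want.kind
            assert abs(got.time_s - want.time_s) <= 1.0 / rec.fs_hz

    def test_stance_fraction_converges_with_cycles(self):
        # quantization error is bounded by one sample per phase per cycle
        # and washes out as cycles accumulate
        short = generate_recording(GaitProfile(n_cycles=4, noise_sd=0.0, seed=3))
        long = generate_recording(GaitProfile(n_cycles=40, noise_sd=0.0, seed=3))
        per_cycle = 1.0 / (50.0 * 1.2)
        assert short.stance_ref.mean() == pytest.approx(0.6, abs=2 * per_cycle)
        assert long.stance_ref.mean() == pytest.approx(0.6, abs=0.002)

    @pytest.mark.parametrize("seed", range(5))
    def test_quiet_channels_have_small_variance(self, seed):
        rec = generate_recording(GaitProfile(seed=seed))
        informative_min = min(float(np.var(rec.channels[c])) for c in INFORMATIVE)
        for c in QUIET:
            assert float(np.var(rec.channels[c])) <= 0.1 * informative_min

    @given(
        cadence=st.floats(80, 130),
        stance_fraction=st.floats(0.45, 0.75),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_stance_mean_tracks_requested_fraction(self, cadence,
                                                   stance_fraction, seed):
        rec = generate_recording(
            GaitProfile(cadence_spm=cadence, stance_fraction=stance_fraction,
                        n_cycles=8, noise_sd=0.0, seed=seed)
        )
        # quantization error is at most one sample per phase per cycle
        tol = 2 * 8 / rec.n_samples
        assert rec.stance_ref.mean() == pytest.approx(stance_fraction, abs=tol)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cadence_spm": 0.0},
            {"cadence_spm": -50.0},
            {"stance_fraction": 0.0},
            {"stance_fraction": 1.0},
            {"n_cycles": 0},
            {"noise_sd": -0.1},
            {"speed_condition": "sprint"},
            {"task": "DTW"},
        ],
    )
    def test_invalid_profiles_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GaitProfile(**kwargs)


class TestGenerateCohort:
    def test_one_recording_per_subject_and_age_band(self):
        cohort = generate_cohort(6, seed=0)
        assert len(cohort) == 6
        assert sorted(r.meta["age_group"] for r in cohort) == sorted(AGE_GROUPS)

    def test_stratification_of_full_cohort(self):
        cohort = generate_cohort(150, seed=0)
        counts = {}
        for rec in cohort:
            counts[rec.meta["age_group"]] = counts.get(rec.meta["age_group"], 0) + 1
        assert counts == {g: 25 for g in AGE_GROUPS}

    def test_same_seed_reproduces_cohort(self):
        a = generate_cohort(5, seed=9)
        b = generate_cohort(5, seed=9)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.channels["Ay"], rb.channels["Ay"])

    def test_speed_conditions_multiply_recordings(self):
        cohort = generate_cohort(4, seed=1, speed_conditions=("normal", "low", "high"))
        assert len(cohort) == 12
        low = next(r for r in cohort if r.meta["speed_condition"] == "low")
        normal = next(r for r in cohort if r.meta["speed_condition"] == "normal")
        assert low.n_samples > normal.n_samples  # slower gait, longer trial

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(3, profile_ranges={"cadence_spm": (120.0, 100.0)}, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0)

    def test_task_pair_shares_subject_profiles(self):
        pair = generate_task_pair(4, tasks=("STW", "VFT"), seed=5)
        assert set(pair) == {"STW", "VFT"}
        for stw, vft in zip(pair["STW"], pair["VFT"]):
            assert stw.meta["subject_id"] == vft.meta["subject_id"]
            # dual task slows the same subject down
            assert vft.meta["cadence_spm"] < stw.meta["cadence_spm"]
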