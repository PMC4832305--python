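"""End-tracker tests: backbone refinement, proposal, state machine, wiring."""

import numpy as np
import pytest

from mttrack.lattice import GrowthParams
from mttrack.track import (
    TrackState,
    TrackerConfig,
    _resample_polyline,
    axial_profile,
    build_mask,
    propose_end,
    refine_backbone,
    track_movie,
)
from tests.conftest import NOISELESS, make_movie, track_errors


def ridge_frame(shape=(40, 80), row=20.0, end_col=60.0, amp=100.0, bg=10.0):
    jj, ii = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    lateral = np.exp(-((ii - row) ** 2) / (2 * 1.2**2))
    axial = 1.0 / (1.0 + np.exp((jj - end_col) / 0.8))
    return bg + amp * lateral * axial


class TestRefineBackbone:
    def test_recovers_lateral_translation(self):
        frame = ridge_frame(row=22.0)
        backbone = np.column_stack([np.arange(5.0, 55.0), np.full(50, 20.0)])
        refined = refine_backbone(frame, backbone, search_halfwidth=3.0)
        # interior points move onto the displaced ridge (+-0.5 px)
        assert np.allclose(refined[10:-5, 1], 22.0, atol=0.5)

    def test_zero_halfwidth_is_identity(self):
        frame = ridge_frame()
        backbone = np.column_stack([np.arange(5.0, 55.0), np.full(50, 20.0)])
        refined = refine_backbone(frame, backbone, search_halfwidth=0.0)
        assert np.allclose(refined, _resample_polyline(backbone))

    def test_seed_end_stays_pinned(self):
        frame = ridge_frame(row=23.0)
        backbone = np.column_stack([np.arange(5.0, 55.0), np.full(50, 20.0)])
        refined = refine_backbone(frame, backbone, search_halfwidth=3.0)
        assert np.allclose(refined[0], backbone[0])


class TestAxialProfile:
    def test_horizontal_profile_matches_row_and_tail(self):
        frame = ridge_frame()
        backbone = np.column_stack([np.arange(5.0, 50.0), np.full(45, 20.0)])
        profile, arclens, pts = axial_profile(frame, backbone, n_extrapolate=25)
        assert len(profile) == len(backbone) + 25
        assert np.allclose(profile[: len(backbone)], frame[20, 5:50], rtol=1e-6)
        assert profile[-3:].mean() == pytest.approx(10.0, abs=1.0)

    def test_extrapolation_truncated_at_frame_edge(self):
        frame = ridge_frame()
        backbone = np.column_stack([np.arange(60.0, 78.0), np.full(18, 20.0)])
        profile, _, pts = axial_profile(frame, backbone, n_extrapolate=30)
        assert pts[:, 0].max() <= frame.shape[1] - 1


class TestProposeEnd:
    def cfg(self):
        return TrackerConfig()

    def make_profile(self, end_s=60.0, n=90, amp=100.0):
        s = np.arange(float(n))
        return amp / (1.0 + np.exp((s - end_s) / 0.8)), s

    def test_noiseless_proposal_lands_near_end(self):
        profile, s = self.make_profile(end_s=60.0)
        ts = TrackState(backbone=np.zeros((2, 2)))
        gp = GrowthParams(v_g=0, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1, exposure=1)
        idx, det, ts = propose_end(profile, s, 58.0, ts, gp, 120.0, 135.0,
                                   bg_mean=0.0, bg_sd=1.0, cfg=self.cfg())
        assert det
        assert abs(s[idx] - 60.0) <= 2.0

    def test_state_flips_once_after_k_switch_misses(self):
        profile = np.zeros(90)
        s = np.arange(90.0)
        ts = TrackState(backbone=np.zeros((2, 2)))
        gp = GrowthParams(v_g=10, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1, exposure=1)
        cfg = self.cfg()
        states = []
        for _ in range(cfg.k_switch + 2):
            _, det, ts = propose_end(profile, s, 45.0, ts, gp, 120.0, 135.0,
                                     bg_mean=10.0, bg_sd=1.0, cfg=cfg)
            assert not det
            states.append(ts.dyn_state)
        assert states[: cfg.k_switch - 1] == [1] * (cfg.k_switch - 1)
        assert states[cfg.k_switch - 1 :] == [-1] * 3  # flipped exactly once

    def test_refractory_period_blocks_rapid_flip_back(self):
        profile = np.zeros(90)
        s = np.arange(90.0)
        ts = TrackState(backbone=np.zeros((2, 2)))
        gp = GrowthParams(v_g=10, D_p=0, sigma_LD=0, taper_length=0,
                          frame_interval=1, exposure=1)
        cfg = self.cfg()
        flips = 0
        prev = ts.dyn_state
        for _ in range(cfg.k_switch + cfg.k_refractory - 1):
            _, _, ts = propose_end(profile, s, 45.0, ts, gp, 120.0, 135.0,
                                   bg_mean=10.0, bg_sd=1.0, cfg=cfg)
            if ts.dyn_state != prev:
                flips += 1
                prev = ts.dyn_state
        assert flips == 1  # second flip would violate the refractory period


class TestBuildMask:
    def test_straight_backbone_ribbon_width(self):
        backbone = np.column_stack([np.arange(5.0, 30.0), np.full(25, 10.0)])
        mask = build_mask((20, 40), backbone, end_arclen=24.0, dilation_radius=2)
        assert mask[10, 15]
        assert mask[8:13, 15].all()  # 5-px-wide ribbon
        assert not mask[10, 35]  # beyond the proposed end

    def test_gap_closed_and_connected(self):
        from scipy import ndimage

        backbone = np.column_stack([np.arange(5.0, 30.0), np.full(25, 10.0)])
        backbone = np.delete(backbone, 12, axis=0)  # 1-px gap
        mask = build_mask((20, 40), backbone, end_arclen=50.0, dilation_radius=2)
        _, n_components = ndimage.label(mask)
        assert n_components == 1

    def test_area_monotone_in_dilation_radius(self):
        backbone = np.column_stack([np.arange(5.0, 30.0), np.full(25, 10.0)])
        areas = [
            build_mask((20, 40), backbone, 24.0, r).sum() for r in (0, 1, 2, 3)
        ]
        assert all(a < b for a, b in zip(areas, areas[1:]))


class TestTrackMovie:
    def test_noiseless_growth_tracked_below_5nm(self, noiseless_movie):
        ex, ey, tracks = track_errors(noiseless_movie)
        assert tracks["reliability"].all()
        assert np.abs(ex).max() < 5.0
        assert np.abs(ey).max() < 5.0

    def test_fit_consumes_raw_counts_not_filtered(self, noisy_movie):
        # fitted background must sit at the raw detector level (offset +
        # background photons x gain), far from the Wallis-normalized scale
        _, _, tracks = track_errors(noisy_movie)
        ip = noisy_movie.ip
        expected_bg = ip.camera_offset + ip.background_photons * ip.gain
        med = tracks.loc[tracks.reliability, "background"].median()
        assert med == pytest.approx(expected_bg, rel=0.15)

    def test_transient_shrinkage_does_not_flip_state(self):
        # highly diffusive growth: brief losses happen but the dynamic
        # state stays polymerizing and the track follows reversals
        mv = make_movie(n_frames=50, seed=6, snr_target=3.0, v_g_nm_per_s=10,
                        d_p_nm2_per_s=300, sigma_ld_nm=0)
        ex, _, tracks = track_errors(mv)
        assert (tracks["dyn_state"] == "polymerizing").all()
        assert np.std(ex) < 60.0

    def test_output_has_one_row_per_frame(self, noisy_movie):
        _, _, tracks = track_errors(noisy_movie)
        assert len(tracks) == noisy_movie.frames.shape[0]
        assert list(tracks["frame"]) == list(range(len(tracks)))
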