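"""Movie rendering, spot detection, registration and trace extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from scfret import fretpop, imaging, simkit
from scfret.exceptions import DegenerateGeometryError, InvalidParameterError
from scfret.imaging import ChannelMap, detect_spots, extract_traces, register_channels
from scfret.simkit import (AcquisitionParams, KineticScheme, MovieGeometry,
                           PhotophysicsParams, StatePathTruth, place_molecules,
                           render_movie, render_traces)


def _static_traceset(n_mol, rng, e_means=(0.35, 0.62), total=2000.0,
                     n_green=10, noise_sd=0.0):
    """Static molecules of random class, noise-free traces."""
    sch = KineticScheme(["u", "w"], np.zeros((2, 2)),
                        list(e_means), [0.05, 0.05])
    phys = PhotophysicsParams(total_emission=total, background_mean=0.0,
                              noise_sd=noise_sd)
    acq = AcquisitionParams(0.05, (("green", n_green), ("red", 4)))
    paths = []
    for i in range(n_mol):
        p = StatePathTruth(i, duration=acq.duration, state_names=["u", "w"])
        p.events.append((int(rng.random() < 0.5), 0.0, acq.duration))
        paths.append(p)
    return render_traces(paths, sch, phys, acq, rng)


# ---------------------------------------------------------------- rendering

def test_empty_field_is_pure_background(rng):
    ts = _static_traceset(1, rng)
    ts.donor[:] = 0.0
    ts.acceptor[:] = 0.0
    geom = MovieGeometry(field_size=64)
    sd_, sa_, _ = render_movie(ts, geom, rng=1, background_mean=100,
                               noise_sd=10)
    se = 10 / np.sqrt(sd_[0].size)
    assert sd_[0].mean() == pytest.approx(100, abs=5 * se)


def test_single_spot_integral_matches_trace_value(rng):
    ts = _static_traceset(1, rng)
    geom = MovieGeometry(field_size=64)
    sd_, sa_, pos = render_movie(ts, geom, rng=2, background_mean=0,
                                 noise_sd=0)
    g = ts.green_frames[0]
    total = sd_[g].sum() + sa_[g].sum()
    expected = ts.donor[0, g] + ts.acceptor[0, g]
    assert total == pytest.approx(expected, rel=0.005)


def test_overcrowded_field_raises():
    with pytest.raises(InvalidParameterError):
        place_molecules(2000, MovieGeometry(field_size=64, min_separation=6),
                        rng=0)


# ---------------------------------------------------------------- detection

def test_constant_image_yields_no_spots():
    assert len(detect_spots(np.full((64, 64), 7.0))) == 0


def test_detection_recall_and_false_positives(rng):
    ts = _static_traceset(100, rng)
    geom = MovieGeometry(field_size=160)
    sd_, sa_, pos = render_movie(ts, geom, rng=3, background_mean=100,
                                 noise_sd=10)
    avg = sd_[ts.green_frames[:8]].mean(axis=0)
    spots = detect_spots(avg, threshold_sigmas=6, min_separation=4)
    d, idx = cKDTree(pos).query(spots[["x", "y"]].to_numpy())
    recall = len(set(idx[d < 2.0]))
    false_pos = int((d >= 2.0).sum())
    assert recall >= 95
    assert false_pos <= 5


def test_close_pair_never_kept_twice():
    img = np.zeros((64, 64))
    for x in (30.0, 31.0):
        from scfret.simkit.movie import _add_spot
        _add_spot(img, x, 32.0, 1000.0, 1.2)
    spots = detect_spots(img + 1e-3, threshold_sigmas=5, min_separation=3)
    assert len(spots) <= 1


def test_detection_monotone_in_threshold(rng):
    ts = _static_traceset(50, rng)
    sd_, _, _ = render_movie(ts, MovieGeometry(field_size=128), rng=4,
                             background_mean=100, noise_sd=10)
    avg = sd_[ts.green_frames[:8]].mean(axis=0)
    counts = [len(detect_spots(avg, threshold_sigmas=s, min_separation=3))
              for s in (3, 5, 8, 12, 20)]
    assert counts == sorted(counts, reverse=True)


# ------------------------------------------------------------- registration

def test_identity_registration():
    pts = np.array([[10.0, 10.0], [50.0, 12.0], [30.0, 40.0], [20.0, 25.0]])
    cm = register_channels(pts, pts)
    assert np.allclose(cm.matrix, np.eye(2), atol=1e-12)
    assert np.allclose(cm.offset, 0, atol=1e-12)
    assert cm.residual_rms < 1e-12


def test_known_shift_recovered():
    rng = np.random.default_rng(5)
    pts = rng.uniform(10, 100, (40, 2))
    cm = register_channels(pts, pts + np.array([2.0, -1.5]))
    assert np.allclose(cm.offset, [2.0, -1.5], atol=0.05)


def test_known_rotation_recovered():
    rng = np.random.default_rng(6)
    pts = rng.uniform(10, 100, (40, 2))
    th = np.deg2rad(0.5)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    cm = register_channels(pts, pts @ R.T)
    assert np.allclose(cm.matrix, R, atol=1e-3)


def test_registration_is_idempotent_on_own_output():
    rng = np.random.default_rng(7)
    pts = rng.uniform(10, 100, (30, 2))
    cm = register_channels(pts, pts + np.array([1.0, 2.0]))
    cm2 = register_channels(cm.apply(pts), pts + np.array([1.0, 2.0]))
    assert np.allclose(cm2.matrix, np.eye(2), atol=1e-9)
    assert np.allclose(cm2.offset, 0.0, atol=1e-9)


def test_degenerate_geometry_rejected():
    with pytest.raises(DegenerateGeometryError):
        register_channels(np.zeros((2, 2)), np.zeros((2, 2)))
    line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(DegenerateGeometryError):
        register_channels(line, line)
    with pytest.raises(DegenerateGeometryError):
        ChannelMap(np.zeros((2, 2)), np.zeros(2))


# --------------------------------------------------------------- extraction

def test_noiseless_spot_gives_flat_trace_at_full_brightness(rng):
    ts = _static_traceset(1, rng)
    geom = MovieGeometry(field_size=64)
    sd_, sa_, pos = render_movie(ts, geom, rng=8, background_mean=50,
                                 noise_sd=0)
    spots = pd.DataFrame(pos, columns=["x", "y"])
    cmap = ChannelMap(np.array(geom.channel_matrix),
                      np.array(geom.channel_offset))
    ets = extract_traces(sd_, sa_, spots, cmap, excitation=ts.excitation,
                         frame_time=ts.frame_time, aperture=5.0,
                         annulus=(6.0, 9.0))
    g = ts.green_frames
    rel = (ets.donor[0, g] + ets.acceptor[0, g]) / (
        ts.donor[0, g] + ts.acceptor[0, g])
    assert np.all(np.abs(rel - 1.0) < 0.005)


def test_background_only_aperture_near_zero():
    rng = np.random.default_rng(9)
    stack = rng.normal(100, 10, (30, 64, 64))
    spots = pd.DataFrame({"x": [32.0], "y": [32.0]})
    ts = extract_traces(stack, stack, spots, aperture=2)
    se = 10 * np.sqrt(13) * np.sqrt(2)    # aperture noise + bg-estimate noise
    assert abs(ts.donor.mean()) < 3 * se / np.sqrt(30)


def test_off_field_spot_flagged_not_dropped(rng):
    ts = _static_traceset(2, rng)
    sd_, sa_, pos = render_movie(ts, MovieGeometry(field_size=64), rng=10,
                                 background_mean=0, noise_sd=0)
    spots = pd.DataFrame({"x": [pos[0, 0], 1.0], "y": [pos[0, 1], 1.0]})
    ets = extract_traces(sd_, sa_, spots, aperture=3, annulus=(4, 6))
    assert ets.n_molecules == 2
    assert list(ets.flags["off_field"]) == [False, True]


def test_movie_tiff_round_trip(tmp_path, rng):
    ts = _static_traceset(3, rng, n_green=4)
    sd_, sa_, _ = render_movie(ts, MovieGeometry(field_size=48), rng=12,
                               background_mean=100, noise_sd=5)
    p_d, p_a = simkit.write_movie_tiff(sd_, sa_, tmp_path, prefix="m")
    import tifffile
    back = tifffile.imread(p_d)
    assert back.shape == sd_.shape
    assert np.allclose(back, sd_)


def test_movie_round_trip_preserves_fret(rng):
    """trace -> movie -> extracted trace: per-frame E within 0.03 RMS at SNR ~10."""
    ts = _static_traceset(60, rng, e_means=(0.25, 0.75), total=2000.0,
                          n_green=12)
    geom = MovieGeometry(field_size=128)
    sd_, sa_, pos = render_movie(ts, geom, rng=11, background_mean=100,
                                 noise_sd=10)
    cmap = ChannelMap(np.array(geom.channel_matrix),
                      np.array(geom.channel_offset))
    spots = pd.DataFrame(pos, columns=["x", "y"])
    ets = extract_traces(sd_, sa_, spots, cmap, excitation=ts.excitation,
                         frame_time=ts.frame_time)
    f_in = fretpop.compute_fret(ts, min_total=None)
    f_out = fretpop.compute_fret(ets, min_total=None)
    err = (f_out.E - f_in.E).ravel()
    assert np.sqrt(np.mean(err ** 2)) < 0.03
    # donor-channel correlation with the input traces (the donor level
    # separates the two populations; total emission is the same for all)
    g = ts.green_frames
    r = np.corrcoef(ts.donor[:, g].ravel(), ets.donor[:, g].ravel())[0, 1]
    assert r >= 0.98
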