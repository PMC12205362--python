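"""FRET efficiency, acceptor filtering, histograms, mixtures, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scfret import fretpop, simkit
from scfret.containers import FretSeries
from scfret.exceptions import (ConfigurationError, FitFailureError,
                               InvalidParameterError)
from scfret.fretpop import (ClassificationRule, FRETHistogram, MixtureFit,
                            acceptor_filter, build_histogram, classify_molecules,
                            compute_fret, find_intersections, fit_three_gaussians,
                            fraction_unwound)
from conftest import make_traceset


# ----------------------------------------------------------------- compute_fret

@pytest.mark.parametrize("I_D, I_A, leakage, expected", [
    (400.0, 600.0, 0.0, 0.600),
    (500.0, 0.0, 0.0, 0.0),
    (500.0, 550.0, 0.1, 0.500),
])
def test_proximity_ratio(I_D, I_A, leakage, expected):
    ts = make_traceset([[I_D] * 3], [[I_A] * 3])
    series = compute_fret(ts, leakage=leakage, min_total=None)
    assert np.allclose(series.E, expected)


def test_zero_total_intensity_is_masked_not_nan():
    ts = make_traceset([[400.0, 0.0]], [[600.0, 0.0]])
    series = compute_fret(ts, min_total=None)
    assert series.valid[0, 0]
    assert not series.valid[0, 1]
    assert np.isnan(series.E[0, 1])


def test_frames_after_donor_bleach_are_masked():
    donor = [[500.0] * 5 + [0.0] * 5]
    acceptor = [[500.0] * 5 + [0.0] * 5]
    ts = make_traceset(donor, acceptor)
    series = compute_fret(ts, min_total="auto")
    assert series.valid[0, :5].all()
    assert not series.valid[0, 5:].any()


def test_no_green_frames_is_configuration_error():
    ts = make_traceset([[100.0] * 4], [[100.0] * 4],
                       excitation=["red"] * 4)
    with pytest.raises(ConfigurationError):
        compute_fret(ts)


# --------------------------------------------------------------- acceptor_filter

def _snap_traceset(n_mol, rng, inactive_fraction=0.0):
    phys = simkit.PhotophysicsParams(total_emission=1000, background_mean=100,
                                     noise_sd=50,
                                     inactive_acceptor_fraction=inactive_fraction)
    acq = simkit.acquisition_presets()["cas9_proximal_mm"]
    cond = simkit.UnwindingCondition("x", 0.3, 0.76)
    return simkit.simulate_snapshot(cond, 4.0, n_mol, phys, acq, rng)


def test_background_only_acceptor_rejected_and_bright_kept():
    exc = ["green"] * 4 + ["red"] * 6
    bg_rows = [[100.0] * 10, [100.0] * 10]
    acc = [[100.0] * 10,                      # pure background -> reject
           [100.0] * 4 + [100.0 + 10 * 5.0] * 6]  # 10 sigma above -> keep
    ts = make_traceset(bg_rows, acc, excitation=exc)
    keep = acceptor_filter(ts, k_sigmas=4, background_mean=100.0,
                           background_sd=5.0)
    assert list(keep) == [False, True]


def test_inactive_fraction_recovered(rng):
    ts = _snap_traceset(800, rng, inactive_fraction=0.3)
    keep = acceptor_filter(ts, k_sigmas=4)
    rejected = 1 - keep.mean()
    assert rejected == pytest.approx(0.30, abs=0.03)
    # ground-truth agreement, not just the aggregate rate
    assert (keep == ts.truth["acceptor_active"]).mean() > 0.98


# ------------------------------------------------------------------ histograms

def test_five_frames_pooled_per_molecule(rng):
    ts = _snap_traceset(100, rng)
    series = compute_fret(ts, min_total=None)
    hist = build_histogram(series)
    assert hist.counts.sum() + hist.n_out_of_range == 100 * 5
    assert hist.frames_per_molecule == 5


def test_constant_molecule_gives_single_bin():
    E = np.full((1, 8), 0.6)
    series = FretSeries(E=E, valid=np.ones_like(E, bool), frame_time=0.05)
    hist = build_histogram(series)
    assert hist.counts.max() == 5
    assert (hist.counts > 0).sum() == 1


def test_short_molecules_excluded_with_count():
    E = np.full((3, 8), 0.5)
    valid = np.ones_like(E, bool)
    valid[2, 4] = False                       # < 7 leading valid frames
    series = FretSeries(E=E, valid=valid, frame_time=0.05)
    hist = build_histogram(series)
    assert hist.n_molecules == 2
    assert hist.n_excluded == 1


def test_bimodal_histogram_modes_near_truth(rng):
    sch = simkit.KineticScheme(["a", "b"], np.zeros((2, 2)), [0.4, 0.6],
                               [0.05, 0.05])
    series, _ = simkit.simulate_fret_series(sch, 0.05, 8, 500, rng=rng)
    # split molecules between the two states
    sch2 = simkit.KineticScheme(["a", "b"], np.zeros((2, 2)), [0.4, 0.6],
                                [0.05, 0.05], initial_state="b")
    series2, _ = simkit.simulate_fret_series(sch2, 0.05, 8, 500, rng=rng)
    E = np.vstack([series.E, series2.E])
    hist = build_histogram(FretSeries(E, np.ones_like(E, bool), 0.05))
    c = hist.bin_centers
    sm = np.convolve(hist.counts, np.ones(3) / 3, mode="same")
    lo_mode = c[(c < 0.5)][np.argmax(sm[c < 0.5])]
    hi_mode = c[(c >= 0.5)][np.argmax(sm[c >= 0.5])]
    assert lo_mode == pytest.approx(0.4, abs=0.02)
    assert hi_mode == pytest.approx(0.6, abs=0.02)


# ------------------------------------------------------------- mixture fitting

def _sampled_mixture_hist(rng, weights=(0.2, 0.5, 0.3),
                          means=(0.08, 0.32, 0.62), sds=(0.04, 0.06, 0.07),
                          n=100_000):
    comp = rng.choice(3, size=n, p=np.asarray(weights) / np.sum(weights))
    vals = rng.normal(np.take(means, comp), np.take(sds, comp))
    edges = np.arange(-0.1, 1.1 + 0.01, 0.02)
    counts, _ = np.histogram(vals, bins=edges)
    return FRETHistogram(edges, counts, n // 5, 5)


def test_mixture_fit_recovers_known_parameters(rng):
    hist = _sampled_mixture_hist(rng)
    fit = fit_three_gaussians(hist, seed=1)
    assert np.allclose(fit.means, [0.08, 0.32, 0.62], atol=0.01)
    w = fit.weights / fit.weights.sum()
    assert np.allclose(w, [0.2, 0.5, 0.3], atol=0.03)


def test_mixture_fit_mirror_symmetry(rng):
    hist = _sampled_mixture_hist(rng, means=(0.2, 0.5, 0.8),
                                 weights=(0.3, 0.4, 0.3), sds=(0.05, 0.05, 0.05))
    mirrored = FRETHistogram(hist.bin_edges, hist.counts[::-1].copy(),
                             hist.n_molecules, 5)
    fit = fit_three_gaussians(hist, seed=2)
    fit_m = fit_three_gaussians(mirrored, seed=2)
    assert np.allclose(np.sort(1.0 - fit_m.means), fit.means, atol=0.02)


def test_degenerate_third_component_flagged(rng):
    hist = _sampled_mixture_hist(rng, weights=(0.0, 0.6, 0.4),
                                 means=(0.05, 0.35, 0.65))
    fit = fit_three_gaussians(hist, seed=3)
    assert any(f.startswith("degenerate") or f.startswith("no_crossing")
               for f in fit.flags) or fit.weights.min() / fit.weights.sum() < 0.02


def test_too_sparse_histogram_raises():
    edges = np.arange(-0.1, 1.11, 0.02)
    counts = np.zeros(len(edges) - 1, dtype=int)
    counts[10] = 50
    with pytest.raises(FitFailureError):
        fit_three_gaussians(FRETHistogram(edges, counts, 10, 5))


# ---------------------------------------------------------------- intersections

def _fit_from(amps, means, sds):
    return MixtureFit(amplitudes=np.asarray(amps, float),
                      means=np.asarray(means, float),
                      sds=np.asarray(sds, float), rss=0.0)


def test_equal_pair_crosses_at_midpoint():
    fit = _fit_from([1, 1, 1], [0.3, 0.6, 0.9], [0.05, 0.05, 0.05])
    t_low, t_high = find_intersections(fit)
    assert t_low == pytest.approx(0.45, abs=1e-9)
    assert t_high == pytest.approx(0.75, abs=1e-9)


def test_weighted_pair_matches_closed_form():
    """Equal sds: crossing at midpoint + s^2 ln(a1/a2) / (m2 - m1)."""
    a1, a2, m1, m2, s = 2.0, 1.0, 0.3, 0.6, 0.05
    fit = _fit_from([a1, a2, 0.5], [m1, m2, 0.95], [s, s, 0.05])
    t_low, _ = find_intersections(fit)
    expected = 0.5 * (m1 + m2) + s ** 2 * np.log(a1 / a2) / (m2 - m1)
    assert t_low == pytest.approx(expected, abs=1e-9)


def test_root_agrees_with_dense_grid(rng):
    """Brute-force grid argmin |f1 - f2| agrees with the root finder."""
    for _ in range(30):
        m = np.sort(rng.uniform(0.05, 0.95, 3))
        while np.min(np.diff(m)) < 0.08:
            m = np.sort(rng.uniform(0.05, 0.95, 3))
        fit = _fit_from(rng.uniform(0.5, 3.0, 3), m, rng.uniform(0.03, 0.09, 3))
        t_low, t_high = find_intersections(fit)
        for (i, j), t in (((0, 1), t_low), ((1, 2), t_high)):
            xs = np.linspace(fit.means[i], fit.means[j], 200_001)
            grid = xs[np.argmin(np.abs(fit.component(i, xs) -
                                       fit.component(j, xs)))]
            assert abs(t - grid) < 1e-3


def test_thresholds_invariant_under_count_rescaling(rng):
    hist = _sampled_mixture_hist(rng)
    fit = fit_three_gaussians(hist, seed=4)
    scaled = FRETHistogram(hist.bin_edges, hist.counts * 7, hist.n_molecules, 5)
    fit2 = fit_three_gaussians(scaled, seed=4)
    assert np.allclose(fit.thresholds, fit2.thresholds, atol=2e-3)


def test_dominant_crossing_on_two_population_histogram():
    """With a degenerate third component, the threshold falls between the
    two real populations near their weighted crossing."""
    fit = _fit_from([0.02, 1.5, 1.0], [0.9, 0.35, 0.60], [0.05, 0.05, 0.05])
    fit.means = np.sort(fit.means)  # keep the sorted-means invariant
    fit = _fit_from([1.5, 1.0, 0.02], [0.35, 0.60, 0.9], [0.05, 0.05, 0.05])
    t = fretpop.dominant_crossing(fit)
    expected = 0.475 + 0.05 ** 2 * np.log(1.5 / 1.0) / 0.25
    assert t == pytest.approx(expected, abs=1e-6)


def test_frame_pooled_fraction_matches_per_molecule_on_static_data():
    E = np.vstack([np.full((70, 7), 0.30), np.full((30, 7), 0.62)])
    series = FretSeries(E, np.ones_like(E, bool), 0.05)
    rule = ClassificationRule(0.14, 0.47)
    f_frames, _ = fretpop.fraction_unwound_frames(series, rule)
    f_mol, _ = fraction_unwound(classify_molecules(series, rule))
    assert f_frames == pytest.approx(f_mol) == pytest.approx(0.70)


# -------------------------------------------------------------- classification

def test_classification_windows():
    rule = ClassificationRule(0.14, 0.47)
    E = np.array([[0.30] * 7, [0.60] * 7, [0.10] * 7])
    series = FretSeries(E, np.ones_like(E, bool), 0.05)
    cats = classify_molecules(series, rule)
    assert list(cats) == ["unwound", "wound", "excluded"]


def test_category_counts_are_conserved(rng):
    ts = _snap_traceset(300, rng)
    series = compute_fret(ts, min_total=None)
    cats = classify_molecules(series, ClassificationRule(0.14, 0.47))
    n = sum((cats == c).sum() for c in ("unwound", "wound", "excluded"))
    assert n == series.n_molecules


def test_fraction_unwound_arithmetic():
    cats = np.array(["unwound"] * 50 + ["wound"] * 50 + ["excluded"] * 10)
    f, se = fraction_unwound(cats)
    assert f == 0.5
    assert se == pytest.approx(np.sqrt(0.25 / 100))
    assert fraction_unwound(np.array(["wound"] * 5))[0] == 0.0
    with pytest.raises(InvalidParameterError):
        fraction_unwound(np.array(["excluded"] * 3))


@settings(derandomize=True, max_examples=25)
@given(hi=st.floats(0.2, 1.0))
def test_fraction_monotone_in_upper_edge(hi):
    rng = np.random.default_rng(0)
    E = rng.uniform(0, 1, (200, 7))
    series = FretSeries(E, np.ones_like(E, bool), 0.05)
    f1, _ = fraction_unwound(classify_molecules(series,
                                                ClassificationRule(0.1, hi)))
    f2, _ = fraction_unwound(classify_molecules(
        series, ClassificationRule(0.1, min(hi + 0.1, 1.05))))
    assert f2 >= f1 - 1e-12


def test_misclassification_below_2pct_at_4sd_separation(rng):
    """Well-separated populations are classified against ground truth."""
    ts = _snap_traceset(1000, rng)
    keep = acceptor_filter(ts, k_sigmas=4)
    series = compute_fret(ts, min_total=None).subset(keep)
    states = ts.truth["snapshot_states"][keep]    # 0 resid, 1 unwound, 2 wound
    cats = classify_molecules(series, ClassificationRule(0.17, 0.46))
    truth_cat = np.take(["excluded", "unwound", "wound"], states)
    mis = np.mean(cats != truth_cat)
    assert mis < 0.02


def test_pipeline_fraction_matches_generator_truth(rng):
    """f_unwound from classification tracks the generator's occupancy."""
    phys = simkit.PhotophysicsParams(total_emission=1000, background_mean=100,
                                     noise_sd=50)
    cond = simkit.UnwindingCondition("x", 0.3, 0.77, y0=0.77)  # static at 0.77
    ts = simkit.simulate_snapshot(cond, 30.0, 2000, phys, rng=rng)
    from scfret.pipeline import snapshot_fraction
    f, se, _ = snapshot_fraction(ts)
    assert f == pytest.approx(0.77, abs=0.02)
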