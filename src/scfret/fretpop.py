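"""FRET populations: efficiency series, histograms, mixtures, classification.

FRET efficiency is the uncorrected proximity ratio with optional donor
leakage correction,

    E = (I_A - l * I_D) / (I_D + I_A - l * I_D),

computed on background-subtracted intensities over the green-excitation
frames. Snapshot histograms pool frames 3-7 (1-based) of each molecule,
are fitted with a sum of three Gaussians, and the crossings of adjacent
components define the FRET thresholds that split the population into
unwound (low-FRET) and wound (high-FRET) molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq, least_squares
from scipy.signal import find_peaks

from .containers import EXC_RED, FretSeries, TraceSet
from .exceptions import ConfigurationError, FitFailureError, InvalidParameterError

HIST_RANGE = (-0.1, 1.1)
DEFAULT_BIN_WIDTH = 0.02
#: 1-based inclusive snapshot frame window ("third to seventh frames").
DEFAULT_FRAME_WINDOW = (3, 7)

CAT_UNWOUND = "unwound"
CAT_WOUND = "wound"
CAT_EXCLUDED = "excluded"


# ---------------------------------------------------------------------------
# FRET efficiency and molecule filtering
# ---------------------------------------------------------------------------

def _auto_min_total(total: np.ndarray) -> float:
    """Heuristic signal threshold separating emitting from dark frames.

    Otsu's split of the pooled frame totals, applied only when the two
    classes it finds are separated by more than four within-class standard
    deviations; otherwise the totals are considered unimodal (no dark
    population) and no frames are masked.
    """
    from skimage.filters import threshold_otsu

    finite = total[np.isfinite(total)]
    if finite.size < 10 or np.ptp(finite) == 0:
        return -np.inf
    thr = float(threshold_otsu(finite, nbins=512))
    lo, hi = finite[finite <= thr], finite[finite > thr]
    if lo.size < 2 or hi.size < 2:
        return -np.inf
    if hi.mean() - lo.mean() < 4 * max(lo.std(), hi.std(), 1e-12):
        return -np.inf
    return thr


def compute_fret(traces: TraceSet, leakage: float = 0.0,
                 min_total: float | str | None = "auto") -> FretSeries:
    """Per-frame FRET efficiency over the green-excitation block.

    Frames whose leakage-corrected total intensity falls below
    ``min_total`` (donor bleached, or a dark/unbound molecule) are masked;
    frames with non-positive total are always masked rather than producing
    NaN-propagating divisions. ``min_total='auto'`` derives the threshold
    from the bimodality of the pooled totals; pass an explicit value (in
    background-subtracted counts) when the emission level is known.
    """
    if not 0.0 <= leakage < 1.0:
        raise InvalidParameterError("leakage must be in [0, 1)")
    g = traces.green_frames
    if g.size == 0:
        raise ConfigurationError("schedule contains no green-excitation frames")
    bg_d, bg_a = traces.background
    I_D = traces.donor[:, g] - bg_d
    I_A = traces.acceptor[:, g] - bg_a
    num = I_A - leakage * I_D
    den = I_D + I_A - leakage * I_D
    if min_total == "auto":
        min_total = _auto_min_total(den)
    elif min_total is None:
        min_total = -np.inf
    valid = den > max(min_total, 1e-9)
    E = np.full(den.shape, np.nan)
    np.divide(num, den, out=E, where=valid)
    return FretSeries(E=E, valid=valid, frame_time=traces.frame_time,
                      molecule_ids=traces.molecule_ids,
                      time_s=traces.time_s[g])


def acceptor_filter(traces: TraceSet, k_sigmas: float = 4.0,
                    background_mean: float | None = None,
                    background_sd: float | None = None) -> np.ndarray:
    """Keep molecules whose direct (red-excitation) acceptor signal is real.

    A molecule passes iff its median red-block acceptor intensity exceeds
    background + ``k_sigmas`` * background sd. If background statistics are
    not given they are estimated from the donor channel during red
    excitation, which sees background only.
    """
    r = traces.red_frames
    if r.size == 0:
        raise ConfigurationError(
            "schedule contains no red-excitation frames; cannot filter on "
            "direct acceptor signal")
    red_acc = traces.acceptor[:, r]
    if background_mean is None or background_sd is None:
        ref = traces.donor[:, r].ravel()
        est_mean = float(np.median(ref))
        est_sd = float(1.4826 * np.median(np.abs(ref - est_mean)))
        background_mean = est_mean if background_mean is None else background_mean
        background_sd = max(est_sd, 1e-9) if background_sd is None else background_sd
    med = np.median(red_acc, axis=1)
    return med > background_mean + k_sigmas * background_sd


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------

@dataclass
class FRETHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_molecules: int
    frames_per_molecule: int
    n_excluded: int = 0
    n_out_of_range: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "count": self.counts})


def build_histogram(series: FretSeries,
                    frame_window: tuple[int, int] = DEFAULT_FRAME_WINDOW,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    keep: np.ndarray | None = None) -> FRETHistogram:
    """Pool the snapshot-window frames of each molecule into a histogram.

    ``frame_window`` is 1-based inclusive (the default (3, 7) pools five
    frames per molecule). Molecules lacking valid frames through the window
    end (e.g. fewer than 7 valid frames for the default) are excluded and
    counted in ``n_excluded``.
    """
    lo, hi = frame_window
    if not (1 <= lo <= hi <= series.n_frames):
        raise InvalidParameterError(f"frame window {frame_window} outside trace")
    sl = slice(lo - 1, hi)                      # 1-based inclusive -> 0-based
    ok_mol = series.valid[:, :hi].all(axis=1)
    if keep is not None:
        ok_mol &= np.asarray(keep, dtype=bool)
    vals = series.E[ok_mol, sl].ravel()
    edges = np.arange(HIST_RANGE[0], HIST_RANGE[1] + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    n_out = int(vals.size - counts.sum())
    return FRETHistogram(bin_edges=edges, counts=counts,
                         n_molecules=int(ok_mol.sum()),
                         frames_per_molecule=hi - lo + 1,
                         n_excluded=int((~ok_mol).sum()),
                         n_out_of_range=n_out)


# ---------------------------------------------------------------------------
# Three-Gaussian mixture fit and intersection thresholds
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Sum-of-three-Gaussians description of a FRET histogram.

    Components are sorted by mean. ``weights`` are component areas in
    counts; ``amplitudes`` the peak heights. ``thresholds`` are the two
    crossings of adjacent weighted component curves bracketing the middle
    component.
    """

    amplitudes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    rss: float
    thresholds: tuple[float, float] | None = None
    flags: list[str] = field(default_factory=list)
    bin_width: float = DEFAULT_BIN_WIDTH

    @property
    def weights(self) -> np.ndarray:
        return self.amplitudes * self.sds * np.sqrt(2 * np.pi) / self.bin_width

    def component(self, i: int, x: np.ndarray) -> np.ndarray:
        return self.amplitudes[i] * np.exp(
            -0.5 * ((np.asarray(x) - self.means[i]) / self.sds[i]) ** 2)

    def density(self, x: np.ndarray) -> np.ndarray:
        return sum(self.component(i, x) for i in range(3))

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.amplitudes.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "rss": self.rss,
            "thresholds": None if self.thresholds is None else list(self.thresholds),
            "flags": self.flags,
        }


def _initial_guess(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ys = gaussian_filter1d(y.astype(float), 2.0)
    peaks, props = find_peaks(ys, prominence=max(ys.max() * 0.02, 1e-9))
    order = np.argsort(props["prominences"])[::-1]
    cand = list(x[peaks[order[:3]]])
    # fill missing components from the mass quantiles
    if len(cand) < 3:
        total = y.sum()
        if total > 0:
            cdf = np.cumsum(y) / total
            for q in (0.15, 0.5, 0.85):
                if len(cand) >= 3:
                    break
                pos = x[np.searchsorted(cdf, q)]
                if all(abs(pos - c) > 0.08 for c in cand):
                    cand.append(pos)
        while len(cand) < 3:
            cand.append(x[len(cand) * len(x) // 3])
    cand = np.sort(np.asarray(cand[:3], dtype=float))
    amp = np.interp(cand, x, np.maximum(ys, 1e-3))
    sd = np.full(3, 0.05)
    return np.concatenate([amp, cand, sd])


def fit_three_gaussians(hist: FRETHistogram, init: np.ndarray | None = None,
                        n_restarts: int = 5, seed: int = 0) -> MixtureFit:
    """Nonlinear least squares of three Gaussians on binned counts.

    Runs ``n_restarts`` seeded perturbations of the initial guess and keeps
    the best residual sum of squares. A component with negligible area or a
    width at the bound is flagged ``degenerate`` rather than failing.
    """
    x, y = hist.bin_centers, hist.counts.astype(float)
    if np.count_nonzero(y) < 9:
        raise FitFailureError("too few nonzero bins for a 3-component fit",
                              {"nonzero_bins": int(np.count_nonzero(y))})
    p0 = _initial_guess(x, y) if init is None else np.asarray(init, dtype=float)
    lo = np.array([0.0] * 3 + [HIST_RANGE[0]] * 3 + [0.005] * 3)
    hi = np.array([max(4 * y.max(), 1.0)] * 3 + [HIST_RANGE[1]] * 3 + [0.5] * 3)

    def model(p):
        a, m, s = p[:3], p[3:6], p[6:9]
        return np.sum(a[:, None] * np.exp(
            -0.5 * ((x[None, :] - m[:, None]) / s[:, None]) ** 2), axis=0)

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    errors = []
    for r in range(max(1, n_restarts)):
        p = p0.copy()
        if r > 0:
            p[0:3] *= rng.uniform(0.5, 2.0, 3)
            p[3:6] += rng.normal(0.0, 0.03, 3)
            p[6:9] *= rng.uniform(0.7, 1.4, 3)
        p = np.clip(p, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(lambda q: model(q) - y, p, bounds=(lo, hi),
                                method="trf", max_nfev=2000)
        except Exception as exc:   # pragma: no cover - scipy rarely raises here
            errors.append(str(exc))
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res, res.cost
    if best is None:
        raise FitFailureError("all mixture-fit restarts failed",
                              {"errors": errors})

    a, m, s = best.x[:3], best.x[3:6], best.x[6:9]
    order = np.argsort(m)
    fit = MixtureFit(amplitudes=a[order], means=m[order], sds=s[order],
                     rss=float(2 * best.cost), bin_width=float(np.diff(x[:2])[0]))
    wtot = fit.weights.sum()
    for i in range(3):
        if wtot > 0 and fit.weights[i] < 0.01 * wtot:
            fit.flags.append(f"degenerate_component_{i}")
        if fit.sds[i] >= 0.5 - 1e-6:
            fit.flags.append(f"width_at_bound_{i}")
    fit.thresholds = find_intersections(fit)
    return fit


def _pair_crossing(fit: MixtureFit, i: int, j: int) -> tuple[float, bool]:
    """Crossing of weighted component curves i, j between their means."""
    mi, mj = fit.means[i], fit.means[j]
    if mj - mi < 1e-12:
        return 0.5 * (mi + mj), False
    g = lambda x: fit.component(i, x) - fit.component(j, x)
    xs = np.linspace(mi, mj, 2001)
    vals = g(xs)
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if idx.size:
        k = idx[0]
        try:
            root = brentq(g, xs[k], xs[k + 1], xtol=1e-12)
            return float(root), True
        except ValueError:
            pass
    # nested/non-crossing components: fall back to the point of closest
    # approach of the two curves (equal-posterior surrogate), flagged
    return float(xs[np.argmin(np.abs(vals))]), False


def find_intersections(fit: MixtureFit) -> tuple[float, float]:
    """Thresholds (t_low, t_high) bracketing the middle component.

    Each threshold is the numerically located crossing of the two adjacent
    weighted Gaussian curves between their means; a missing crossing
    (nested components) falls back to the closest-approach point and adds a
    ``no_crossing`` flag.
    """
    t_low, ok_low = _pair_crossing(fit, 0, 1)
    t_high, ok_high = _pair_crossing(fit, 1, 2)
    if not ok_low:
        fit.flags.append("no_crossing_low")
    if not ok_high:
        fit.flags.append("no_crossing_high")
    return (t_low, t_high)


# ---------------------------------------------------------------------------
# Classification and the unwound fraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationRule:
    """FRET window rule: (lo, hi] -> unwound, > hi -> wound, <= lo -> excluded.

    The fixed windows used for the two mismatch designs are available as
    presets: proximal single mismatch (0.14, 0.47) and distal triple
    mismatch (0.18, 0.51); thresholds can also come from a
    :class:`MixtureFit` via :func:`rule_from_fit`.
    """

    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise InvalidParameterError("rule requires lo < hi")


RULE_PRESETS = {
    "cas9_proximal_mm": ClassificationRule(0.14, 0.47),
    "cas9_distal_mm": ClassificationRule(0.18, 0.51),
}


def dominant_crossing(fit: MixtureFit) -> float:
    """Crossing of the two heaviest mixture components.

    The robust single wound/unwound threshold when the third component is
    degenerate (histograms with only two real populations): the crossing
    of the two dominant weighted Gaussians, located between their means.
    """
    order = np.argsort(fit.weights)[::-1][:2]
    i, j = int(min(order)), int(max(order))
    t, _ = _pair_crossing(fit, i, j)
    return t


def rule_from_fit(fit: MixtureFit) -> ClassificationRule:
    if fit.thresholds is None:
        fit.thresholds = find_intersections(fit)
    return ClassificationRule(*fit.thresholds)


def classify_molecules(series: FretSeries, rule: ClassificationRule,
                       frame_window: tuple[int, int] = DEFAULT_FRAME_WINDOW,
                       ) -> np.ndarray:
    """Categorize each molecule by its mean E over the snapshot window."""
    lo, hi = frame_window
    sl = slice(lo - 1, hi)
    E = np.where(series.valid[:, sl], series.E[:, sl], np.nan)
    with np.errstate(invalid="ignore"):
        meanE = np.nanmean(E, axis=1)
    cats = np.full(series.n_molecules, CAT_EXCLUDED, dtype=object)
    cats[meanE > rule.hi] = CAT_WOUND
    cats[(meanE > rule.lo) & (meanE <= rule.hi)] = CAT_UNWOUND
    return cats.astype("U8")


def fraction_unwound_frames(series: FretSeries, rule: ClassificationRule,
                            frame_window: tuple[int, int] = DEFAULT_FRAME_WINDOW,
                            ) -> tuple[float, float]:
    """Unwound fraction from pooled per-frame values (histogram-population mode).

    Counts individual snapshot-window frames inside the unwound window
    versus above it, mirroring the division of low-FRET by total histogram
    populations; the per-molecule mode (:func:`classify_molecules` +
    :func:`fraction_unwound`) is the default elsewhere.
    """
    lo, hi = frame_window
    sl = slice(lo - 1, hi)
    vals = series.E[:, sl][series.valid[:, sl]]
    n_u = int(((vals > rule.lo) & (vals <= rule.hi)).sum())
    n_w = int((vals > rule.hi).sum())
    if n_u + n_w == 0:
        raise InvalidParameterError("no frames above the total threshold")
    f = n_u / (n_u + n_w)
    return f, float(np.sqrt(f * (1 - f) / (n_u + n_w)))


def fraction_unwound(categories: np.ndarray) -> tuple[float, float]:
    """Unwound fraction among non-excluded molecules, with binomial SE."""
    categories = np.asarray(categories)
    n_u = int(np.sum(categories == CAT_UNWOUND))
    n_w = int(np.sum(categories == CAT_WOUND))
    n = n_u + n_w
    if n == 0:
        raise InvalidParameterError(
            "all molecules excluded; unwound fraction undefined")
    f = n_u / n
    se = np.sqrt(f * (1 - f) / n)
    return f, float(se)
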