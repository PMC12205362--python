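"""Two-state HMM idealization of FRET trajectories and dwell extraction.

Trajectories are modelled with a shared-parameter two-state hidden Markov
model with Gaussian emissions, fitted by maximum-likelihood Baum-Welch
(multiple seeded restarts, best likelihood kept) across all traces.
Decoding uses Viterbi; masked frames (donor bleach, dark intervals)
terminate the decoded region, so each contiguous valid segment is decoded
independently. Dwells are run lengths times the frame time, with
first/last-dwell censoring flags and an outcome label per dwell:
``to_low``/``to_high`` (observed transition), ``to_dark`` (the segment
ends by signal loss before the end of the trace) or ``censored`` (cut by
the end of observation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .containers import FretSeries
from .exceptions import FitFailureError, InvalidParameterError

STATE_LOW, STATE_HIGH = 0, 1
VARIANCE_FLOOR = 1e-4          # E-units^2; sd floor 0.01

OUT_TO_LOW = "to_low"
OUT_TO_HIGH = "to_high"
OUT_TO_DARK = "to_dark"
OUT_CENSORED = "censored"


@dataclass
class HMMParams:
    """Shared two-state Gaussian HMM, states ordered by emission mean."""

    means: np.ndarray              # (2,) E-units, ascending
    sds: np.ndarray                # (2,) E-units
    transmat: np.ndarray           # (2, 2) per-frame transition probabilities
    startprob: np.ndarray
    frame_time: float
    log_likelihood: float = np.nan
    flags: list[str] = field(default_factory=list)

    def rates(self) -> dict[str, float]:
        """First-order rate estimates k_ij = p_ij / dt (valid for p << 1)."""
        return {
            "k_low_to_high": float(self.transmat[0, 1] / self.frame_time),
            "k_high_to_low": float(self.transmat[1, 0] / self.frame_time),
        }

    def to_dict(self) -> dict:
        return {"means": self.means.tolist(), "sds": self.sds.tolist(),
                "transmat": self.transmat.tolist(),
                "startprob": self.startprob.tolist(),
                "frame_time": self.frame_time,
                "log_likelihood": self.log_likelihood, "flags": self.flags}


def _valid_segments(series: FretSeries, min_len: int = 2):
    """Yield (molecule_index, start_frame, E-values) per contiguous valid run."""
    for i in range(series.n_molecules):
        v = series.valid[i]
        if not v.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], v.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= min_len:
                yield i, int(s), series.E[i, s:e]


def fit_hmm2(series: FretSeries, n_restarts: int = 5, seed: int = 0,
             n_iter: int = 200, tol: float = 1e-4) -> HMMParams:
    """Baum-Welch ML fit of the shared two-state model.

    Initialization spreads the two means over the lower/upper quartiles of
    the pooled E values with per-restart jitter; emission variances are
    floored at 1e-4 (sd 0.01) and a fit touching the floor is flagged.
    """
    segs = list(_valid_segments(series))
    if not segs:
        raise InvalidParameterError("no valid frames to fit")
    X = np.concatenate([e for _, _, e in segs])[:, None]
    lengths = [len(e) for _, _, e in segs]
    if len(lengths) < 10 and X.size < 1000:
        raise InvalidParameterError(
            "need >= 10 traces or >= 1000 total frames for a shared fit")

    q25, q75 = np.percentile(X, [25, 75])
    spread = max(q75 - q25, 0.05)
    rng = np.random.default_rng(seed)
    best_model, best_ll = None, -np.inf
    for r in range(max(1, n_restarts)):
        m = GaussianHMM(n_components=2, covariance_type="diag",
                        min_covar=VARIANCE_FLOOR, n_iter=n_iter, tol=tol,
                        init_params="", params="stmc",
                        random_state=int(rng.integers(2 ** 31 - 1)))
        m.startprob_ = np.array([0.5, 0.5])
        p = np.clip(0.05 * rng.uniform(0.5, 2.0), 1e-3, 0.4)
        m.transmat_ = np.array([[1 - p, p], [p, 1 - p]])
        jit = rng.normal(0.0, 0.1 * spread, 2)
        means = np.array([q25, q75]) + jit
        if r % 2 == 1:               # occasionally start label-swapped
            means = means[::-1]
        m.means_ = means[:, None]
        m.covars_ = np.full((2, 1), max((0.25 * spread) ** 2, VARIANCE_FLOOR))
        try:
            m.fit(X, lengths=lengths)
            ll = m.score(X, lengths=lengths)
        except Exception:
            continue
        if ll > best_ll:
            best_model, best_ll = m, ll
    if best_model is None:
        raise FitFailureError("all HMM restarts failed")

    means = best_model.means_.ravel()
    sds = np.sqrt(np.asarray(best_model.covars_).reshape(2, -1)[:, 0])
    order = np.argsort(means)
    params = HMMParams(
        means=means[order], sds=sds[order],
        transmat=best_model.transmat_[np.ix_(order, order)],
        startprob=best_model.startprob_[order],
        frame_time=series.frame_time, log_likelihood=float(best_ll))
    if np.any(params.sds <= np.sqrt(VARIANCE_FLOOR) * 1.01):
        params.flags.append("variance_floored")
    if abs(params.means[1] - params.means[0]) < 1e-6:
        params.flags.append("means_collapsed")
    return params


def viterbi_path(series: FretSeries, params: HMMParams) -> np.ndarray:
    """Most-probable state per frame; -1 on masked frames.

    Each contiguous valid segment is decoded independently. Tie-break: in
    the recursion an exact tie between predecessors prefers the
    self-transition (the state continues); an exact tie at the segment end
    prefers the state that is its own best predecessor.
    """
    log_a = np.log(np.clip(params.transmat, 1e-300, None))
    log_pi = np.log(np.clip(params.startprob, 1e-300, None))
    out = np.full((series.n_molecules, series.n_frames), -1, dtype=int)
    for i, s0, e in _valid_segments(series, min_len=1):
        n = len(e)
        log_b = (-0.5 * ((e[:, None] - params.means[None, :]) /
                         params.sds[None, :]) ** 2
                 - np.log(params.sds[None, :] * np.sqrt(2 * np.pi)))
        delta = log_pi + log_b[0]
        psi = np.zeros((n, 2), dtype=int)
        for t in range(1, n):
            new = np.empty(2)
            for j in (0, 1):
                cand = delta + log_a[:, j]
                best = int(np.argmax(cand))
                if cand[j] >= cand[best]:      # tie -> continue in state j
                    best = j
                psi[t, j] = best
                new[j] = cand[best] + log_b[t, j]
            delta = new
        jstar = int(np.argmax(delta))
        other = 1 - jstar
        if delta[other] == delta[jstar] and psi[n - 1, other] == other:
            jstar = other
        seq = np.empty(n, dtype=int)
        seq[-1] = jstar
        for t in range(n - 1, 0, -1):
            seq[t - 1] = psi[t, seq[t]]
        out[i, s0:s0 + n] = seq
    return out


def idealization_accuracy(paths: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of decoded (non-masked) frames matching the true state."""
    m = paths >= 0
    if not m.any():
        return np.nan
    return float(np.mean(paths[m] == truth[m]))


def extract_dwells(paths: np.ndarray, frame_time: float,
                   molecule_ids: np.ndarray | None = None,
                   drop_censored: bool = False) -> pd.DataFrame:
    """Run-length encode decoded paths into a dwell table.

    Columns: molecule_id, state ("low"/"high"), t_start (s), duration (s),
    left_censored, right_censored, outcome. ``left_censored`` marks dwells
    starting at frame 0 of the trace and ``right_censored`` dwells ending
    at its final frame (true duration is a lower bound in both cases);
    dwells bounded by interior dark gaps have observed starts/ends.
    """
    paths = np.atleast_2d(paths)
    n_mol, n_frames = paths.shape
    if molecule_ids is None:
        molecule_ids = np.arange(n_mol)
    rows = []
    names = {STATE_LOW: "low", STATE_HIGH: "high"}
    for i in range(n_mol):
        p = paths[i]
        valid = p >= 0
        if not valid.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], valid.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            seg = p[s:e]
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(seg)]))
            for r, (a, b) in enumerate(zip(starts, ends)):
                state = seg[a]
                last_run = r == len(starts) - 1
                if not last_run:
                    outcome = OUT_TO_HIGH if seg[b] == STATE_HIGH else OUT_TO_LOW
                elif e < n_frames:
                    outcome = OUT_TO_DARK       # signal lost before trace end
                else:
                    outcome = OUT_CENSORED
                rows.append({
                    "molecule_id": molecule_ids[i],
                    "state": names[int(state)],
                    "t_start": (s + a) * frame_time,
                    "duration": (b - a) * frame_time,
                    "left_censored": bool(s + a == 0),
                    "right_censored": bool(s + b == n_frames),
                    "outcome": outcome,
                })
    df = pd.DataFrame(rows, columns=["molecule_id", "state", "t_start",
                                     "duration", "left_censored",
                                     "right_censored", "outcome"])
    if drop_censored and len(df):
        df = df[~(df.left_censored | df.right_censored |
                  (df.outcome == OUT_CENSORED))].reset_index(drop=True)
    return df
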