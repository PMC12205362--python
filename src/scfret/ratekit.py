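"""Rate constants from dwell tables.

Dwell-time distributions of a single-rate exit process are exponential, so
the empirical survival curve (1 - CDF) is fitted with

    y(t) = y0 + A1 * exp(-k t),

and the maximum-likelihood estimate k = 1/mean(t) serves as a cross-check.
For the branched exit of the mismatch-bound state (dissociation at k-1
versus sliding-clamp formation at k2) the total rate k = k-1 + k2 from the
dwell fit is decomposed with the branch ratio N2/N-1 = k2/k-1, where N2
counts bound events resolving to the low-FRET clamp and N-1 events ending
by donor-signal loss. Standard errors come from molecule-level bootstrap
resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dwellhmm import OUT_TO_DARK, OUT_TO_HIGH, OUT_TO_LOW
from .exceptions import InvalidParameterError

MIN_DWELLS = 10


@dataclass
class ExpFit:
    y0: float
    A1: float
    k: float                  # s^-1 (or 1/unit of the input times)
    se: dict = field(default_factory=dict)
    n_dwells: int = 0
    method: str = "lsq_1mcdf"
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"y0": self.y0, "A1": self.A1, "k": self.k, "se": self.se,
                "n_dwells": self.n_dwells, "method": self.method,
                "flags": self.flags}


def exp_decay(t, y0, A1, k):
    return y0 + A1 * np.exp(-k * np.asarray(t, dtype=float))


def empirical_survival(durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted dwell times and the empirical 1 - CDF evaluated at them."""
    t = np.sort(np.asarray(durations, dtype=float))
    n = t.size
    y = 1.0 - np.arange(1, n + 1) / n
    return t, y


def fit_exponential_decay(t: np.ndarray, y: np.ndarray,
                          k0: float | None = None) -> ExpFit:
    """Least-squares fit of y = y0 + A1 exp(-k t) to a survival curve."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if k0 is None:
        pos = y > max(y.max() * 1e-3, 1e-12)
        k0 = 1.0 / max(np.interp(np.exp(-1.0) * y[0], y[pos][::-1],
                                 t[pos][::-1]), 1e-9) if pos.sum() > 2 else 1.0
    popt, pcov = curve_fit(exp_decay, t, y, p0=(0.0, max(y[0], 1e-6), k0),
                           bounds=([-0.5, 0.0, 1e-12], [0.5, 2.0, np.inf]),
                           maxfev=20000)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return ExpFit(y0=float(popt[0]), A1=float(popt[1]), k=float(popt[2]),
                  se={"y0": float(perr[0]), "A1": float(perr[1]),
                      "k": float(perr[2])},
                  n_dwells=t.size)


def fit_exp_1mcdf(durations: np.ndarray, method: str = "lsq_1mcdf") -> ExpFit:
    """Exponential rate from dwell durations.

    ``lsq_1mcdf`` fits the empirical survival curve; ``mle`` returns the
    closed form k = 1/mean with SE k/sqrt(n).
    """
    d = np.asarray(durations, dtype=float)
    d = d[np.isfinite(d)]
    if d.size < MIN_DWELLS:
        raise InvalidParameterError(
            f"need >= {MIN_DWELLS} uncensored dwells, got {d.size}")
    if np.ptp(d) == 0:
        raise InvalidParameterError("all dwells identical; degenerate fit")
    if method == "mle":
        k = 1.0 / d.mean()
        return ExpFit(y0=0.0, A1=1.0, k=float(k),
                      se={"k": float(k / np.sqrt(d.size))},
                      n_dwells=d.size, method="mle")
    if method != "lsq_1mcdf":
        raise InvalidParameterError(f"unknown method {method!r}")
    t, y = empirical_survival(d)
    fit = fit_exponential_decay(t, y, k0=1.0 / d.mean())
    fit.method = "lsq_1mcdf"
    return fit


def censored_rate_mle(durations: np.ndarray,
                      event_observed: np.ndarray) -> ExpFit:
    """Exponential-rate MLE including censored dwells.

    For an exponential exit process the residual dwell is again exponential
    (memorylessness), so every observed interval contributes its duration
    to the exposure time while only intervals with an observed termination
    count as events:

        k = n_events / sum(durations).

    This removes the finite-observation-window bias that survival fits of
    completed dwells acquire when the mean dwell is not small relative to
    the trace length.
    """
    d = np.asarray(durations, dtype=float)
    ev = np.asarray(event_observed, dtype=bool)
    if d.size != ev.size:
        raise InvalidParameterError("durations/event_observed length mismatch")
    n_events = int(ev.sum())
    if n_events < MIN_DWELLS:
        raise InvalidParameterError(
            f"need >= {MIN_DWELLS} observed events, got {n_events}")
    total = d.sum()
    if total <= 0:
        raise InvalidParameterError("non-positive total observed time")
    k = n_events / total
    return ExpFit(y0=0.0, A1=1.0, k=float(k),
                  se={"k": float(k / np.sqrt(n_events))},
                  n_dwells=n_events, method="mle_censored")


def rate_from_dwell_table(dwells: pd.DataFrame, state: str,
                          method: str = "lsq_1mcdf",
                          event_outcomes: tuple[str, ...] = (OUT_TO_LOW,
                                                             OUT_TO_HIGH),
                          ) -> ExpFit:
    """Exit rate of one state from a dwell table.

    ``lsq_1mcdf``/``mle`` fit only dwells whose termination is in
    ``event_outcomes``; ``mle_censored`` additionally uses censored dwells
    as exposure time.
    """
    g = dwells[dwells.state == state]
    observed = g.outcome.isin(event_outcomes).to_numpy()
    if method == "mle_censored":
        return censored_rate_mle(g.duration.to_numpy(), observed)
    return fit_exp_1mcdf(g.duration.to_numpy()[observed], method=method)


# ---------------------------------------------------------------------------
# Branch decomposition (total rate + branch ratio -> k-1, k2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BranchCounts:
    """Counts of bound-state outcomes: N2 clamp formations, N-1 dissociations."""

    N2: int
    N_minus1: int

    def __post_init__(self):
        if self.N2 < 0 or self.N_minus1 < 0:
            raise InvalidParameterError("branch counts must be >= 0")


def branch_counts_from_dwells(dwells: pd.DataFrame) -> BranchCounts:
    """Count high-FRET dwell outcomes: to_low -> N2, to_dark -> N-1.

    A low-FRET frame after binding can mean clamp formation, while loss of
    the donor signal marks dissociation (or sliding out of the evanescent
    field); censored dwells are not counted.
    """
    high = dwells[dwells.state == "high"]
    return BranchCounts(N2=int((high.outcome == OUT_TO_LOW).sum()),
                        N_minus1=int((high.outcome == OUT_TO_DARK).sum()))


def decompose_branch(k_total: float, counts: BranchCounts
                     ) -> tuple[float, float, list[str]]:
    """Split the total exit rate into (k_minus1, k_2) using the branch ratio.

    With r = N2/N-1: k2 = k r/(1+r) and k-1 = k/(1+r), so k2 + k-1 = k and
    k2/k-1 = r hold exactly. N-1 = 0 returns the limit (0, k) flagged.
    """
    if k_total <= 0:
        raise InvalidParameterError("k_total must be > 0")
    n2, nm1 = counts.N2, counts.N_minus1
    if n2 + nm1 == 0:
        raise InvalidParameterError("no branch events")
    flags = []
    if nm1 == 0:
        flags.append("no_dissociation_events")
        return 0.0, float(k_total), flags
    frac2 = n2 / (n2 + nm1)           # = r/(1+r)
    k2 = k_total * frac2
    k_minus1 = k_total - k2
    return float(k_minus1), float(k2), flags


# ---------------------------------------------------------------------------
# Association and binding-event rates
# ---------------------------------------------------------------------------

def association_rate(waiting_times: np.ndarray,
                     concentration_nM: float | None = None,
                     method: str = "lsq_1mcdf") -> dict:
    """Pseudo-first-order association rate from waiting times between events.

    Returns ``k_on_prime`` (s^-1) from the exponential fit of the waiting
    times; if a protein concentration is given, the second-order constant
    ``k_on = k_on_prime / concentration`` (per nM per s) is included.
    """
    fit = fit_exp_1mcdf(waiting_times, method=method)
    out = {"k_on_prime": fit.k, "se": fit.se, "n": fit.n_dwells, "fit": fit}
    if concentration_nM is not None:
        if concentration_nM <= 0:
            raise InvalidParameterError("concentration must be > 0")
        out["k_on_per_nM"] = fit.k / concentration_nM
    return out


def waiting_times_from_dwells(dwells: pd.DataFrame) -> np.ndarray:
    """Dark intervals between successive binding events of each molecule.

    The gap between the end of one decoded segment and the start of the
    next (per molecule) is the waiting time t_off; edge gaps are censored
    and not returned.
    """
    waits = []
    for _, g in dwells.groupby("molecule_id"):
        g = g.sort_values("t_start")
        seg_end = (g.t_start + g.duration).to_numpy()
        seg_start = g.t_start.to_numpy()
        # successive segments: gap from the end of a run to the start of the
        # next run that is not contiguous
        gaps = seg_start[1:] - seg_end[:-1]
        waits.extend(gaps[gaps > 1e-12])
    return np.asarray(waits)


def binding_event_rate(dwells: pd.DataFrame, total_observed_time: float,
                       n_molecules: int | None = None) -> dict:
    """Binding events per second: high-FRET dwell starts / observed time.

    Only observed starts count (left-censored dwells began before the
    record). The per-molecule normalization is reported alongside when
    ``n_molecules`` is given; the total-time rate is primary.
    """
    if total_observed_time <= 0:
        raise InvalidParameterError("total_observed_time must be > 0")
    high = dwells[(dwells.state == "high") & (~dwells.left_censored)]
    n_events = int(len(high))
    out = {"k1": n_events / total_observed_time, "n_events": n_events}
    if n_molecules:
        per_mol_time = total_observed_time / n_molecules
        per_mol = high.groupby("molecule_id").size() / per_mol_time
        # molecules with zero events contribute zero rates
        mean_rate = per_mol.sum() / n_molecules
        out["events_per_molecule"] = n_events / n_molecules
        out["k1_per_molecule_mean"] = float(mean_rate)
    return out


# ---------------------------------------------------------------------------
# Bootstrap standard errors
# ---------------------------------------------------------------------------

def bootstrap_se(estimator, dwells: pd.DataFrame, n_boot: int = 500,
                 seed: int = 0) -> dict:
    """Molecule-level bootstrap SE of any dwell-table estimator.

    ``estimator(table) -> float | dict[str, float]``; molecules are
    resampled with replacement and the SE is the standard deviation of the
    estimator over replicates.
    """
    if n_boot < 200:
        raise InvalidParameterError("n_boot must be >= 200")
    ids = dwells["molecule_id"].unique()
    if len(ids) < 5:
        raise InvalidParameterError(
            f"bootstrap needs >= 5 molecules, got {len(ids)}")
    rng = np.random.default_rng(seed)
    groups = {i: g for i, g in dwells.groupby("molecule_id")}
    stats: list[dict] = []
    for _ in range(n_boot):
        draw = rng.choice(ids, size=len(ids), replace=True)
        tab = pd.concat([groups[i] for i in draw], ignore_index=True)
        try:
            val = estimator(tab)
        except Exception:
            continue
        stats.append(val if isinstance(val, dict) else {"value": val})
    if not stats:
        raise InvalidParameterError("estimator failed on all replicates")
    keys = stats[0].keys()
    return {k: float(np.std([s[k] for s in stats if k in s], ddof=1))
            for k in keys}


# ---------------------------------------------------------------------------
# Rate-set summary
# ---------------------------------------------------------------------------

@dataclass
class RateSet:
    """Fitted rate constants of one condition."""

    condition: str = ""
    nucleotide: str = ""               # "ADP" | "ATP" | ""
    k_on_prime: float | None = None
    k_off: float | None = None
    k1: float | None = None
    k_minus1: float | None = None
    k2: float | None = None
    se: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return d
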