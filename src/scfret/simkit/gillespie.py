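"""Exact stochastic simulation of state paths (Gillespie algorithm).

Waiting times in each state are exponential with the state's total exit
rate; the successor state is drawn with probability proportional to its
rate. Every visit to the scheme's high-FRET state records how it ended:
``to_low`` (transition to a lower-FRET emitting state, e.g. sliding-clamp
formation), ``to_dark`` (transition to a non-emitting state, e.g.
dissociation and donor-signal loss) or ``censored`` (cut by the end of the
simulation window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import InvalidParameterError
from .scheme import KineticScheme

OUTCOME_TO_LOW = "to_low"
OUTCOME_TO_DARK = "to_dark"
OUTCOME_CENSORED = "censored"


@dataclass
class StatePathTruth:
    """Ground-truth state path of one molecule.

    ``events`` is a contiguous, non-overlapping list of
    ``(state_index, t_start, t_end)`` covering ``[0, duration]``.
    ``high_outcomes`` holds one outcome label per visit to the scheme's
    high-FRET state, in order of occurrence.
    """

    molecule_id: int
    duration: float
    state_names: list[str]
    events: list[tuple[int, float, float]] = field(default_factory=list)
    high_outcomes: list[str] = field(default_factory=list)

    def occupancy(self) -> np.ndarray:
        """Time-average occupancy of each state."""
        occ = np.zeros(len(self.state_names))
        for s, t0, t1 in self.events:
            occ[s] += t1 - t0
        return occ / self.duration

    def dwell_times(self, state: int, interior_only: bool = True) -> np.ndarray:
        """Dwell durations in ``state``; optionally drop edge-censored visits."""
        out = []
        for k, (s, t0, t1) in enumerate(self.events):
            if s != state:
                continue
            if interior_only and (t0 == 0.0 or t1 >= self.duration):
                continue
            out.append(t1 - t0)
        return np.asarray(out)


def simulate_state_path(scheme: KineticScheme, duration: float,
                        rng: np.random.Generator | int | None = None,
                        molecule_id: int = 0) -> StatePathTruth:
    """Simulate one exact continuous-time Markov path of length ``duration``.

    An absorbing state simply holds until the end of the window (single
    event). The high-FRET-visit outcome labels are derived from the successor
    state: lower-FRET emitting -> ``to_low``, dark -> ``to_dark``, truncated
    by the window -> ``censored``.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    rng = np.random.default_rng(rng)
    q = scheme.rates.copy()
    np.fill_diagonal(q, 0.0)
    exit_rates = q.sum(axis=1)
    high = scheme.high_state
    high_mean = scheme.fret_mean[high]

    path = StatePathTruth(molecule_id=molecule_id, duration=duration,
                          state_names=list(scheme.state_names))
    s = scheme.index(scheme.initial_state)
    t = 0.0
    while t < duration:
        r = exit_rates[s]
        if r <= 0:                      # absorbing
            t_end, nxt = duration, None
        else:
            dt = rng.exponential(1.0 / r)
            if t + dt >= duration:
                t_end, nxt = duration, None
            else:
                t_end = t + dt
                nxt = int(rng.choice(scheme.n_states, p=q[s] / r))
        path.events.append((s, t, t_end))
        if s == high:
            if nxt is None:
                path.high_outcomes.append(OUTCOME_CENSORED)
            elif scheme.is_emitting(nxt) and scheme.fret_mean[nxt] < high_mean:
                path.high_outcomes.append(OUTCOME_TO_LOW)
            else:
                path.high_outcomes.append(OUTCOME_TO_DARK)
        if nxt is None:
            break
        s, t = nxt, t_end
    return path


def simulate_paths(scheme: KineticScheme, duration: float, n_molecules: int,
                   rng: np.random.Generator | int | None = None) -> list[StatePathTruth]:
    """Simulate independent paths for ``n_molecules`` molecules."""
    rng = np.random.default_rng(rng)
    return [simulate_state_path(scheme, duration, rng, molecule_id=i)
            for i in range(n_molecules)]
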