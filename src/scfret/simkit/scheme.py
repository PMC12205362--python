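"""Continuous-time Markov schemes with per-state FRET emission parameters.

A :class:`KineticScheme` is the generator of a labelled continuous-time Markov
chain. Off-diagonal entries of ``rates`` are transition rate constants in
s^-1; the diagonal is defined implicitly as the negative row sum. Each state
carries either a FRET emission (mean efficiency and width in E-units) or is
"dark" (no donor signal: unbound labelled protein, or a bleached dye).

Presets mirror the two experimental systems:

* Cas9 R-loop dynamics on a dual-labelled protospacer: a wound (high-FRET)
  and an unwound / R-loop (low-FRET) state interconverting with unwinding
  rate k1 and rewinding rate k-1.
* MutS mismatch binding: a dark unbound state, a mismatch-bound high-FRET
  state, and (with ATP) a low-FRET sliding-clamp state entered at rate k2 in
  competition with dissociation at rate k-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..exceptions import InvalidParameterError

#: Marker for non-emitting states in ``fret_mean``.
DARK = None


@dataclass
class KineticScheme:
    state_names: list[str]
    rates: np.ndarray              # (n, n) off-diagonal transition rates, s^-1
    fret_mean: list[float | None]  # per state; None marks a dark state
    fret_sd: list[float | None]    # per state; E-units, > 0 for emitting states
    initial_state: str | None = None

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        n = len(self.state_names)
        if n == 0:
            raise InvalidParameterError("scheme must have at least one state")
        if self.rates.shape != (n, n):
            raise InvalidParameterError(
                f"rates must be {n}x{n}, got {self.rates.shape}")
        off = self.rates[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise InvalidParameterError("off-diagonal rates must be >= 0")
        if all(m is None for m in self.fret_mean):
            raise InvalidParameterError("scheme needs at least one emitting state")
        for name, m, s in zip(self.state_names, self.fret_mean, self.fret_sd):
            if m is not None:
                if not (0.0 <= m <= 1.0):
                    raise InvalidParameterError(
                        f"fret_mean of state {name!r} must lie in [0, 1]")
                if s is None or s <= 0:
                    raise InvalidParameterError(
                        f"fret_sd of emitting state {name!r} must be > 0")
        if self.initial_state is None:
            self.initial_state = self.state_names[0]
        if self.initial_state not in self.state_names:
            raise InvalidParameterError(
                f"unknown initial state {self.initial_state!r}")

    # -- convenience ------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return self.state_names.index(name)

    @property
    def generator(self) -> np.ndarray:
        """Generator matrix Q: off-diagonal rates, diagonal = -row sum."""
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def exit_rate(self, i: int) -> float:
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        return float(q[i].sum())

    def is_emitting(self, i: int) -> bool:
        return self.fret_mean[i] is not None

    @property
    def high_state(self) -> int:
        """Index of the emitting state with the highest FRET mean."""
        means = [(-1.0 if m is None else m) for m in self.fret_mean]
        return int(np.argmax(means))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def two_state_scheme(k_high_to_low: float, k_low_to_high: float,
                     e_high: float = 0.60, e_low: float = 0.35,
                     sd: float = 0.06, initial: str = "high") -> KineticScheme:
    """Generic two-emitting-state interconversion scheme."""
    return KineticScheme(
        state_names=["low", "high"],
        rates=np.array([[0.0, k_low_to_high], [k_high_to_low, 0.0]]),
        fret_mean=[e_low, e_high],
        fret_sd=[sd, sd],
        initial_state=initial,
    )


def cas9_distal_mm_scheme(k_unwind: float = 0.9, k_rewind: float = 0.4,
                          e_wound: float = 0.60, e_unwound: float = 0.35,
                          sd: float = 0.06) -> KineticScheme:
    """R-loop breathing with a PAM-distal triple mismatch.

    The wound protospacer is high FRET; the unwound R-loop is low FRET.
    Defaults are the nicked-plasmid rates (k1 ~ 0.9 s^-1, k-1 ~ 0.4 s^-1).
    """
    return KineticScheme(
        state_names=["unwound", "wound"],
        rates=np.array([[0.0, k_rewind], [k_unwind, 0.0]]),
        fret_mean=[e_unwound, e_wound],
        fret_sd=[sd, sd],
        initial_state="wound",
    )


def muts_adp_scheme(k_on: float = 0.06, k_off: float = 0.204,
                    e_bound: float = 0.75, sd: float = 0.08) -> KineticScheme:
    """MutS + ADP: repetitive mismatch binding without clamp formation.

    The unbound state is dark (the donor is on the protein, outside the
    evanescent field); binding produces high FRET to the DNA acceptor.
    Default k_off is the relaxed-circular value (0.204 s^-1).
    """
    return KineticScheme(
        state_names=["unbound", "bound"],
        rates=np.array([[0.0, k_on], [k_off, 0.0]]),
        fret_mean=[DARK, e_bound],
        fret_sd=[None, sd],
        initial_state="unbound",
    )


def muts_atp_scheme(k1: float = 0.05, k_minus1: float = 0.3, k2: float = 0.1,
                    k_clamp_exit: float = 0.5,
                    e_bound: float = 0.75, e_clamp: float = 0.25,
                    sd: float = 0.08) -> KineticScheme:
    """MutS + ATP: mismatch binding branching to sliding-clamp formation.

    unbound --k1--> bound(high FRET); bound --k-1--> unbound (dissociation)
    in competition with bound --k2--> clamp(low FRET); the clamp slides away
    or dissociates (dark) at ``k_clamp_exit``. The high-FRET exit rate is
    k = k-1 + k2 and the branch ratio N2/N-1 equals k2/k-1.
    """
    rates = np.zeros((3, 3))
    names = ["unbound", "bound", "clamp"]
    rates[0, 1] = k1
    rates[1, 0] = k_minus1
    rates[1, 2] = k2
    rates[2, 0] = k_clamp_exit
    return KineticScheme(
        state_names=names,
        rates=rates,
        fret_mean=[DARK, e_bound, e_clamp],
        fret_sd=[None, sd, sd],
        initial_state="unbound",
    )


SCHEME_PRESETS = {
    "cas9_distal_mm": cas9_distal_mm_scheme,
    "muts_adp": muts_adp_scheme,
    "muts_atp": muts_atp_scheme,
}
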