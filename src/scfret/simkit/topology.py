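"""Supercoiling bookkeeping: linking number and superhelical density.

For a closed circular duplex of ``length_bp`` base pairs with helical repeat
``helical_repeat`` (bp/turn), the relaxed linking number is
``Lk0 = length_bp / helical_repeat`` and the superhelical density is

    sigma = dLk / Lk0

where ``dLk = Lk - Lk0`` is the linking-number change introduced by a
topoisomerase (gyrase for negative, reverse gyrase for positive supercoils).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..exceptions import InvalidParameterError

#: Canonical B-DNA helical repeat used when none is given (bp/turn).
DEFAULT_HELICAL_REPEAT = 10.5

#: Plasmid length used throughout the presets (bp).
DEFAULT_PLASMID_LENGTH_BP = 2800


def superhelical_density(delta_Lk: float, length_bp: float,
                         helical_repeat: float = DEFAULT_HELICAL_REPEAT) -> float:
    """Return sigma = dLk / Lk0 with Lk0 = length_bp / helical_repeat.

    Parameters
    ----------
    delta_Lk :
        Linking-number change relative to the relaxed topoisomer (turns).
    length_bp :
        Duplex length in base pairs; must be positive.
    helical_repeat :
        Helical repeat in bp/turn; must be positive.
    """
    if length_bp <= 0:
        raise InvalidParameterError(f"length_bp must be > 0, got {length_bp}")
    if helical_repeat <= 0:
        raise InvalidParameterError(f"helical_repeat must be > 0, got {helical_repeat}")
    lk0 = length_bp / helical_repeat
    return delta_Lk / lk0


@dataclass(frozen=True)
class TopologyCondition:
    """A labelled plasmid topology state.

    ``sigma`` is always derived from ``delta_Lk`` so the invariant
    ``sigma == delta_Lk / Lk0`` holds by construction.
    """

    label: str                      # one of: neg_sc, relaxed, nicked, pos_sc
    length_bp: int = DEFAULT_PLASMID_LENGTH_BP
    helical_repeat: float = DEFAULT_HELICAL_REPEAT
    delta_Lk: float = 0.0
    sigma: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(
            self, "sigma",
            superhelical_density(self.delta_Lk, self.length_bp, self.helical_repeat),
        )


def topology_presets() -> dict[str, TopologyCondition]:
    """Measured average topologies of the plasmid conditions.

    The supercoiled densities are the 2D-gel estimates (sigma = -0.07 and
    +0.03); relaxed and nicked plasmids are torsionally relaxed controls.
    Labels carry no mechanistic consequence for simulated kinetics — users
    supply per-condition rate constants.
    """
    lk0 = DEFAULT_PLASMID_LENGTH_BP / DEFAULT_HELICAL_REPEAT
    return {
        "neg_sc": TopologyCondition("neg_sc", delta_Lk=-0.07 * lk0),
        "relaxed": TopologyCondition("relaxed", delta_Lk=0.0),
        "nicked": TopologyCondition("nicked", delta_Lk=0.0),
        "pos_sc": TopologyCondition("pos_sc", delta_Lk=+0.03 * lk0),
    }
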