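"""Snapshot time-course generator for the R-loop formation assay.

Emulates the proximal-mismatch unwinding experiment: at each incubation
time t after adding the Cas9 ribonucleoprotein, short [10 green | 10 red]
snapshot movies are recorded and each molecule is effectively static during
the 0.5 s snapshot. The probability that a molecule has been unwound by
time t follows the one-phase association law

    p(t) = y0 + (plateau - y0) * (1 - exp(-k t)),

i.e. unwinding is quasi-irreversible with rate k and a fraction
(1 - plateau) of molecules never converts. A small "residual" low-FRET
subpopulation (weakly transferring molecules that nevertheless pass the
acceptor check) makes the FRET histograms genuinely three-component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..containers import TraceSet
from .gillespie import StatePathTruth
from .photophysics import AcquisitionParams, PhotophysicsParams, acquisition_presets
from .scheme import KineticScheme
from .traces import render_traces

#: Default snapshot emission parameters (E-units).
E_WOUND = 0.62
E_UNWOUND = 0.30
E_RESIDUAL = 0.05
SNAPSHOT_SD = 0.05
RESIDUAL_FRACTION = 0.06


@dataclass(frozen=True)
class UnwindingCondition:
    """One topology condition of the unwinding time course."""

    label: str
    k_per_min: float      # one-phase association rate constant (min^-1)
    plateau: float        # long-time unwound fraction
    y0: float = 0.02      # unwound fraction before enzyme addition


def unwinding_presets() -> dict[str, UnwindingCondition]:
    """Per-topology unwinding kinetics.

    Plateaus are the measured long-time unwound fractions (0.79 / 0.76 /
    0.50 for negatively supercoiled / nicked / positively supercoiled DNA);
    the rate constants keep the measured ratios (negative supercoiling
    about two-fold faster than nicked and three-fold faster than positive).
    """
    return {
        "neg_sc": UnwindingCondition("neg_sc", k_per_min=0.60, plateau=0.79),
        "nicked": UnwindingCondition("nicked", k_per_min=0.30, plateau=0.76),
        "pos_sc": UnwindingCondition("pos_sc", k_per_min=0.20, plateau=0.50),
    }


#: Incubation time points (minutes) of the snapshot series.
DEFAULT_TIME_POINTS_MIN = (1, 2, 3, 4, 7, 10, 13, 20, 30, 45, 60)


def unwound_probability(t_min: float, cond: UnwindingCondition) -> float:
    return cond.y0 + (cond.plateau - cond.y0) * (1.0 - np.exp(-cond.k_per_min * t_min))


def _snapshot_scheme(sd: float = SNAPSHOT_SD) -> KineticScheme:
    return KineticScheme(
        state_names=["residual", "unwound", "wound"],
        rates=np.zeros((3, 3)),
        fret_mean=[E_RESIDUAL, E_UNWOUND, E_WOUND],
        fret_sd=[sd, sd, sd],
    )


def simulate_snapshot(cond: UnwindingCondition, t_min: float, n_molecules: int,
                      phys: PhotophysicsParams | None = None,
                      acq: AcquisitionParams | None = None,
                      rng: np.random.Generator | int | None = None,
                      residual_fraction: float = RESIDUAL_FRACTION) -> TraceSet:
    """Render one snapshot TraceSet at incubation time ``t_min`` minutes."""
    rng = np.random.default_rng(rng)
    phys = phys or PhotophysicsParams()
    acq = acq or acquisition_presets()["cas9_proximal_mm"]
    scheme = _snapshot_scheme()
    p_unwound = unwound_probability(t_min, cond)
    u = rng.random(n_molecules)
    # residual molecules are a fixed side population; the rest split
    # wound/unwound by the association law
    states = np.where(u < residual_fraction, 0,
                      np.where(rng.random(n_molecules) < p_unwound, 1, 2))
    paths = []
    for i, s in enumerate(states):
        p = StatePathTruth(molecule_id=i, duration=acq.duration,
                           state_names=list(scheme.state_names))
        p.events.append((int(s), 0.0, acq.duration))
        paths.append(p)
    ts = render_traces(paths, scheme, phys, acq, rng)
    ts.truth["snapshot_states"] = states
    ts.truth["t_min"] = t_min
    ts.truth["p_unwound"] = p_unwound
    return ts


def simulate_timecourse(cond: UnwindingCondition,
                        time_points_min=DEFAULT_TIME_POINTS_MIN,
                        n_molecules_per_point: int = 500,
                        phys: PhotophysicsParams | None = None,
                        acq: AcquisitionParams | None = None,
                        rng: np.random.Generator | int | None = None,
                        ) -> list[tuple[float, TraceSet]]:
    """Simulate the full snapshot series of one condition."""
    rng = np.random.default_rng(rng)
    return [(float(t), simulate_snapshot(cond, t, n_molecules_per_point,
                                         phys, acq, rng))
            for t in time_points_min]
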