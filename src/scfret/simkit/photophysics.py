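"""Noise, bleaching and acquisition parameters for the trace simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..exceptions import ConfigurationError, InvalidParameterError


@dataclass(frozen=True)
class PhotophysicsParams:
    """Camera/dye noise model.

    ``total_emission`` is the summed two-channel signal of one molecule per
    frame (counts). ``leakage`` is the fraction of donor photons detected in
    the acceptor channel. Bleaching is exponential, one-way, per dye; an
    inactive acceptor (dark from the start) occurs with probability
    ``inactive_acceptor_fraction``.
    """

    total_emission: float = 1000.0
    background_mean: float = 100.0
    noise_sd: float = 50.0
    donor_bleach_rate: float = 0.0       # s^-1
    acceptor_bleach_rate: float = 0.0    # s^-1
    inactive_acceptor_fraction: float = 0.0
    leakage: float = 0.0

    def __post_init__(self):
        for name in ("total_emission", "background_mean", "noise_sd",
                     "donor_bleach_rate", "acceptor_bleach_rate"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.inactive_acceptor_fraction <= 1.0:
            raise InvalidParameterError("inactive_acceptor_fraction must be in [0, 1]")
        if not 0.0 <= self.leakage < 1.0:
            raise InvalidParameterError("leakage must be in [0, 1)")


@dataclass(frozen=True)
class AcquisitionParams:
    """Frame time, excitation schedule and field layout."""

    frame_time: float                                  # s
    schedule: tuple[tuple[str, int], ...]              # ((excitation, n_frames), ...)
    n_fields: int = 1
    molecules_per_field: int = 200

    def __post_init__(self):
        if self.frame_time <= 0:
            raise InvalidParameterError("frame_time must be > 0")
        if not self.schedule:
            raise ConfigurationError("schedule must be non-empty")
        object.__setattr__(self, "schedule",
                           tuple((str(e), int(n)) for e, n in self.schedule))
        for exc, n in self.schedule:
            if n <= 0:
                raise ConfigurationError("schedule block lengths must be > 0")

    @property
    def n_frames(self) -> int:
        return sum(n for _, n in self.schedule)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_time


def acquisition_presets() -> dict[str, AcquisitionParams]:
    """Acquisition layouts of the four experiment types.

    * ``cas9_proximal_mm`` — 50 ms snapshots: 10 green frames (FRET) then
      10 red frames (acceptor check), captured repeatedly over an
      incubation time course.
    * ``cas9_distal_mm`` — 50 ms long movies: 10 red | 980 green | 10 red.
    * ``muts_adp`` — 200 ms long movies: 10 red | 980 green | 10 red.
    * ``muts_atp`` — 50 ms long movies: 10 red | 1480 green | 10 red.
    """
    return {
        "cas9_proximal_mm": AcquisitionParams(
            0.050, (("green", 10), ("red", 10)), n_fields=10,
            molecules_per_field=480),
        "cas9_distal_mm": AcquisitionParams(
            0.050, (("red", 10), ("green", 980), ("red", 10)), n_fields=5),
        "muts_adp": AcquisitionParams(
            0.200, (("red", 10), ("green", 980), ("red", 10)), n_fields=3),
        "muts_atp": AcquisitionParams(
            0.050, (("red", 10), ("green", 1480), ("red", 10)), n_fields=3),
    }
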