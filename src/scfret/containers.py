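"""Shared in-memory containers passed between pipeline stages.

``TraceSet`` holds per-molecule two-channel intensity time series plus the
excitation schedule; it is produced either by the simulator
(:func:`scfret.simkit.render_traces`) or by trace extraction from image
stacks (:func:`scfret.imaging.extract_traces`), with an identical on-disk
TSV schema so downstream modules are source-agnostic.

``FretSeries`` holds per-molecule FRET-efficiency series over the
green-excitation frames together with a validity mask (False after donor
bleach / during dark intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

EXC_GREEN = "green"
EXC_RED = "red"


def expand_schedule(schedule: list[tuple[str, int]]) -> np.ndarray:
    """Expand a [(excitation, n_frames), ...] schedule to a per-frame array."""
    if not schedule:
        raise ConfigurationError("excitation schedule is empty")
    parts = []
    for exc, n in schedule:
        if exc not in (EXC_GREEN, EXC_RED):
            raise ConfigurationError(f"unknown excitation {exc!r}")
        if n <= 0:
            raise ConfigurationError("schedule block lengths must be > 0")
        parts.append(np.full(int(n), exc, dtype=object))
    return np.concatenate(parts).astype("U5")


@dataclass
class TraceSet:
    """Two-channel intensity traces for a set of molecules.

    ``donor``/``acceptor`` are (n_molecules, n_frames) arrays of raw
    (background-containing) intensities in counts/frame. ``background`` is
    the known or estimated mean background level per channel, subtracted by
    FRET computation. ``truth`` optionally carries simulator ground truth.
    """

    frame_time: float
    excitation: np.ndarray            # (n_frames,) "green" | "red"
    donor: np.ndarray                 # (n_molecules, n_frames)
    acceptor: np.ndarray              # (n_molecules, n_frames)
    molecule_ids: np.ndarray | None = None
    background: tuple[float, float] = (0.0, 0.0)   # (donor, acceptor)
    truth: dict | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor = np.atleast_2d(np.asarray(self.donor, dtype=float))
        self.acceptor = np.atleast_2d(np.asarray(self.acceptor, dtype=float))
        self.excitation = np.asarray(self.excitation)
        if self.donor.shape != self.acceptor.shape:
            raise ConfigurationError("donor/acceptor shapes differ")
        if self.donor.shape[1] != self.excitation.size:
            raise ConfigurationError(
                f"{self.donor.shape[1]} frames but schedule has "
                f"{self.excitation.size}")
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(self.donor.shape[0])
        self.molecule_ids = np.asarray(self.molecule_ids)

    @property
    def n_molecules(self) -> int:
        return self.donor.shape[0]

    @property
    def n_frames(self) -> int:
        return self.donor.shape[1]

    @property
    def time_s(self) -> np.ndarray:
        """Frame-start times in seconds."""
        return np.arange(self.n_frames) * self.frame_time

    @property
    def green_frames(self) -> np.ndarray:
        return np.flatnonzero(self.excitation == EXC_GREEN)

    @property
    def red_frames(self) -> np.ndarray:
        return np.flatnonzero(self.excitation == EXC_RED)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        n_mol, n_fr = self.donor.shape
        return pd.DataFrame({
            "molecule_id": np.repeat(self.molecule_ids, n_fr),
            "frame": np.tile(np.arange(n_fr), n_mol),
            "time_s": np.tile(self.time_s, n_mol),
            "excitation": np.tile(self.excitation, n_mol),
            "I_donor": self.donor.ravel(),
            "I_acceptor": self.acceptor.ravel(),
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path, frame_time: float | None = None,
                 background: tuple[float, float] = (0.0, 0.0)) -> "TraceSet":
        df = pd.read_csv(path, sep="\t")
        ids = df["molecule_id"].unique()
        first = df[df["molecule_id"] == ids[0]].sort_values("frame")
        excitation = first["excitation"].to_numpy().astype("U5")
        if frame_time is None:
            t = first["time_s"].to_numpy()
            frame_time = float(np.median(np.diff(t))) if t.size > 1 else 1.0
        n_fr = len(first)
        piv = df.sort_values(["molecule_id", "frame"])
        donor = piv["I_donor"].to_numpy().reshape(len(ids), n_fr)
        acceptor = piv["I_acceptor"].to_numpy().reshape(len(ids), n_fr)
        return cls(frame_time=frame_time, excitation=excitation, donor=donor,
                   acceptor=acceptor, molecule_ids=ids, background=background)


@dataclass
class FretSeries:
    """FRET efficiency per molecule over the green-excitation frames.

    ``E`` and ``valid`` are (n_molecules, n_green_frames); invalid frames
    (dark, post-bleach, or zero total intensity) hold E = NaN.
    """

    E: np.ndarray
    valid: np.ndarray
    frame_time: float
    molecule_ids: np.ndarray | None = None
    time_s: np.ndarray | None = None     # times of the green frames

    def __post_init__(self):
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.valid = np.atleast_2d(np.asarray(self.valid, dtype=bool))
        if self.E.shape != self.valid.shape:
            raise ConfigurationError("E/valid shapes differ")
        if self.molecule_ids is None:
            self.molecule_ids = np.arange(self.E.shape[0])
        self.molecule_ids = np.asarray(self.molecule_ids)
        if self.time_s is None:
            self.time_s = np.arange(self.E.shape[1]) * self.frame_time

    @property
    def n_molecules(self) -> int:
        return self.E.shape[0]

    @property
    def n_frames(self) -> int:
        return self.E.shape[1]

    def subset(self, keep: np.ndarray) -> "FretSeries":
        keep = np.asarray(keep)
        return FretSeries(self.E[keep], self.valid[keep], self.frame_time,
                          molecule_ids=self.molecule_ids[keep],
                          time_s=self.time_s)
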