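"""Render ground-truth state paths into two-channel fluorescence traces.

Within a frame the emitted signal is the exposure-time-weighted average over
the states visited (camera integration / motion blur), so transitions
produce realistic mid-FRET frames. Under green excitation the total
emission of the occupied emitting state(s) is partitioned between donor and
acceptor channels by the occupancy-weighted FRET mean; a dark or bleached
acceptor returns all photons to the donor channel (apart from spectral
leakage). Under red excitation the acceptor is probed directly, which is
what the acceptor-activity filter uses downstream.

Bleaching is modelled per dye as a one-way exponential transition to a dark
state on the wall clock; after donor bleach both channels fall to
background under green excitation.

``simulate_fret_series`` is the corresponding direct E-level generator: it
skips the photon model and draws per-frame FRET values from the per-state
emission distributions (``fret_mean`` +/- ``fret_sd``), which is convenient
for testing idealization at a prescribed E-domain width.
"""

from __future__ import annotations

import numpy as np

from ..containers import EXC_GREEN, FretSeries, TraceSet, expand_schedule
from ..exceptions import ConfigurationError
from .gillespie import StatePathTruth, simulate_paths
from .photophysics import AcquisitionParams, PhotophysicsParams
from .scheme import KineticScheme


def _frame_occupancy(path: StatePathTruth, scheme: KineticScheme,
                     n_frames: int, dt: float):
    """Per-frame emitting occupancy and occupancy-weighted FRET mean."""
    e_occ = np.zeros(n_frames)     # fraction of frame in an emitting state
    e_wsum = np.zeros(n_frames)    # occupancy-weighted sum of fret_mean
    v_wsum = np.zeros(n_frames)    # occupancy-weighted sum of fret variance
    for s, t0, t1 in path.events:
        if not scheme.is_emitting(s):
            continue
        f0 = max(0, int(t0 / dt))
        f1 = min(n_frames - 1, int(np.ceil(t1 / dt)) - 1)
        if f1 < f0:
            continue
        fr = np.arange(f0, f1 + 1)
        ov = np.minimum(t1, (fr + 1) * dt) - np.maximum(t0, fr * dt)
        ov = np.clip(ov, 0.0, None) / dt
        e_occ[fr] += ov
        e_wsum[fr] += ov * scheme.fret_mean[s]
        v_wsum[fr] += ov * scheme.fret_sd[s] ** 2
    return e_occ, e_wsum, v_wsum


def _live_fraction(n_frames: int, dt: float, t_bleach: float) -> np.ndarray:
    """Fraction of each frame before the bleach time."""
    if not np.isfinite(t_bleach):
        return np.ones(n_frames)
    edges = np.arange(n_frames + 1) * dt
    return np.clip((t_bleach - edges[:-1]) / dt, 0.0, 1.0)


def render_traces(paths: list[StatePathTruth], scheme: KineticScheme,
                  phys: PhotophysicsParams, acq: AcquisitionParams,
                  rng: np.random.Generator | int | None = None) -> TraceSet:
    """Render state paths into a noisy two-channel :class:`TraceSet`."""
    rng = np.random.default_rng(rng)
    excitation = expand_schedule(list(acq.schedule))
    n_frames = excitation.size
    dt = acq.frame_time
    duration = n_frames * dt
    for p in paths:
        if p.duration < duration - 1e-9:
            raise ConfigurationError(
                f"path of molecule {p.molecule_id} covers {p.duration:.3f} s "
                f"but the schedule implies {duration:.3f} s")

    n_mol = len(paths)
    donor = np.zeros((n_mol, n_frames))
    acceptor = np.zeros((n_mol, n_frames))
    green = excitation == EXC_GREEN
    red = ~green

    # per-molecule photophysics draws (consumed in a fixed order for
    # seed-reproducibility)
    acc_active = rng.random(n_mol) >= phys.inactive_acceptor_fraction
    t_donor = (rng.exponential(1.0 / phys.donor_bleach_rate, n_mol)
               if phys.donor_bleach_rate > 0 else np.full(n_mol, np.inf))
    t_acc = (rng.exponential(1.0 / phys.acceptor_bleach_rate, n_mol)
             if phys.acceptor_bleach_rate > 0 else np.full(n_mol, np.inf))

    for i, p in enumerate(paths):
        e_occ, e_wsum, _ = _frame_occupancy(p, scheme, n_frames, dt)
        ld = _live_fraction(n_frames, dt, t_donor[i])
        la = _live_fraction(n_frames, dt, t_acc[i]) * acc_active[i]

        s_tot = phys.total_emission * e_occ * ld       # emitted under green
        ebar = np.divide(e_wsum, e_occ, out=np.zeros(n_frames),
                         where=e_occ > 0)
        a_sig = s_tot * ebar * la                      # transferred photons
        d_sig = s_tot - a_sig
        donor[i, green] = d_sig[green]
        acceptor[i, green] = (a_sig + phys.leakage * d_sig)[green]
        # direct acceptor excitation; donor channel sees background only
        acceptor[i, red] = (phys.total_emission * la)[red]

    donor += phys.background_mean
    acceptor += phys.background_mean
    if phys.noise_sd > 0:
        donor += rng.normal(0.0, phys.noise_sd, donor.shape)
        acceptor += rng.normal(0.0, phys.noise_sd, acceptor.shape)

    truth = {
        "paths": paths,
        "acceptor_active": acc_active,
        "t_donor_bleach": t_donor,
        "t_acceptor_bleach": t_acc,
        "phys": phys,
        "acq": acq,
    }
    return TraceSet(frame_time=dt, excitation=excitation, donor=donor,
                    acceptor=acceptor,
                    molecule_ids=np.array([p.molecule_id for p in paths]),
                    background=(phys.background_mean, phys.background_mean),
                    truth=truth)


def simulate_traceset(scheme: KineticScheme, phys: PhotophysicsParams,
                      acq: AcquisitionParams, n_molecules: int,
                      rng: np.random.Generator | int | None = None) -> TraceSet:
    """Gillespie paths + photon rendering in one call (shared seed stream)."""
    rng = np.random.default_rng(rng)
    paths = simulate_paths(scheme, acq.duration, n_molecules, rng)
    return render_traces(paths, scheme, phys, acq, rng)


def simulate_fret_series(scheme: KineticScheme, frame_time: float,
                         n_frames: int, n_molecules: int,
                         rng: np.random.Generator | int | None = None,
                         min_emitting_fraction: float = 0.5,
                         ) -> tuple[FretSeries, list[StatePathTruth]]:
    """Direct E-level trajectories: state path -> per-frame FRET values.

    Each frame's E is the occupancy-weighted state mean plus Gaussian noise
    of the occupancy-weighted emission width. Frames spending less than
    ``min_emitting_fraction`` of the exposure in an emitting state are
    masked (dark).
    """
    rng = np.random.default_rng(rng)
    duration = n_frames * frame_time
    paths = simulate_paths(scheme, duration, n_molecules, rng)
    E = np.full((n_molecules, n_frames), np.nan)
    valid = np.zeros((n_molecules, n_frames), dtype=bool)
    for i, p in enumerate(paths):
        e_occ, e_wsum, v_wsum = _frame_occupancy(p, scheme, n_frames, frame_time)
        ok = e_occ >= min_emitting_fraction
        ebar = np.divide(e_wsum, e_occ, out=np.zeros(n_frames), where=ok)
        esd = np.sqrt(np.divide(v_wsum, e_occ, out=np.zeros(n_frames), where=ok))
        E[i, ok] = ebar[ok] + rng.normal(0.0, 1.0, ok.sum()) * esd[ok]
        valid[i, ok] = True
    series = FretSeries(E=E, valid=valid, frame_time=frame_time)
    return series, paths
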