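"""Render trace sets into two-channel TIRF-style image stacks.

Each molecule is drawn as a pixel-integrated 2D Gaussian point-spread
function whose integral per frame equals the molecule's (background-free)
trace intensity in that channel. The acceptor channel is related to the
donor channel by a known affine map, emulating a dual-view optical layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import erf

from ..containers import TraceSet
from ..exceptions import ConfigurationError, InvalidParameterError


@dataclass(frozen=True)
class MovieGeometry:
    field_size: int = 128          # pixels (square field)
    psf_sd: float = 1.2            # pixels
    margin: float = 8.0            # keep-out border, pixels
    min_separation: float = 6.0    # pixels, between molecule centres
    # affine map donor -> acceptor channel: x' = A @ x + b
    channel_matrix: tuple = ((1.0, 0.0), (0.0, 1.0))
    channel_offset: tuple = (1.5, -0.8)


def place_molecules(n: int, geom: MovieGeometry,
                    rng: np.random.Generator | int | None = None,
                    max_tries: int = 20000) -> np.ndarray:
    """Random (x, y) positions with a minimum pairwise separation."""
    rng = np.random.default_rng(rng)
    lo, hi = geom.margin, geom.field_size - geom.margin
    if hi <= lo:
        raise InvalidParameterError("field too small for the margin")
    pos = np.empty((0, 2))
    tries = 0
    while len(pos) < n:
        tries += 1
        if tries > max_tries:
            raise InvalidParameterError(
                f"could not place {n} molecules at min_separation="
                f"{geom.min_separation} in a {geom.field_size} px field")
        cand = rng.uniform(lo, hi, size=2)
        if len(pos) and np.min(np.hypot(*(pos - cand).T)) < geom.min_separation:
            continue
        pos = np.vstack([pos, cand])
    return pos


def _add_spot(img: np.ndarray, x: float, y: float, amp: float, sd: float):
    """Add a pixel-integrated Gaussian of total intensity ``amp`` at (x, y).

    Pixel (i, j) spans [j-0.5, j+0.5] x [i-0.5, i+0.5] in (x, y): 0-based,
    pixel-centre coordinate convention.
    """
    if amp <= 0:
        return
    r = int(np.ceil(4 * sd)) + 1
    h, w = img.shape
    ix, iy = int(round(x)), int(round(y))
    xs = np.arange(max(0, ix - r), min(w, ix + r + 1))
    ys = np.arange(max(0, iy - r), min(h, iy + r + 1))
    if xs.size == 0 or ys.size == 0:
        return
    s2 = sd * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x) / s2) - erf((xs - 0.5 - x) / s2))
    fy = 0.5 * (erf((ys + 0.5 - y) / s2) - erf((ys - 0.5 - y) / s2))
    img[np.ix_(ys, xs)] += amp * np.outer(fy, fx)


def render_movie(traces: TraceSet, geom: MovieGeometry | None = None,
                 rng: np.random.Generator | int | None = None,
                 background_mean: float = 100.0, noise_sd: float = 10.0,
                 positions: np.ndarray | None = None):
    """Render a :class:`TraceSet` into donor/acceptor image stacks.

    Returns ``(stack_donor, stack_acceptor, positions)`` where positions are
    the donor-channel molecule centres; acceptor-channel centres follow the
    affine channel map in ``geom``. Trace backgrounds are removed before
    rendering so the spot integral equals the molecule signal, on top of an
    independent pixel background.
    """
    geom = geom or MovieGeometry()
    rng = np.random.default_rng(rng)
    n_mol, n_frames = traces.donor.shape
    if positions is None:
        positions = place_molecules(n_mol, geom, rng)
    elif len(positions) != n_mol:
        raise ConfigurationError("positions/molecule count mismatch")

    A = np.asarray(geom.channel_matrix)
    b = np.asarray(geom.channel_offset)
    pos_acc = positions @ A.T + b

    shape = (n_frames, geom.field_size, geom.field_size)
    stack_d = np.zeros(shape, dtype=np.float32)
    stack_a = np.zeros(shape, dtype=np.float32)
    bg_d, bg_a = traces.background
    sig_d = np.clip(traces.donor - bg_d, 0.0, None)
    sig_a = np.clip(traces.acceptor - bg_a, 0.0, None)
    for f in range(n_frames):
        for i in range(n_mol):
            _add_spot(stack_d[f], positions[i, 0], positions[i, 1],
                      sig_d[i, f], geom.psf_sd)
            _add_spot(stack_a[f], pos_acc[i, 0], pos_acc[i, 1],
                      sig_a[i, f], geom.psf_sd)
    stack_d += background_mean
    stack_a += background_mean
    if noise_sd > 0:
        stack_d += rng.normal(0.0, noise_sd, shape).astype(np.float32)
        stack_a += rng.normal(0.0, noise_sd, shape).astype(np.float32)
    return stack_d, stack_a, positions


def write_movie_tiff(stack_donor: np.ndarray, stack_acceptor: np.ndarray,
                     outdir: str | Path, prefix: str = "movie") -> tuple[Path, Path]:
    """Write the two channels as frame-major multi-page TIFFs."""
    import tifffile
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p_d = outdir / f"{prefix}_donor.tif"
    p_a = outdir / f"{prefix}_acceptor.tif"
    tifffile.imwrite(p_d, np.asarray(stack_donor, dtype=np.float32))
    tifffile.imwrite(p_a, np.asarray(stack_acceptor, dtype=np.float32))
    return p_d, p_a
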