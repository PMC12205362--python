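"""Spot detection, channel registration and intensity-trace extraction.

A functional stand-in for interactive acquisition software: spots are local
maxima of a time-averaged image above a robust background threshold,
refined by centroid fitting; the acceptor channel is mapped onto the donor
channel by a least-squares affine transform; traces are aperture sums minus
a local annulus-median background. Pixel coordinates are 0-based with the
pixel-centre convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .containers import TraceSet
from .exceptions import ConfigurationError, DegenerateGeometryError


def robust_background(img: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based sigma of an image's background."""
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med, 1.4826 * mad


def _centroid_refine(img: np.ndarray, y: int, x: int, radius: int = 3,
                     floor: float = 0.0) -> tuple[float, float]:
    """Background-subtracted centre of mass in a small window around (y, x)."""
    h, w = img.shape
    y0, y1 = max(0, y - radius), min(h, y + radius + 1)
    x0, x1 = max(0, x - radius), min(w, x + radius + 1)
    win = img[y0:y1, x0:x1] - floor
    win = np.clip(win, 0.0, None)
    tot = win.sum()
    if tot <= 0:
        return float(y), float(x)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    return float((ys * win).sum() / tot), float((xs * win).sum() / tot)


def detect_spots(avg_image: np.ndarray, threshold_sigmas: float = 5.0,
                 min_separation: float = 4.0) -> pd.DataFrame:
    """Detect single-molecule spots on a time-averaged image.

    Returns a DataFrame with columns ``x, y, amplitude, background``;
    empty (never an error) for constant or empty images.
    """
    avg_image = np.asarray(avg_image, dtype=float)
    if avg_image.size == 0:
        return pd.DataFrame(columns=["x", "y", "amplitude", "background"])
    bg, sd = robust_background(avg_image)
    if sd == 0:
        sd = float(avg_image.std())
    thr = bg + threshold_sigmas * sd
    if not np.any(avg_image > thr):
        return pd.DataFrame(columns=["x", "y", "amplitude", "background"])
    peaks = peak_local_max(avg_image, min_distance=max(1, int(round(min_separation))),
                           threshold_abs=thr, exclude_border=2)
    rows = []
    for y, x in peaks:
        yc, xc = _centroid_refine(avg_image, y, x, floor=bg)
        rows.append((xc, yc, float(avg_image[y, x] - bg), bg))
    df = pd.DataFrame(rows, columns=["x", "y", "amplitude", "background"])
    # enforce min_separation after sub-pixel refinement: greedy keep by
    # amplitude, drop any later spot within the exclusion radius
    df = df.sort_values("amplitude", ascending=False).reset_index(drop=True)
    keep: list[int] = []
    for i, row in df.iterrows():
        p = np.array([row.x, row.y])
        if all(np.hypot(*(p - df.loc[j, ["x", "y"]].to_numpy(dtype=float)))
               >= min_separation for j in keep):
            keep.append(i)
    return df.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class ChannelMap:
    """Affine map between channels: x' = matrix @ x + offset (pixels)."""

    matrix: np.ndarray
    offset: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise DegenerateGeometryError("channel map matrix is singular")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.atleast_2d(xy) @ self.matrix.T + self.offset

    @classmethod
    def identity(cls) -> "ChannelMap":
        return cls(np.eye(2), np.zeros(2))


def register_channels(spots_a: pd.DataFrame | np.ndarray,
                      spots_b: pd.DataFrame | np.ndarray) -> ChannelMap:
    """Least-squares affine map from matched spot pairs (a -> b).

    The two inputs must list the same molecules in the same order; at least
    3 non-collinear pairs are required.
    """
    def _xy(s):
        if isinstance(s, pd.DataFrame):
            return s[["x", "y"]].to_numpy(dtype=float)
        return np.asarray(s, dtype=float)

    a, b = _xy(spots_a), _xy(spots_b)
    if len(a) != len(b):
        raise DegenerateGeometryError("spot lists have different lengths")
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 matched pairs")
    centered = a - a.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateGeometryError("control points are collinear")
    design = np.column_stack([a, np.ones(len(a))])
    sol, *_ = np.linalg.lstsq(design, b, rcond=None)
    matrix = sol[:2].T
    offset = sol[2]
    resid = b - (a @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return ChannelMap(matrix, offset, rms)


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    m = dy ** 2 + dx ** 2 <= radius ** 2
    return np.column_stack([dy[m], dx[m]])


def _annulus_offsets(r_in: float, r_out: float) -> np.ndarray:
    r = int(np.ceil(r_out))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy ** 2 + dx ** 2
    m = (d2 > r_in ** 2) & (d2 <= r_out ** 2)
    return np.column_stack([dy[m], dx[m]])


def extract_traces(stack_donor: np.ndarray, stack_acceptor: np.ndarray,
                   spots: pd.DataFrame, channel_map: ChannelMap | None = None,
                   excitation: np.ndarray | None = None,
                   frame_time: float = 1.0, aperture: float = 2.0,
                   annulus: tuple[float, float] = (3.0, 5.0)) -> TraceSet:
    """Aperture-summed, annulus-background-subtracted traces per spot.

    ``spots`` are donor-channel positions; acceptor positions follow
    ``channel_map``. Spots whose aperture leaves the field are flagged in
    ``TraceSet.flags['off_field']`` rather than dropped.
    """
    channel_map = channel_map or ChannelMap.identity()
    stack_donor = np.asarray(stack_donor, dtype=float)
    stack_acceptor = np.asarray(stack_acceptor, dtype=float)
    if stack_donor.shape != stack_acceptor.shape:
        raise ConfigurationError("channel stacks differ in shape")
    n_frames, h, w = stack_donor.shape
    if excitation is None:
        excitation = np.full(n_frames, "green", dtype="U5")

    pos_d = spots[["x", "y"]].to_numpy(dtype=float)
    pos_a = channel_map.apply(pos_d)
    disk = _disk_offsets(aperture)
    ann = _annulus_offsets(*annulus)
    n_mol = len(pos_d)
    donor = np.zeros((n_mol, n_frames))
    acceptor = np.zeros((n_mol, n_frames))
    off_field = np.zeros(n_mol, dtype=bool)

    for i in range(n_mol):
        for stack, pos, out in ((stack_donor, pos_d, donor),
                                (stack_acceptor, pos_a, acceptor)):
            cx, cy = pos[i]
            iy, ix = int(round(cy)), int(round(cx))
            ys, xs = disk[:, 0] + iy, disk[:, 1] + ix
            ay, ax = ann[:, 0] + iy, ann[:, 1] + ix
            if (ys.min() < 0 or xs.min() < 0 or ys.max() >= h or xs.max() >= w):
                off_field[i] = True
                continue
            ain = (ay >= 0) & (ay < h) & (ax >= 0) & (ax < w)
            px = stack[:, ys, xs]                       # (n_frames, n_px)
            bg = np.median(stack[:, ay[ain], ax[ain]], axis=1)
            out[i] = px.sum(axis=1) - bg * len(ys)

    ts = TraceSet(frame_time=frame_time, excitation=excitation, donor=donor,
                  acceptor=acceptor, background=(0.0, 0.0))
    ts.flags["off_field"] = off_field
    return ts
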