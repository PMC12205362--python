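"""One-phase association fits of the unwound-fraction time course.

The fraction of unwound molecules after enzyme addition follows

    y(x) = y0 + (plateau - y0) * (1 - exp(-k x)),

with x the incubation time. All three parameters are free; weighting by
per-point standard errors is optional. Rate-constant ratios between
topology conditions are reported with first-order propagated errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InvalidParameterError


@dataclass
class TimeCourse:
    """f_unwound versus incubation time for one condition."""

    time: np.ndarray          # minutes unless noted in ``time_unit``
    f_unwound: np.ndarray
    se: np.ndarray | None = None
    condition: str = ""
    time_unit: str = "min"

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.f_unwound = np.asarray(self.f_unwound, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.f_unwound.size:
            raise InvalidParameterError("time and f_unwound must match 1-D")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.time[0] < 0:
            raise InvalidParameterError("first time point must be >= 0")


def one_phase(x: np.ndarray, y0: float, plateau: float, k: float) -> np.ndarray:
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(x, dtype=float)))


@dataclass
class AssociationFit:
    y0: float
    plateau: float
    k: float                     # in 1/time_unit of the input
    se: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    residuals: np.ndarray | None = None
    flagged: bool = False
    condition: str = ""
    time_unit: str = "min"

    def predict(self, x):
        return one_phase(x, self.y0, self.plateau, self.k)

    def to_dict(self) -> dict:
        return {"y0": self.y0, "plateau": self.plateau, "k": self.k,
                "k_unit": f"1/{self.time_unit}", "se": self.se,
                "flagged": self.flagged, "condition": self.condition}


def fit_one_phase(tc: TimeCourse, weighted: bool = False) -> AssociationFit:
    """Least-squares fit of the one-phase association law.

    Flat data (no resolvable rise above the point scatter) yields a
    flagged fit carrying k with infinite SE instead of a spurious rate.
    """
    if tc.time.size < 4:
        raise InvalidParameterError("need at least 4 time points")
    t, y = tc.time, tc.f_unwound
    sigma = tc.se if (weighted and tc.se is not None) else None
    if sigma is not None:
        sigma = np.clip(sigma, 1e-6, None)

    # initial guess: endpoints for the levels, half-rise time for the rate
    y0_0, pl_0 = y[0], y[-1]
    span = pl_0 - y0_0
    if abs(span) > 1e-12:
        mid = y0_0 + 0.5 * span
        cross = np.nonzero((y - mid) * np.sign(span) >= 0)[0]
        t_half = t[cross[0]] if cross.size else t[t.size // 2]
        k0 = np.log(2.0) / max(t_half, np.diff(t).min() / 4)
    else:
        k0 = 1.0 / max(t.mean(), 1e-6)

    try:
        popt, pcov = curve_fit(one_phase, t, y, p0=(y0_0, pl_0, k0),
                               sigma=sigma, absolute_sigma=sigma is not None,
                               maxfev=20000)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    except Exception:
        popt, pcov = np.array([y.mean(), y.mean(), k0]), None
        perr = np.array([np.inf, np.inf, np.inf])

    y0, plateau, k = map(float, popt)
    pred = one_phase(t, *popt)
    resid = y - pred
    noise = (np.median(tc.se) if tc.se is not None and np.all(np.isfinite(tc.se))
             else float(np.std(resid)))
    # k is unidentifiable when the fitted curve barely rises over the
    # sampled window relative to the point scatter
    rise = float(pred.max() - pred.min())
    flagged = rise < 3 * max(noise, 1e-9)
    se = {"y0": float(perr[0]), "plateau": float(perr[1]),
          "k": np.inf if flagged else float(perr[2])}
    return AssociationFit(y0=y0, plateau=plateau, k=k, se=se, cov=pcov,
                          residuals=resid, flagged=flagged,
                          condition=tc.condition, time_unit=tc.time_unit)


def compare_conditions(fits: list[AssociationFit]) -> pd.DataFrame:
    """All pairwise rate-constant ratios with propagated standard errors.

    Flagged fits (unidentifiable k) are excluded with a warning column in
    the empty case; requires at least two usable fits.
    """
    usable = [f for f in fits if not f.flagged and np.isfinite(f.k) and f.k > 0]
    if len(usable) < 2:
        raise InvalidParameterError("need >= 2 unflagged fits with finite k")
    rows = []
    for i, fa in enumerate(usable):
        for fb in usable[i + 1:]:
            ratio = fa.k / fb.k
            ra = fa.se.get("k", np.inf) / fa.k
            rb = fb.se.get("k", np.inf) / fb.k
            se = ratio * np.sqrt(ra ** 2 + rb ** 2)
            rows.append({"condition_a": fa.condition, "condition_b": fb.condition,
                         "k_a": fa.k, "k_b": fb.k, "ratio": ratio,
                         "ratio_se": se})
    return pd.DataFrame(rows)
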