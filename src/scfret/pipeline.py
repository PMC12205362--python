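"""End-to-end workflows: simulate -> extract -> classify/idealize -> rates.

One function per experiment type, each consuming a :class:`TraceSet` (from
the simulator or from image stacks) and returning the fitted quantities;
:func:`run_pipeline` orchestrates them from a single config with explicit
seeding and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dwellhmm, fretpop, ratekit, simkit, unwind_kinetics
from .containers import FretSeries, TraceSet
from .exceptions import ConfigurationError

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Analysis building blocks
# ---------------------------------------------------------------------------

def snapshot_fraction(ts: TraceSet, rule: fretpop.ClassificationRule | None = None,
                      leakage: float = 0.0, k_sigmas: float = 4.0,
                      min_total: float | str | None = "auto",
                      ) -> tuple[float, float, dict]:
    """Unwound fraction of one snapshot TraceSet.

    Applies the acceptor filter, classifies molecules on their mean E over
    frames 3-7, and returns (f_unwound, se, details). When no rule is
    given, thresholds are taken from a three-Gaussian fit of this
    snapshot's histogram.
    """
    keep = fretpop.acceptor_filter(ts, k_sigmas=k_sigmas)
    series = fretpop.compute_fret(ts, leakage=leakage, min_total=min_total)
    series = series.subset(keep)
    details: dict = {"n_kept": int(keep.sum()), "n_total": ts.n_molecules}
    if rule is None:
        hist = fretpop.build_histogram(series)
        fit = fretpop.fit_three_gaussians(hist)
        rule = fretpop.rule_from_fit(fit)
        details["mixture"] = fit.to_dict()
    cats = fretpop.classify_molecules(series, rule)
    f, se = fretpop.fraction_unwound(cats)
    details["rule"] = {"lo": rule.lo, "hi": rule.hi}
    details["categories"] = {c: int((cats == c).sum())
                             for c in np.unique(cats)}
    return f, se, details


def pooled_rule(tracesets: list[TraceSet], leakage: float = 0.0,
                k_sigmas: float = 4.0, seed: int = 0,
                ) -> tuple[fretpop.ClassificationRule, fretpop.MixtureFit]:
    """Classification thresholds from the pooled histogram of many snapshots."""
    counts = None
    hist = None
    for ts in tracesets:
        keep = fretpop.acceptor_filter(ts, k_sigmas=k_sigmas)
        series = fretpop.compute_fret(ts, leakage=leakage).subset(keep)
        h = fretpop.build_histogram(series)
        counts = h.counts if counts is None else counts + h.counts
        hist = h
    hist.counts = counts
    fit = fretpop.fit_three_gaussians(hist, seed=seed)
    return fretpop.rule_from_fit(fit), fit


def analyze_timecourse(snapshots: list[tuple[float, TraceSet]],
                       rule: fretpop.ClassificationRule | None = None,
                       condition: str = "", leakage: float = 0.0,
                       seed: int = 0) -> tuple[unwind_kinetics.TimeCourse,
                                               unwind_kinetics.AssociationFit]:
    """f_unwound(t) of a snapshot series and its one-phase association fit."""
    if rule is None:
        rule, _ = pooled_rule([ts for _, ts in snapshots], leakage=leakage,
                              seed=seed)
    times, fs, ses = [], [], []
    for t, ts in snapshots:
        f, se, _ = snapshot_fraction(ts, rule=rule, leakage=leakage)
        times.append(t)
        fs.append(f)
        ses.append(max(se, 1e-4))
    tc = unwind_kinetics.TimeCourse(np.array(times), np.array(fs),
                                    np.array(ses), condition=condition)
    return tc, unwind_kinetics.fit_one_phase(tc)


def idealize(series: FretSeries, n_restarts: int = 5, seed: int = 0,
             ) -> tuple[dwellhmm.HMMParams, np.ndarray, pd.DataFrame]:
    """HMM fit + Viterbi decoding + dwell table for a trace set."""
    params = dwellhmm.fit_hmm2(series, n_restarts=n_restarts, seed=seed)
    paths = dwellhmm.viterbi_path(series, params)
    dwells = dwellhmm.extract_dwells(paths, series.frame_time,
                                     molecule_ids=series.molecule_ids)
    return params, paths, dwells


def two_state_rates(dwells: pd.DataFrame,
                    method: str = "mle_censored") -> dict:
    """Unwinding/rewinding rates from a two-state dwell table.

    k_unwind is the exit rate of the high-FRET (wound) state and k_rewind
    that of the low-FRET (R-loop) state. The default censored-MLE
    estimator uses censored dwells as exposure time, avoiding the
    short-trace selection bias; the survival-curve fit (``lsq_1mcdf``) is
    available for comparison.
    """
    out = {}
    for state, key in (("high", "k_unwind"), ("low", "k_rewind")):
        fit = ratekit.rate_from_dwell_table(dwells, state, method=method)
        out[key] = fit.k
        out[f"{key}_se"] = fit.se.get("k", np.nan)
        out[f"{key}_n"] = fit.n_dwells
    return out


def binding_bursts(series: FretSeries) -> pd.DataFrame:
    """Dwell table of signal bursts for a single-emitting-state experiment.

    Valid (signal) runs are treated as bound (high) dwells and dark gaps as
    unbound intervals; no HMM is needed when only one FRET state emits.
    """
    paths = np.where(series.valid, dwellhmm.STATE_HIGH, -1)
    return dwellhmm.extract_dwells(paths, series.frame_time,
                                   molecule_ids=series.molecule_ids)


def dark_gaps(series: FretSeries) -> pd.DataFrame:
    """Dwell-style table of dark (unbound) intervals between signal bursts.

    Reuses the run-length encoder on the inverted validity mask; the
    ``to_dark`` outcome then means "terminated by a binding event" while
    ``censored`` marks gaps cut by the end of the trace.
    """
    paths = np.where(~series.valid, dwellhmm.STATE_HIGH, -1)
    return dwellhmm.extract_dwells(paths, series.frame_time,
                                   molecule_ids=series.molecule_ids)


def muts_adp_rates(series: FretSeries, concentration_nM: float | None = None,
                   method: str = "mle_censored") -> dict:
    """k_off (from t_on) and k'_on (from t_off) of repetitive mismatch binding.

    The bound time t_on is the duration of each signal burst (the donor
    rides on the protein, so dissociation is signal loss) and the waiting
    time t_off the dark gap between bursts. Both exit processes are
    exponential; the default censored-MLE estimator counts censored
    intervals as exposure, the ``lsq_1mcdf`` option reproduces the
    survival-curve procedure on completed intervals only.
    """
    bursts = binding_bursts(series)
    gaps = dark_gaps(series)
    if method == "mle_censored":
        hb = bursts[bursts.state == "high"]
        k_off_fit = ratekit.censored_rate_mle(
            hb.duration.to_numpy(),
            (hb.outcome == dwellhmm.OUT_TO_DARK).to_numpy())
        hg = gaps[gaps.state == "high"]
        k_on_fit = ratekit.censored_rate_mle(
            hg.duration.to_numpy(),
            (hg.outcome == dwellhmm.OUT_TO_DARK).to_numpy())
    else:
        high = bursts[(bursts.state == "high") &
                      (bursts.outcome == dwellhmm.OUT_TO_DARK) &
                      (~bursts.left_censored)]
        k_off_fit = ratekit.fit_exp_1mcdf(high.duration.to_numpy(),
                                          method=method)
        waits = ratekit.waiting_times_from_dwells(bursts)
        k_on_fit = ratekit.fit_exp_1mcdf(waits, method=method)
    if concentration_nM:
        k_on_per_nM = k_on_fit.k / concentration_nM
    return {"k_off": k_off_fit.k, "k_off_se": k_off_fit.se.get("k"),
            "n_on": k_off_fit.n_dwells,
            "k_on_prime": k_on_fit.k,
            "k_on_prime_se": k_on_fit.se.get("k"), "n_off": k_on_fit.n_dwells,
            "dwells": bursts}


def muts_atp_rates(series: FretSeries, n_restarts: int = 5, seed: int = 0,
                   total_observed_time: float | None = None,
                   method: str = "mle_censored") -> dict:
    """k1, k-1 and k2 of mismatch binding with sliding-clamp formation.

    The high-FRET exit rate k = k-1 + k2 comes from the bound-dwell
    distribution (censored-MLE by default, survival fit optional); the
    branch ratio N2/N-1 splits it; k1 is the number of observed binding
    events per second of observation (an events-per-second count, i.e. the
    per-molecule binding rate times the unbound occupancy).
    """
    params, paths, dwells = idealize(series, n_restarts=n_restarts, seed=seed)
    k_fit = ratekit.rate_from_dwell_table(
        dwells, "high", method=method,
        event_outcomes=(dwellhmm.OUT_TO_LOW, dwellhmm.OUT_TO_DARK))
    high = dwells[(dwells.state == "high") & (~dwells.left_censored) &
                  (dwells.outcome.isin([dwellhmm.OUT_TO_LOW,
                                        dwellhmm.OUT_TO_DARK]))]
    counts = ratekit.branch_counts_from_dwells(high)
    k_minus1, k2, flags = ratekit.decompose_branch(k_fit.k, counts)
    out = {"k_total": k_fit.k, "k_total_se": k_fit.se.get("k"),
           "k_minus1": k_minus1, "k2": k2,
           "N2": counts.N2, "N_minus1": counts.N_minus1,
           "hmm": params, "dwells": dwells, "flags": flags}
    if total_observed_time:
        ev = ratekit.binding_event_rate(dwells, total_observed_time,
                                        n_molecules=series.n_molecules)
        out.update({"k1": ev["k1"], "n_events": ev["n_events"]})
    return out


# ---------------------------------------------------------------------------
# Config-driven orchestration
# ---------------------------------------------------------------------------

KNOWN_PRESETS = ("cas9_proximal_mm", "cas9_distal_mm", "muts_adp", "muts_atp")
DEFAULT_STAGES = ("simulate", "extract", "analyze", "report")


@dataclass
class RunConfig:
    preset: str
    seed: int = 0
    outdir: str = "scfret_out"
    conditions: list[dict] = field(default_factory=list)
    n_molecules: int = 200
    n_frames: int | None = None          # optional green-block override
    stages: tuple[str, ...] = DEFAULT_STAGES
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.preset not in KNOWN_PRESETS:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; options: {KNOWN_PRESETS}")
        if not self.conditions:
            self.conditions = _default_conditions(self.preset)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _default_conditions(preset: str) -> list[dict]:
    if preset == "cas9_proximal_mm":
        return [{"label": c.label, "k_per_min": c.k_per_min,
                 "plateau": c.plateau, "y0": c.y0}
                for c in simkit.unwinding_presets().values()]
    if preset == "cas9_distal_mm":
        return [{"label": "nicked", "k_unwind": 0.9, "k_rewind": 0.4}]
    if preset == "muts_adp":
        return [{"label": "RC", "k_on": 0.06, "k_off": 0.204},
                {"label": "pos_sc", "k_on": 0.06, "k_off": 0.107},
                {"label": "neg_sc", "k_on": 0.072, "k_off": 0.075}]
    return [{"label": "RC", "k1": 0.05, "k_minus1": 0.3, "k2": 0.1}]


def _acq_for(config: RunConfig) -> simkit.AcquisitionParams:
    acq = simkit.acquisition_presets()[config.preset]
    if config.n_frames is not None:
        schedule = tuple((e, config.n_frames) if e == "green" else (e, n)
                         for e, n in acq.schedule)
        acq = simkit.AcquisitionParams(acq.frame_time, schedule,
                                       acq.n_fields, acq.molecules_per_field)
    return acq


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow and write artifacts + manifest.

    Reruns with the same config and seed are bit-identical; every output
    file is checksummed in the manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    results: dict = {"preset": config.preset, "conditions": {}}
    written: list[Path] = []
    phys_kwargs = config.options.get("photophysics", {})
    phys = simkit.PhotophysicsParams(**phys_kwargs)
    acq = _acq_for(config)
    leakage = phys.leakage

    for cond, child in zip(config.conditions,
                           ss.spawn(len(config.conditions))):
        label = cond["label"]
        rng = np.random.default_rng(child)
        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        res: dict = {}

        if config.preset == "cas9_proximal_mm":
            uc = simkit.UnwindingCondition(label, cond["k_per_min"],
                                           cond["plateau"],
                                           cond.get("y0", 0.02))
            snaps = simkit.simulate_timecourse(
                uc, n_molecules_per_point=config.n_molecules,
                phys=phys, acq=acq, rng=rng)
            if "simulate" in config.stages:
                snaps[0][1].to_tsv(cdir / "snapshot_t1.tsv")
                written.append(cdir / "snapshot_t1.tsv")
            tc, fit = analyze_timecourse(snaps, condition=label,
                                         leakage=leakage, seed=config.seed)
            pd.DataFrame({"time_min": tc.time, "f_unwound": tc.f_unwound,
                          "se": tc.se}).to_csv(cdir / "timecourse.csv",
                                               index=False)
            written.append(cdir / "timecourse.csv")
            res["fit"] = fit.to_dict()
            res["_fit_obj"] = fit

        else:
            ts = simkit.simulate_traceset(
                _scheme_for(config.preset, cond), phys, acq,
                config.n_molecules, rng)
            if "simulate" in config.stages:
                ts.to_tsv(cdir / "traces.tsv")
                written.append(cdir / "traces.tsv")
            series = fretpop.compute_fret(
                ts, leakage=leakage,
                min_total=config.options.get("min_total", "auto"))
            if config.preset == "cas9_distal_mm":
                params, paths, dwells = idealize(series, seed=config.seed)
                res["hmm"] = params.to_dict()
                res.update(two_state_rates(dwells))
            elif config.preset == "muts_adp":
                r = muts_adp_rates(series)
                dwells = r.pop("dwells")
                res.update(r)
            else:
                green_s = sum(n for e, n in acq.schedule if e == "green")
                r = muts_atp_rates(series, seed=config.seed,
                                   total_observed_time=config.n_molecules *
                                   green_s * acq.frame_time)
                dwells = r.pop("dwells")
                res["hmm"] = r.pop("hmm").to_dict()
                res.update(r)
            dwells.to_csv(cdir / "dwells.csv", index=False)
            written.append(cdir / "dwells.csv")

        with open(cdir / "rates.json", "w") as fh:
            json.dump({k: v for k, v in res.items()
                       if not k.startswith("_")}, fh, indent=2, default=float)
        written.append(cdir / "rates.json")
        results["conditions"][label] = res

    fits = [res["_fit_obj"] for res in results["conditions"].values()
            if "_fit_obj" in res]
    if len(fits) >= 2:
        comp = unwind_kinetics.compare_conditions(fits)
        comp.to_csv(outdir / "rate_ratios.csv", index=False)
        written.append(outdir / "rate_ratios.csv")
        results["rate_ratios"] = comp.to_dict(orient="records")
    for res in results["conditions"].values():
        res.pop("_fit_obj", None)

    manifest = {
        "package_version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "n_molecules": config.n_molecules,
        "stages": list(config.stages),
        "conditions": config.conditions,
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results


def _scheme_for(preset: str, cond: dict) -> simkit.KineticScheme:
    if preset == "cas9_distal_mm":
        return simkit.cas9_distal_mm_scheme(cond.get("k_unwind", 0.9),
                                            cond.get("k_rewind", 0.4))
    if preset == "muts_adp":
        return simkit.muts_adp_scheme(cond.get("k_on", 0.06),
                                      cond.get("k_off", 0.204))
    return simkit.muts_atp_scheme(cond.get("k1", 0.05),
                                  cond.get("k_minus1", 0.3),
                                  cond.get("k2", 0.1))
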