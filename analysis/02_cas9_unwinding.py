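#!/usr/bin/env python
"""R-loop formation kinetics versus DNA topology (PAM-proximal mismatch).

Simulates the snapshot time-course experiment for negatively supercoiled,
nicked and positively supercoiled plasmid, classifies molecules with
thresholds from pooled three-Gaussian histogram fits, fits each
f_unwound(t) series to the one-phase association law and tabulates the
rate-constant ratios. Negative supercoiling should come out roughly
two-fold faster than nicked and three-fold faster than positive.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scfret import pipeline, simkit, unwind_kinetics

OUT = Path("results")
SEED = 2026
N_PER_POINT = 1000


def main():
    OUT.mkdir(exist_ok=True)
    phys = simkit.PhotophysicsParams(total_emission=1000, background_mean=100,
                                     noise_sd=50,
                                     inactive_acceptor_fraction=0.15)
    rng = np.random.default_rng(SEED)
    rows, fits = [], []
    for label, cond in simkit.unwinding_presets().items():
        snaps = simkit.simulate_timecourse(cond, n_molecules_per_point=N_PER_POINT,
                                           phys=phys, rng=rng)
        tc, fit = pipeline.analyze_timecourse(snaps, condition=label, seed=1)
        fits.append(fit)
        for t, f, se in zip(tc.time, tc.f_unwound, tc.se):
            rows.append({"condition": label, "time_min": t,
                         "f_unwound": round(f, 4), "se": round(se, 4)})
        print(f"{label:8s} k = {fit.k:.3f} /min (true {cond.k_per_min}), "
              f"plateau = {fit.plateau:.3f} (true {cond.plateau})")
    pd.DataFrame(rows).to_csv(OUT / "cas9_unwinding_timecourses.csv",
                              index=False)
    ratios = unwind_kinetics.compare_conditions(fits)
    ratios.to_csv(OUT / "cas9_unwinding_rate_ratios.csv", index=False)
    print(ratios.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
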