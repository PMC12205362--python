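#!/usr/bin/env python
"""Generate small preview datasets for each experiment type.

Writes a few-molecule trace table (TSV) and a ground-truth summary per
experiment under results/simulated/, so the on-disk schema can be
inspected by eye. The downstream analyses and the verification suite
regenerate data at full scale in memory; these previews are deliberately
tiny.
"""

import json
from pathlib import Path

import numpy as np

from scfret import simkit

OUT = Path("results/simulated")
SEED = 2026


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(SEED)
    r1, r2, r3 = (np.random.default_rng(s) for s in ss.spawn(3))
    phys = simkit.PhotophysicsParams(total_emission=1000, background_mean=100,
                                     noise_sd=50)
    summary = {"seed": SEED}

    # R-loop breathing, nicked plasmid, PAM-distal triple mismatch
    acq = simkit.acquisition_presets()["cas9_distal_mm"]
    ts = simkit.simulate_traceset(simkit.cas9_distal_mm_scheme(0.9, 0.4),
                                  phys, acq, 1, r1)
    ts.to_tsv(OUT / "cas9_distal_nicked_traces.tsv")
    summary["cas9_distal_nicked"] = {
        "n_molecules": 1, "frame_time_s": acq.frame_time,
        "true_rates_per_s": {"k_unwind": 0.9, "k_rewind": 0.4}}

    # MutS + ADP, relaxed circle
    acq = simkit.acquisition_presets()["muts_adp"]
    ts = simkit.simulate_traceset(simkit.muts_adp_scheme(0.06, 0.204),
                                  phys, acq, 1, r2)
    ts.to_tsv(OUT / "muts_adp_rc_traces.tsv")
    summary["muts_adp_rc"] = {
        "n_molecules": 1, "frame_time_s": acq.frame_time,
        "true_rates_per_s": {"k_on_prime": 0.06, "k_off": 0.204}}

    # one snapshot of the proximal-mismatch unwinding series (t = 4 min)
    cond = simkit.unwinding_presets()["nicked"]
    ts = simkit.simulate_snapshot(cond, 4.0, 50, phys, rng=r3)
    ts.to_tsv(OUT / "cas9_proximal_nicked_t4min.tsv")
    summary["cas9_proximal_nicked_t4min"] = {
        "n_molecules": 50, "t_min": 4.0,
        "true_p_unwound": round(float(ts.truth["p_unwound"]), 4)}

    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    for k in summary:
        print("wrote", k)


if __name__ == "__main__":
    main()
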