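# scfret

Single-molecule FRET analysis of DNA-supercoiling effects on protein–DNA
kinetics, paired with a synthetic-data generator so that every stage of the
analysis is verifiable by parameter recovery — no experimental movies
required.

The package targets two smTIRF experiment families performed on
site-specifically labelled ~2.8 kb plasmids whose topology is set
enzymatically (gyrase → σ ≈ −0.07, reverse gyrase → σ ≈ +0.03, nicking or
religation → σ = 0, with σ = ΔLk/Lk₀):

* **CRISPR–Cas9 R-loop formation.** A Cy3/Cy5 pair across the protospacer
  reads duplex DNA as high FRET and the dCas9–gRNA-unwound R-loop as low
  FRET. With a PAM-proximal mismatch, snapshot movies over an incubation
  series give the unwound fraction *f*_unwound(*t*), fitted to the
  one-phase association law *y* = *y*₀ + (plateau − *y*₀)(1 − e^(−*kx*)).
  With PAM-distal mismatches the R-loop breathes, and a two-state
  hidden-Markov idealization of the FRET trajectories yields unwinding and
  rewinding rates *k*₁, *k*₋₁.
* **MutS mismatch recognition.** Cy3-MutS binding at a Cy5-flanked GT
  mismatch is a high-FRET state. Bound times *t*_on and waiting times
  *t*_off are fitted through the empirical survival curve
  1 − CDF ≈ *y*₀ + *A*₁e^(−*kt*) to give *k*_off and *k*′_on (ADP), while
  with ATP the bound-state exit rate *k* = *k*₋₁ + *k*₂ is split by the
  branch ratio *N*₂/*N*₋₁ = *k*₂/*k*₋₁ between sliding-clamp formation
  (transition to low FRET) and dissociation (donor-signal loss).

## Layout

| module | role |
| --- | --- |
| `scfret.simkit` | ground-truth Markov paths (Gillespie), fluorescence traces, TIRF-style two-channel movies, supercoiling bookkeeping, experiment presets |
| `scfret.imaging` | spot detection, affine channel registration, aperture trace extraction from TIFF stacks |
| `scfret.fretpop` | FRET efficiency, acceptor-activity filtering, snapshot histograms (frames 3–7), three-Gaussian fits, intersection thresholds, wound/unwound classification |
| `scfret.unwind_kinetics` | one-phase association fits and condition comparison |
| `scfret.dwellhmm` | shared-parameter two-state Gaussian HMM, Viterbi decoding, dwell tables with censoring flags and outcome labels |
| `scfret.ratekit` | exponential dwell fits (1 − CDF, MLE, censored MLE), branch decomposition, binding-event rates, bootstrap errors |
| `scfret.pipeline` / `scfret.cli` | config-driven orchestration (`scfret` console script) |

Narrative driver scripts live under `analysis/` and write their tables to
`results/`.

## Worked example

Simulate the MutS + ADP experiment at the three measured dissociation
rates and recover them through the full trace → burst → survival analysis
(`python analysis/03_muts_kinetics.py`):

```
ADP RC      k_off 0.1973 (true 0.204) k'_on 0.0573 (true 0.06)
ADP pos_sc  k_off 0.1036 (true 0.107) k'_on 0.0588 (true 0.06)
ADP neg_sc  k_off 0.0749 (true 0.075) k'_on 0.0717 (true 0.072)
...
k_off RC / (-)SC = 2.63 (supercoiling stabilizes the MutS-mismatch complex)
```

Each line compares the rate measured from ~1500 synthetic binding events
(200 molecules, 200 ms frames) against the generator's ground truth; the
final ratio is the headline supercoiling effect — dissociation from the
mismatch is about 2.7× slower on negatively supercoiled DNA than on the
relaxed circle.

The same workflows run from the shell:

```sh
scfret run --preset muts_adp --seed 1 --outdir out/
scfret simulate --preset cas9_distal_mm --seed 2 --n-molecules 50 --out traces.tsv
scfret idealize traces.tsv --frame-time 0.05 --out dwells.csv
scfret dwell-fit dwells.csv --state high
```

Every run writes a manifest (config, seeds, output checksums); identical
configs reproduce bit-identical outputs.

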