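# Methods

## Kinetic model and simulation

Molecular state dynamics are continuous-time Markov chains specified by a
`KineticScheme`: a labelled generator matrix (off-diagonal entries are
transition rate constants in s⁻¹) plus per-state FRET emission parameters
(`fret_mean` in E-units, or a dark marker for states without donor signal;
`fret_sd` the E-domain emission width). Paths are simulated exactly
(Gillespie): the waiting time in each state is exponential with the
state's total exit rate and the successor is drawn proportionally to the
outgoing rates. Every visit to the highest-FRET state records its outcome
— `to_low` (transition to a lower-FRET emitting state, e.g. sliding-clamp
formation), `to_dark` (transition to a non-emitting state, e.g.
dissociation) or `censored` (cut by the simulation window) — which is the
ground truth for branch-ratio recovery.

Scheme presets encode the two experimental systems at their measured rate
scales: R-loop breathing (`cas9_distal_mm`, defaults k₁ = 0.9 s⁻¹ wound →
unwound, k₋₁ = 0.4 s⁻¹ back, E ≈ 0.60/0.35), repetitive MutS–mismatch
binding (`muts_adp`, dark unbound state, k_off defaults 0.204 s⁻¹ for the
relaxed circle with 0.107/0.075 s⁻¹ for positively/negatively supercoiled
DNA, bound E ≈ 0.75), and the branched ATP scheme (`muts_atp`,
k₋₁ = 0.3 s⁻¹, k₂ = 0.1 s⁻¹, low-FRET clamp at E ≈ 0.25 departing at
0.5 s⁻¹). Supercoiling enters only as bookkeeping — σ = ΔLk/Lk₀ with
Lk₀ = length/helical repeat (2800 bp, 10.5 bp/turn by default) — never as
a mechanistic modifier of rates; users assign per-condition rate
constants, exactly as the topology conditions are separate samples in the
experiment.

## Trace rendering and what it emulates

`render_traces` integrates state occupancy over each camera exposure
(motion blur): a frame spanning a transition carries the
occupancy-weighted mean FRET, which produces the realistic mid-FRET
frames that challenge idealization. Under green excitation the occupied
state's total emission (default 1000 counts/frame) is partitioned into
donor and acceptor channels by that weighted mean; a dark or bleached
acceptor returns the photons to the donor channel, apart from a spectral
leakage fraction added to the acceptor channel (default 0, i.e. ideal
detection — no γ or leakage corrections are published for these
experiments). Under red excitation the acceptor is probed directly.
Gaussian read noise (default σ = 50 counts) and a constant background
(default 100 counts) are added per channel per frame; at the defaults the
propagated E-domain width is ≈ 0.04, comparable to the widths of the
experimental histogram components. Photobleaching is per-dye exponential
and one-way on the wall clock; after donor bleach both channels sit at
background under green excitation. An inactive-acceptor subpopulation
(probability per molecule) emulates molecules that fail the red-excitation
check.

Because the per-frame E spread arises from channel-noise propagation, the
scheme's `fret_sd` is not re-applied during photon rendering (with zero
channel noise the computed E equals the state mean exactly); `fret_sd` is
used by the direct E-level generator `simulate_fret_series`, which skips
the photon model and is the convenient route for testing idealization at a
prescribed E-domain width.

Acquisition presets mirror the experiments: 50 ms frames with
[10 green | 10 red] snapshots for the proximal-mismatch series, and long
movies of [10 red | 980 green | 10 red] at 50 ms (distal mismatch),
[10 red | 980 green | 10 red] at 200 ms (MutS + ADP) and
[10 red | 1480 green | 10 red] at 50 ms (MutS + ATP).

The movie renderer draws each molecule as a pixel-integrated 2D Gaussian
PSF (default σ = 1.2 px) whose integral per frame equals the trace signal,
at random positions with a minimum-separation constraint, on a noisy
background; the acceptor channel is displaced by a known affine map.
What the generator does **not** emulate: Poisson shot statistics (noise is
Gaussian of fixed width), EMCCD gain and excess noise, stage drift,
spectral crosstalk beyond a single leakage coefficient, dye blinking, and
heterogeneity of emission levels between molecules. Passing tests
therefore demonstrate correctness of the measurement chain under a clean
noise model, not robustness to every artefact of real movies.

## Imaging stand-in

Spot detection is deliberately simple (the original acquisition software
is proprietary and none of the study's numbers depend on it): local maxima
of a time-averaged image above median + kσ (robust MAD σ), centroid
refinement, and a greedy minimum-separation rule. Channel registration is
a least-squares affine fit to matched pairs (≥ 3, non-collinear). Traces
are aperture sums (default radius 2 px) minus the annulus median (3–5 px)
per frame. Coordinates are 0-based, pixel-centre convention.

## Population analysis

FRET efficiency is the uncorrected proximity ratio with optional leakage
correction, E = (I_A − lI_D)/(I_D + I_A − lI_D), on background-subtracted
intensities. Dark/bleached frames are masked by a total-intensity
threshold; the automatic threshold is Otsu's split of the pooled frame
totals, accepted only when the two classes separate by more than four
within-class standard deviations (otherwise nothing is masked). The
acceptor filter keeps molecules whose median red-block acceptor intensity
exceeds background + kσ (default k = 4), with background statistics taken
from the donor channel during red excitation, which sees background only.

Snapshot histograms pool frames 3–7 (1-based, five frames) of each
molecule into fixed bins of width 0.02 over [−0.1, 1.1]; molecules with
fewer than seven valid leading frames are excluded and counted. Histograms
are fitted with a sum of three Gaussians (amplitude parameterization,
bounded least squares, ≥ 5 seeded restarts keeping the best residual;
means reported sorted). Thresholds are the numerically located crossings
of adjacent weighted component curves between their means (bisection to
|Δf| < 10⁻¹²); nested components without a crossing fall back, flagged, to
the closest-approach point. When a histogram has only two real
populations the crossing of the two heaviest components
(`dominant_crossing`) is the robust single threshold. Classification uses
each molecule's snapshot-window mean E — (lo, hi] unwound, > hi wound,
≤ lo excluded — and f_unwound = n_unwound/(n_unwound + n_wound) with a
binomial SE; a pooled per-frame mode (`fraction_unwound_frames`) mirrors
the histogram-population division and is used where populations rather
than molecules are counted. The fixed published windows (0.14–0.47
proximal, 0.18–0.51 distal) are available as rule presets.

## Dwell-time analysis

Idealization is a shared-parameter two-state Gaussian HMM fitted by
maximum-likelihood Baum–Welch (hmmlearn backend, ≥ 5 seeded restarts,
quartile-spread initialization, emission variance floored at 10⁻⁴ and
flagged if touched), replacing the empirical-Bayes machinery used
originally: the downstream quantities are dwell times, which depend on the
idealized path, not on the inference style. Viterbi decoding is
implemented in-package because masked frames must terminate the decoded
region (each contiguous valid segment is decoded independently) and the
tie-break is fixed: an exact tie prefers the self-transition, i.e. the
state continues. Dwells are run lengths × frame time with first/last-dwell
censoring flags; each dwell's outcome is `to_low`/`to_high` (observed
transition), `to_dark` (segment ends by signal loss before the trace end)
or `censored`. For MutS, `to_low` bound-dwell outcomes count as
sliding-clamp formations (N₂) and `to_dark` as dissociations (N₋₁), since
low FRET after binding signals the clamp while signal loss signals
departure; the assignment is recorded per event.

Rates come from the dwell distributions three ways: the survival-curve
procedure (sorted dwells, empirical 1 − CDF, least-squares
y = y₀ + A₁e^(−kt)); the closed-form MLE k = 1/mean as a cross-check; and
a censored-MLE option k = (observed terminations)/(summed observed
durations), exact for exponential exits by memorylessness. The censored
MLE is the default for end-to-end rate recovery because restricting to
completed dwells inside a finite trace under-samples long dwells — a +6 to
+13% bias when the mean dwell reaches ~5% of the trace length, as for the
faster rates at the standard movie lengths — while the survival fit
remains the published procedure and the default of `fit_exp_1mcdf`.
Branch decomposition solves k = k₋₁ + k₂ and N₂/N₋₁ = k₂/k₋₁ exactly;
N₋₁ = 0 returns the flagged limit (0, k). The binding-event rate k₁ is
counted events per second of observation (left-censored starts excluded);
note this equals the per-molecule binding rate times the unbound
occupancy, the same convention as counting events in the movies. Standard
errors are molecule-level bootstrap resamples (≥ 200 replicates, seeded).
Reportable rates are bounded by the sampling window: roughly
1/(5 × trace duration) to 1/(2 × frame time).

For the one-phase association fit all eleven sampled time points
(1–60 min) are used, with y₀, plateau and k free; a fit whose predicted
rise over the sampled window is below three times the point scatter is
flagged with infinite SE on k rather than reporting a spurious rate.
Weighting by per-point SEs is available but off by default (the published
analysis does not state a weighting).

## Synthetic study conditions

Values not printed in the source experiments were chosen once, as
follows, and are not tuned: unwinding time-course rate constants
0.60/0.30/0.20 min⁻¹ for negatively supercoiled/nicked/positively
supercoiled DNA (preserving the stated ~2× and ~3× ratios and placing the
rise within the 1–60 min grid) with plateaus 0.79/0.76/0.50 and y₀ = 0.02;
snapshot emission means 0.05/0.30/0.62 (residual/unwound/wound) with a 6%
residual low-FRET subpopulation so histograms are genuinely
three-component; MutS association k′_on = 0.06 s⁻¹ (0.072 s⁻¹ for the
negatively supercoiled sample, 1.2× as measured); ATP-arm k₁ = 0.05 s⁻¹
and clamp departure 0.5 s⁻¹.

Problem sizes in the verification runs are the experiments' own scales:
~5000 molecules per snapshot time point across three replicate series,
200 molecules per dwell-analysis condition yielding ≳ 500 events
(1200–1800 typical), 100 molecules × 980 frames for the R-loop dynamics,
2000 molecules for equilibrium population fractions, and 100-spot fields
for the imaging round trip.

## Known limitations

* Dwells shorter than one frame are unobservable; at the fastest measured
  rate (0.9 s⁻¹ at 50 ms frames) this and transition-frame blur bias the
  recovered exit rate a few percent low.
* The events-per-second k₁ understates the true binding rate by the bound
  occupancy factor (a property of the counting convention, reported as
  such).
* The three-Gaussian fit is unstable when fewer than three populations
  exist; degenerate components are flagged and `dominant_crossing` should
  be used for two-population histograms.
* The Gaussian noise model has no intensity dependence, so
  signal-to-noise does not fall with E as it would with shot noise.
* Trace selection for idealization is automatic (validity masking);
  the original manual selection of dynamic traces is not reproduced.
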