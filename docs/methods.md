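# Methods

`badmotor` simulates and analyses magnetic-tweezers recordings of a
processive, ssDNA-loop-extruding helicase–nuclease (a bacterial DNA2-like
enzyme, "Bad") loaded at a 5′ poly-dT flap on a ~6.6 kb DNA tether, together
with the bulk enzymology of the same enzyme.  This note records the models,
the parameter choices, the numerical conventions, and what the synthetic
data do and do not capture.

## Polymer models and the nm↔bp conversion

Double-stranded DNA follows the extensible Marko–Siggia worm-like-chain
interpolation,

    F = (kBT/P) · [ 1/(4(1 − x/Lc + F/S)²) − 1/4 + x/Lc − F/S ],

solved for the fractional extension x/Lc by bracketed Brent root finding
(absolute tolerance 1e−6).  Defaults are the standard values for B-DNA in
physiological salt — persistence length P = 50 nm, contour rise 0.34 nm/bp,
stretch modulus S = 1000 pN, temperature 296 K — all configurable.  The
experiments this emulates do not pin these down; the conversion constant at
8 pN (0.3255 nm/bp with the defaults) therefore carries a few-percent
systematic uncertainty that propagates into every bp-denominated quantity.
The exact WLC solution differs from the interpolation by ~1% at these
forces, well inside that systematic band.

Single-stranded DNA follows a freely-jointed chain with Kuhn length 1.5 nm
and contour 0.56 nm/nt, chosen so that the extension per residue of ssDNA
crosses the duplex rise per bp at ≈6.1 pN: above the crossover ssDNA is the
longer polymer, below it the shorter.  This reproduces the regime boundary
that separates the two signs of a *canonical* unwinding signal, and is the
reason the observed force-independent *decrease* in bead height identifies
loop extrusion rather than canonical unwinding.

Force calibration uses the equipartition estimator F = kBT·⟨z⟩/var(x) on
lateral bead excursions.  The simulator draws lateral samples i.i.d. from
the equipartition variance; a real bead's excursions are autocorrelated
(Lorentzian spectrum), so the synthetic estimator error shrinks faster with
record length than a real one would.  Recovery is within 10% at 8 and
14 pN from 60 s of samples.

## The motor state machine

One tether cycles through

    waiting → unwinding ⇄ (pause | backslide) → rehybridization → waiting.

All waiting times are exponential.  Event bookkeeping is exact in
continuous time (Gillespie-style breakpoints); the 60 Hz camera grid and
Gaussian bead noise (SD 15 nm per sample, leaving ≈10 bp of noise at the
3 Hz analysis bandwidth) are imposed only at sampling time.  In the looping
geometry the bead height decreases by exactly
`position · rise_per_bp(F)`; the CANONICAL profile instead uses the signed
ssDNA-minus-dsDNA extension difference, which at 8 pN is ~7× smaller per
base pair — a faithful illustration of why the loop-extrusion signal is so
much easier to read than a canonical unwinding signal on this instrument.

Key modelling choices:

- **Initiation** is second-order: waiting times exponential with mean
  1/(kon·[protein]).  The built-in concentration profiles install the
  *printed dwell means* (61 s at 30 nM, 11.6 s at 163 nM) as generative
  truth, which implies per-profile effective kon values of 5.46×10⁵ and
  5.29×10⁵ M⁻¹s⁻¹; the free-standing `InitiationModel` default is the
  printed global fit, kon = 5.9×10⁵ M⁻¹s⁻¹.  These differ by ~10% — the
  headline dwell constants and the hyperbolic kon fit are not perfectly
  mutually consistent, and the package preserves each number where it is
  quoted.
- **Processivity** is a constant per-bp detachment probability, giving
  exponential event lengths (mean ⟨L⟩ = 900 bp at 30 nM, 1181 bp at
  163 nM, 870 bp on the bottom-nicked tether), clipped at the 6155 bp
  track with a logged warning.
- **Per-event rates** are Gaussian between events and constant within an
  event (CV 0.5, motivated by the reported SEM of 9 bp/s over n = 147 ⇒
  SD ≈ 109 bp/s; a CV 0.2 preset is also provided).  The Gaussian is
  truncated at 30 bp/s — the segmentation velocity threshold — because
  slower motors are invisible to the assay and cannot contribute to the
  printed rate distributions.  Without this truncation, near-zero-rate
  events last tens of minutes and fragment into artifactual slow events.
- **Pauses and backslides** enter as Poisson processes *per bp
  translocated* (rates quoted in s⁻¹ at the mean unwinding rate and
  divided by it internally).  Per-bp hazards keep the per-event frequency
  independent of the event's own drawn speed, matching the observation
  that backslide frequency is constant across conditions whose mean rates
  differ.  The printed per-event percentages f are converted to entry
  rates through the exact relation for exponentially distributed exposure
  times, r = f/((1−f)·τ̄), where τ̄ is the mean exposure (⟨L⟩/v for
  unwinding, ⟨L⟩/rehyb rate for rehybridization).
- **Pause durations** are a shifted exponential (minimum 1.5 s, mean 3 s).
  The studies print pause frequencies but not durations; the minimum keeps
  simulated pauses resolvable at 3 Hz so that the printed *frequencies*
  are recoverable — with a bare exponential, a third of pauses would be
  sub-resolution and the frequency table could not be reproduced by any
  detector.
- **Backslides** replace unwinding with fast rehybridization to a depth
  that is complete (back to baseline) with the printed probability (97% /
  52% / 58% by condition), else uniform in 10–90% of current progress,
  then restart after 0.5 s.  Re-climbed distance does not advance the
  detachment position, so a complete backslide with restart still produces
  one event of the originally drawn length — matching the analysts'
  convention of counting such cycles as a single event.
- **Rehybridization** runs at 2000 bp/s (only described as "rapid"); its
  pauses use the same duration law.
- **Nicks.** A top-strand (translocated-strand) nick arrests the motor at
  the nick position plus Gaussian jitter (SD 100 bp, hard-bounded at
  ±3 SD — the motor never passes the lesion), followed by a ~2 s stall and
  detachment.  A bottom-strand nick is mechanically transparent and never
  releases the bead, as loop extrusion predicts.  The nick distance is not
  printed; the default of 500 bp from the loading site was chosen a priori
  so that, with ⟨L⟩ = 900 bp, the majority of events (e^(−500/900) ≈ 57%)
  reach the nick and the arrested Gaussian mode dominates the length
  distribution, as observed.  (A nick thousands of bp downstream would be
  reached by almost no events and the arrest signature would vanish.)
- **SSB co-incubation** multiplies rehybridization duration by 20 ("
  dramatically slower") and the backslide entry rate by 0.275, putting the
  generative backslide-containing fraction at ≈8%, inside the reported
  "reduced to ∼10%" envelope.
- **MED50** (50 nM) prints only its pause/backslide statistics; its speed
  (190 bp/s) and processivity (1040 bp) are interpolations between the
  printed flanking conditions and are labelled as such.

## Trace analysis

The processing chain mirrors the experimental convention: 60 Hz → 3 Hz by
non-overlapping boxcar averaging; nm → bp through the WLC rise at the
applied force, with the baseline estimated as the mode of the height
histogram (25 bp bins, robust to recordings that begin mid-event);
segmentation on the central-difference velocity of the 3 Hz series.

Thresholds (all in `SegmentationConfig`): v_min = v_pause = 30 bp/s,
t_min = t_pause = 1 s, minimum event length 100 bp, baseline tolerance
50 bp, backslide window 1.5 s, backslide minimum depth 50 bp.  At 3 Hz
with ~10 bp of filtered noise these produce no false events in five hours
of flat-trace simulation.  The backslide window (the longest gap across
which renewed unwinding is attached to its parent event) is 1.5 s because
genuine backslide gaps are bounded by retreat time (≤0.5 s) plus the
restart delay (0.5 s); a wider window would increasingly merge true
re-initiations at the 163 nM condition, where 16% of genuine dwells are
shorter than 2 s.

Conventions worth stating explicitly:

- **Per-event rate** is the mean of central-difference velocities over
  moving frames (v > v_min), excluding one or two frames at each run edge
  where the boxcar attenuates the derivative.  This estimates the motor's
  instantaneous rate irrespective of backslide re-climbs; the net-length ÷
  duration variant is reported alongside.
- **Event length** is the maximal baseline-referenced excursion plus a
  first-order boxcar correction (+rate·dt/2) for the clipped peak sample.
- **Pauses** are called on a 3-frame-smoothed velocity against an adaptive
  threshold (half the event's own median moving velocity, capped at
  v_pause) so slow events are not spuriously flagged.  Rehybridization
  pauses are plateaus (|v| < 75 bp/s for ≥2 frames) strictly between the
  event maximum and the baseline — against a 2000 bp/s descent these are
  unambiguous.
- **Dwells** run from an event's return to baseline to the next
  *initiation*, where initiations include sub-threshold events: any
  velocity run with ≥50 bp net climb, and any single-frame excursion
  >40 bp (≈4σ of 3 Hz noise) rising from baseline, terminates a dwell
  even though it is too small to count as an event.

### Detection-limit corrections

Two corrections make the fitted constants unbiased estimates of the
generative ones; both are standard truncation/censoring arguments and both
are validated against the simulator's ground truth.

1. **Event lengths.**  An event moving at rate v must sustain the velocity
   threshold for ≈2.5 filtered frames, so it is observable only above
   a(v) = max(100 bp, v·2.5/3 Hz) — ≈290 bp at 215 bp/s.  (The 2.5-frame
   constant was measured by injecting noiseless ramps of known length and
   rate into the filter chain and locating the 50% detection point.)  For
   an exponential length law, memorylessness makes the per-event-truncated
   MLE exact: mean = mean(Lᵢ − a(vᵢ)).
2. **Dwell times.**  Initiations below the spike-marker floor go unseen, so
   a geometric number of consecutive dwells merge; for exponential dwells
   the observed mean is inflated by exactly 1/(1−p).  p is estimated from
   the fitted length distribution as 1 − exp(−40 bp/⟨L⟩) — the effective
   floor equals the spike threshold because the boxcar preserves the area
   of a brief excursion, so phase-averaged 50% detection sits at the
   threshold itself (confirmed against ground truth: 7.1% true missed
   fraction vs 7.0% estimated at the 30 nM condition).  Dwells shorter
   than the backslide window are absorbed into events, an ordinary left
   truncation handled the same way as (1).

## Distribution fits

Exponential fits are maximum likelihood (mean = sample mean, SE =
mean/√n), with optional scalar or per-sample left truncation as above; a
histogram least-squares estimate ("error of fitting" convention) is
reported alongside in `extras`.  Gaussian and Gamma models for rate
distributions are both fitted by ML; R² on a Freedman–Diaconis-binned
density (≥8 bins) is reported for display, but the *preferred* model is
chosen by log-likelihood, because binned R² flags the wrong model a third
of the time on near-symmetric data while the likelihood discriminates at
>95%.  Arrest-length discrimination (Gaussian vs exponential) compares
log-likelihoods directly.  The kon fit is unweighted least squares of
⟨Δt⟩ = 1/(kon·c) (a 1/SE²-weighted option exists behind a flag); dwells
following backslide restarts are excluded upstream, since those waiting
times reflect a pre-bound enzyme rather than association from solution.

## Bulk kinetics

Michaelis–Menten (kcat = 101 s⁻¹, Km = 223 µM), hyperbolic ssDNA
activation (basal 1 s⁻¹, Vmax 101 s⁻¹, K_DNA 1.66 µM nt) and
single-exponential progress curves (displacement kobs = 0.48 min⁻¹;
helicase 0.66 and 0.05 min⁻¹) are fitted by nonlinear least squares
weighted for the multiplicative (constant-CV) error model that
coupled-assay and gel-quantification noise actually follow — σᵢ ∝ yᵢ,
floored at 10% of the largest signal.  The synthetic generator applies
unit-mean lognormal noise at CV 3% (rate assays) or 5% (gel time
courses).  Designs: 8 ATP points log-spaced over 0.05–2 mM; 8 DNA points
0–20 µM nt; 8 timepoints over 4 min; 3 replicates.  The iron assay is
Beer–Lambert arithmetic (ε535 = 22 369 M⁻¹cm⁻¹) through the stated
dilution scheme (10 µl of 15 µM protein into ≈143 µl of assay volume).

## Problem sizes

The recovery analyses pool simulated hour-long tethers until each
condition holds at least 550 events (30 nM), 500 (163 nM), 350
(bottom-nicked) — comfortably above the event counts the study reports
(147–290) — with 300 initiation waits per concentration for the kon fit.
These sizes put the sampling SE of each stochastic statistic at 4–6%,
small against the 15% recovery tolerance.  A full condition simulates and
segments in well under a second.

## What the synthetic data do not capture

- Multi-motor traffic: the concentration-dependent slowing, pausing and
  processivity changes are *installed phenomenologically* per profile, not
  produced by a mechanistic multi-motor collision model.
- Bead physics: no hydrodynamics, no rotational dynamics, white rather
  than Lorentzian position noise, no drift by default.
- Nuclease chemistry, Mg²⁺ dependence, and the wild-type enzyme's
  self-inhibition; the single-molecule statistics all describe the
  nuclease-dead mutant under low free Mg²⁺.
- The segmentation defaults are tuned for the looping geometry; in the
  canonical geometry the conversion constant is ~7× smaller and the same
  thresholds flood with noise events.

Passing recovery tests therefore demonstrate that the analysis chain is an
unbiased, correctly calibrated estimator of the generative parameters under
realistic noise — not that these parameters are the only model consistent
with real recordings.
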