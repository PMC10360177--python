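# Methods

## Scope and intent

`pacesim` couples an adaptive stimulation controller to a deliberately
minimal synthetic respiratory plant. The controller side is a faithful
implementation of the PG/PS (pattern generator / pattern shaper) scheme used
in closed-loop diaphragm pacing; the plant side is a stand-in for an
anesthetized, spontaneously breathing rat, built only as detailed as the
closed-loop behaviors require. Quantities the package computes — tracking
error, charge, fatigue indices, sigh volumes, entrainment onsets — are
properties of this simulated preparation, not predictions of animal values.

## Controller

**Pattern generator.** A fixed-period clock. The period is the measured
baseline breath period, rounded to the nearest whole number of 40 ms control
steps (exact half-step ties round down, so a 1.5 s baseline becomes
1.48 s = 37 steps). Controller rate is 25 Hz throughout.

**Pattern shaper.** One single-layer network serves both muscles: 25
Gaussian basis functions uniformly tiling cycle phase, width σ = 1/25 of a
cycle (with this spacing the basis sum is flat in phase to better than 1%).
Output is the clipped weighted sum u ∈ [0, 1]. Learning is a delta rule on
the per-step normalized volume error with nonnegativity clipping; the basis
activation used for credit assignment is evaluated 80 ms (two control steps)
earlier in phase, compensating the actuation-plus-sensing lag (τ_lung =
150 ms; the compensation deliberately undershoots since the error sample
itself is also lagged). Default learning rate η = 0.03 per step. Two
safeguards keep the integrator honest: updates happen only inside the
stimulation window, and weights do not grow while the output is already
clipped at 1 (anti-windup; without it, pre-entrainment wind-up takes ~50
cycles to unwind and contaminates early charge measurements).

**Stimulation window.** Stimulation and learning are confined to the steps
where the desired volume is rising or within 10% of its peak. Pacing assists
inspiration only; expiration is passive.

**Channel mapping.** Each channel maps u affinely from its twitch threshold
(u just above the 0.05 activation floor) to its maximum amplitude (u = 1)
and saturates there. Defaults: diaphragm 1.5 → 3.0 mA, intercostal
1.0 → 2.0 mA (maximum = 2 × threshold, inside the conventional 1.5–2×
safety band). Pulses are cathodic-first biphasic, 80 µs/phase at 75 Hz;
charge bookkeeping counts the leading phase only, since the pulses are
charge-balanced — stated so the numbers are comparable across conventions.

**Sighs.** Every 30th cycle the stored normalized outputs of the previous
(non-sigh) cycle are replayed at exactly 2×, then clipped per channel at the
hardware maximum. Learning pauses for the sigh cycle and the following one;
the weight vector is bit-identical across the pause.

## Plant

All plant state advances by explicit Euler at 1 ms (40 substeps per control
step); a refinement test confirms the trace changes by < 0.5% when the step
is halved.

**Recruitment.** Activation is 0 below the twitch threshold and linear up to
the saturation current (2 × threshold), matching the channel map so that
a ≈ u in steady operation.

**Lung.** First-order volume dynamics, τ_lung = 0.15 s, driven by
P = D₀·c(t) + g_dia·a_dia + g_eic·a_eic + g_syn·a_dia·a_eic (ml), where c(t)
is the intrinsic drive. The synergy term makes co-activation worth more than
the sum of its parts, reflecting thoracic stabilization by the intercostals.
Gains are calibrated, not measured: g_dia = 1.8, g_eic = 0.65, g_syn =
0.5 ml. The calibration criteria were (i) diaphragm-only pacing can reach
the 120% target, approaching saturation as fatigue accumulates, while
(ii) combined pacing reaches it at distinctly lower diaphragm charge, and
(iii) neither mode is pinned at its amplitude limit after adaptation, so
charge remains a live readout of fatigue compensation. Smaller diaphragm
gains (≈1.0 ml) fail criterion (i) outright: the muscle saturates below the
Hering-Breuer threshold, entrainment never bootstraps, and the fatigue
comparison inverts.

**Fatigue.** Per muscle, dF/dt = k_f·q̇·(1−F) − ρ·F with q̇ the delivered
charge rate (mC/s); effective activation is a·(1−F). Equilibrium under
constant charge rate is k_f q̇/(k_f q̇ + ρ), verified against the closed form
to 1%. Defaults k_f = 0.15 /mC and ρ = 0.0015 /s (both muscles, identical)
were chosen so a 550-cycle diaphragm-only trial lands at a fatigue index of
roughly 0.1–0.3 — enough headroom for the paired comparison — with a
recovery time constant (~11 min) long against a trial. These are design
values, not physiological claims.

**Intrinsic oscillator.** A phase oscillator with period T₀ = 1.5 s;
the inspiratory half emits a half-sine drive whose amplitude is calibrated
(exactly, by linearity) so the unassisted plant produces the 1.0 ml baseline
tidal volume. The Hering-Breuer inflation reflex is modelled with
hysteresis: if volume reaches V_HB = 1.1 × baseline tidal volume during
intrinsic inspiration, inspiration terminates (phase jumps to expiration)
and the reflex engages; while engaged, expiratory phase is held, releasing
only when volume falls below 0.25 × V_HB. Engagement-by-inflation plus
release-by-deflation is what phase-locks the intrinsic rhythm to a paced
breath larger than V_HB: the next intrinsic breath can only start one
expiratory half-period after the paced breath has emptied. With the cut
alone (no hold) the oscillator settles into a stable *anti-phase* lock —
its inspiration repeatedly fires during paced expiration — and the paced
target becomes unreachable in every mode; the hysteresis is therefore part
of the mechanism, not a tuning nicety. The reflex never engages during
spontaneous breathing (baseline peaks at 1.0 < 1.1).

One entrainment behavior deserves honesty: lowering the target to 100% of
baseline does *not* de-entrain this plant. Transient overlap of the paced
and intrinsic breaths still exceeds V_HB often enough to re-lock the rhythm,
and raising V_HB far enough to prevent that destroys the fatigue-comparison
regime. The on/off dichotomy the tests assert is therefore mechanistic:
reflex enabled → phase lock at the 120% target; reflex disabled (or
stimulation off) → free run at T₀, drifting ~1.35% of a cycle per cycle
against the quantized 1.48 s pacing period.

**Sensor.** Measured volume is true volume minus a baseline captured at each
paced cycle start, plus Gaussian noise (σ = 0.02 ml). The physical
flow-integrator time constant (0.2 s) is carried as metadata; the simulated
readout is instantaneous so that the noise-free measurement equals the true
volume change exactly.

## Protocol

Each trial: ≥ 60 s of spontaneous breathing; baseline tidal volume and
period are the averages over baseline cycles, excluding any cycle whose peak
exceeds 1.5 × the running median (sigh-like behavior); the desired pattern
is a half-sine over the inspiratory half-cycle with peak = 1.2 × baseline
tidal volume at the baseline period; then the closed loop runs for the
configured duration. Trials are independent — fatigue resets between them,
standing in for the 20–30 min inter-trial rest. A session runs one trial per
(mode × sigh) combination in seed-shuffled order. Cohorts apply ±10%
uniform, seeded jitter to plant gains and twitch thresholds per subject
(channel limits track the jittered thresholds at 2×), standing in for
inter-animal variability. One seed per trial feeds every stochastic draw in
a fixed order; identical (config, seed) reruns are bit-identical.

## Metrics

* **iRMSE** per cycle: 100 × RMS(desired − measured over the inspiratory
  window) / peak(desired). Normalization by the desired peak keeps the
  0–100% scale consistent with the 10%/20% thresholds; the inspiratory
  window is the same rising-or-near-peak mask the controller stimulates in.
* **Entrainment onset**: first cycle starting ≥ 20 consecutive cycles with
  iRMSE strictly below 20%. **Adaptation**: same with ≤ 10% (inclusive).
* **Fatigue index**: mean charge over a 50-cycle final window vs a 50-cycle
  initial window, (Q_f − Q_i)/Q_i; initial window at entrainment onset,
  final window 400 cycles later ("approximately 400" fixed at exactly 400),
  both overridable. Requires ≥ 450 cycles past onset.
* **Sigh tidal volume factor**: sigh-cycle tidal volume / targeted tidal
  volume.
* **Synchrony**: a sigh is preceded by loss of synchrony when ≥ 3
  consecutive pre-sigh cycles have |onset phase error| > 0.25 cycles (the
  tolerance is a package default, configurable); it resets synchrony when
  the error returns within tolerance within 3 post-sigh cycles.
* **Wilcoxon signed-rank, one-sided**: exact p over all 2ⁿ sign assignments
  (dynamic programming on doubled ranks; average ranks on ties; zero
  differences dropped; n ≤ 25). The direction must be supplied by the
  caller — the protocol's hypotheses are directional.

## Strength-duration toolkit

The Weiss (charge-linear) form I(pw) = I_rh(1 + t_ch/pw) is used because it
is the standard hyperbolic strength-duration law and is linear in its
parameters after multiplying by pw (fit as Q = I·pw against pw by ordinary
least squares). Both rheobase conventions are reported: the fitted asymptote
and the operational threshold-at-500-µs, together with the pulse width where
the fitted curve crosses twice the operational rheobase. The two chronaxie
readings differ by construction by a relative factor
(2·t_ch/500)/(1 + 2·t_ch/500). Simulated measurements draw rheobase from
[0.35, 1.3] mA and chronaxie from [35, 100] µs with multiplicative Gaussian
noise over the 14-point grid (500→100 µs by 100, 100→10 µs by 10).

## Problem sizes

Default suite and reproduction runs use 500-cycle single trials (~12.5 min
of simulated pacing) and 6-subject × 550-cycle × 2-mode cohorts — the same
cycle counts the fatigue-index definition requires — which complete in
seconds to a couple of minutes on one core at the 1 ms plant step.

## What the synthetic plant does and does not show

The plant reproduces the qualitative closed-loop phenomena: adaptation to a
target pattern, volume-triggered entrainment, charge-reflected fatigue and
its reduction under load sharing, sigh elicitation with larger sighs under
co-activation. It omits compliance/resistance partitioning, gas exchange and
CO₂ chemoreflexes, intrinsic sigh generation, respiratory-rate variability,
and any animal-to-animal physiology beyond parameter jitter. Passing tests
therefore demonstrate correctness of the controller, metrics and protocol
logic under a plausible plant — not agreement with animal-specific numbers
(cycles-to-entrainment means, reset success rates, p-values), which depend
on data this package does not model.
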