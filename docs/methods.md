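# Methods

## Model

The generative model has two levels. The top level contains, per candidate
syllable, an evidence accumulator ω (a perfect integrator: in the
generative direction dω/dt = 0 between resets), read out through a softmax
ψ = softmax(ω) that represents the instantaneous belief over syllable
identity; an 8-unit gamma sequence y₁…y₈ indexing temporal position within
a syllable's 6×8 spectrotemporal template; and a theta module that tracks
the stimulus envelope. The bottom level is a 6-channel spectral state z.
The model's prediction of the current spectrogram column is the belief- and
position-weighted blend of stored templates,

    u = Σ_k ψ_k (T_k · y),

and z relaxes toward u while being pushed toward the observed column by the
input prediction error.

**Precision oscillator.** Two hidden states follow a harmonic rotation with
angular increment k₁ = 2πΨ/1000 per 1 ms sample, initial condition
(p₁, p₂) = (0, 1) so p₂ is a unit cosine at Ψ Hz. Each deterministic step
is the exact unit-step propagator (a rotation by k₁ radians), which agrees
with forward Euler to O(k₁²) while conserving p₁² + p₂² exactly; explicit
Euler variants drift measurably at the upper end of the 2–60 Hz sweep
(k₁ ≈ 0.38), where the amplitude — and with it the precision range — must
stay fixed for variants to be comparable across frequencies. Optional
Gaussian state noise (default 0) is added after each rotation.

The causal-state precisions are exponentials of affine functions of p₂
(intercepts and slopes per variant, table in the README). The amplitude of
p₂ is a modelling choice — only the products slope×amplitude matter — and
unit amplitude makes the tabulated slopes span the intended log-precision
ranges. The stationary baseline uses the intercepts (the p₂ → 0 limit of
the oscillating schedules) as its constant precisions and carries no
oscillator states: 17 state variables versus 19.

**Theta.** A canonical theta neuron, dφ/dt = r[(1 − cos φ) + I(1 + cos φ)]
with baseline drive I₀ = 0.25 and rate scale r = π/(200·√I₀), free-runs at
exactly 5 Hz. Drive above baseline shortens the cycle (period ∝ 1/√I). A
Gaussian pulse of the wrapped phase distance to a predefined onset phase
(set to π, in the fast half of the cycle, so the pulse is temporally sharp)
signals syllable onset; the rate signal √(I/I₀) — the theta neuron's cycle
rate relative to rest — signals speech rate. During inversion theta is
driven by the envelope's excursion above its 200 ms running mean rather
than its standing level, so a loud but steady stretch does not detune the
intrinsic rhythm.

**Gamma.** The 8-unit sequence is a cyclic Lotka–Volterra winnerless
competition, dx_i/dt = κ·rate·x_i(σ − Σ_j ρ_ij x_j), with ρ_ii = 1, weak
inhibition 0.5 of each unit's successor and strong inhibition 1.5
elsewhere, integrated at 1 ms steps (two half-step substeps) with an
activity floor of 10⁻⁶ that makes the saddle escapes deterministic. The
gain κ = 1.37847 was set once by bisection so a new unit becomes dominant
every 25 ms at rest (40/s; one full 8-unit cycle per 200 ms, i.e. 5
syllable cycles/s). Rates are measured as (events − 1)/span between the
first and last event, the estimate unaffected by endpoint truncation.

**Resets.** When the last gamma unit's output exceeds 0.6 — the same
threshold that defines segmentation markers — a reset gate opens and ω
relaxes toward its mean at 0.2/ms, so the softmax returns toward uniform
for the next syllable. Relaxation toward a common value preserves the
evidence ranking at every intermediate stage. Evidence integration pauses
while the gate is open (these are exactly the "active resetting" windows
the integration-efficacy metric masks out with h(t) = 0); without the
pause, the handful of samples straddling a reset can overwrite the
near-uniform ranking with arbitrary transients.

## Inversion

Recognition runs the generative dynamics forward while every inferred
state descends the precision-weighted squared prediction errors at 1 ms
steps:

- ω: dω_i = η_ω·V_ω(t)·ψ_i[(T_i·y − u)·(z − u)] — the exact gradient of
  ½V_ω‖z − u‖² through the softmax — paused during resets;
- gamma: a multiplicative correction η_γ·V_γ(t)·(∂u/∂y)ᵀ(z − u) on x,
  clipped at ±0.3 per step as a stability guard;
- z: dz = −η_λ·V_ω(t)·(z − u) + η_z·(s(t) − z). The top-down pull toward
  u carries the same precision as the causal error it descends, so
  high-precision phases are bottom-up dominated and low-precision phases
  top-down dominated — the alternation of regimes the oscillating variants
  are built to exploit;
- p₂ is integrated concurrently (frozen at 0 for the stationary variant)
  and sets V_ω(t), V_γ(t) through the variant's schedule.

Learning rates were calibrated once on noiseless single-syllable stimuli
and frozen: η_ω = 0.02, η_z = 0.4, η_λ = 0.016, η_γ = 0.001. η_γ is kept
small enough that even at the peak of the gamma-precision oscillation
(e^5.5 ≈ 244) the per-step correction does not destroy the heteroclinic
sequence. The theta couplings into gamma (onset-pulse injection and rate
pacing) default to zero: with this corpus the envelope's filter delay
(~80 ms) makes pulse-triggered restarts arrive late enough to disrupt the
free-running 40 Hz cycle, which self-aligns to the 200 ms mean syllable
duration; both couplings remain available as options, and the theta module
itself is exercised and tested per its contract.

A sentence whose states leave the finite range is truncated at the failing
sample and flagged (`status="diverged"`); downstream analyses carry the
flag and drop such sentences pairwise in paired tests, never silently.

**Segmentation.** Markers T_γ are the strict local maxima of y₈ with
amplitude ≥ 0.6; a plateau contributes its first sample (deterministic and
order-preserving). G = [0, …T_γ…, T] defines the windows; per window, the
winner is the syllable with the highest mean ψ (ties to the lowest index),
and degenerate windows are dropped.

## Metrics

All time sums use the 1 kHz grid with half-open windows [start, end), so
each sample belongs to exactly one syllable and one window; this resolves
the double counting a closed-interval convention would create at shared
boundaries. Logarithms are natural throughout; the normalized entropy
E = −(1/ln N)Σψ ln ψ is base-independent and carries the leading minus its
[0, 1] normalization requires. The integration efficacy combines
positive-with-positive and negative-with-negative parts of the bottom-up
syllable error and the evidence derivative, masked by h(t), and averages
over the sentence's syllables as a plain mean (`rms=True` switches to a
root-mean-square aggregate). Zero probabilities on true syllables are
floored at the smallest positive float and flagged. The BIC is
Σ log p − 0.5·N_sent·ln N_p, higher is better.

## Synthetic corpus

The generator emulates the statistical structure of reduced speech
spectrograms: 6 frequency channels × 8 temporal bins per syllable template,
~200 ms mean syllable duration (Gamma-distributed, default coefficient of
variation 0.3, floored at 8 ms so every bin spans ≥ 1 sample), rendering by
piecewise-constant expansion of the 8 columns over 8 equal sub-windows
(inverting the temporal binning exactly, so noiseless rendering followed by
binned averaging round-trips the template), and an envelope — the column
sum low-passed by two causal 50 ms boxcar passes — that peaks once per
syllable shortly after its onset. Templates are i.i.d. uniform fields
smoothed along the temporal axis only (adjacent bins correlate, as in
speech; smoothing across channels was found to collapse the spectral
contrast that discrimination rests on) with per-column energy rescaled to a
declining onset profile (column sums 2·linspace(1, 0.4, 8)): the onset-heavy
energy is what gives the envelope its one-peak-per-syllable shape, while
the channel distribution within each column stays fully random.

Sensory noise is rectified i.i.d. Gaussian per sample and channel, default
sd 0.05: the inputs being emulated are deterministic transforms of clean
recordings, so noise is a small perturbation, exposed as a free parameter.
What the generator does **not** emulate: coarticulation (each syllable
renders identically in every context), speaker variability (one fixed
template per syllable), correlated spectrotemporal distortions, and any
phonotactic structure in the syllable sequence (ids are i.i.d. uniform).
Passing results on this corpus therefore demonstrate the mechanics of the
model and metrics — not robustness to the variability of real speech.

## Study conditions and what the experiments show

The default study corpus is 30 sentences of 8 syllables from a 10-template
inventory (inventory seed 1, corpus seed 0), mean duration 200 ms,
cv 0.3, noise sd 0.05 — sizes chosen so the full recognition study runs in
minutes on one CPU. On it, the oscillating-precision variants reproduce
the directional effect of interest: the full anti-phase variant at 20 and
30 Hz achieves higher mean overlap than the stationary baseline (the test
suite recomputes this end to end). The advantage arises in the
dynamics-limited regime — duration jitter misaligns the gamma cycle with
the true syllable windows, and concentrated high-precision episodes
interleaved with top-down consolidation of the spectral state cope with
that misalignment better than a constant compromise gain. Two boundaries
of the effect, both computed by the package and worth knowing: with heavy
i.i.d. sample noise (sd ≥ 0.2) the ordering reverses, as uniform-gain
integration is the optimal filter for white noise and bursty gain reduces
the effective sample count; and the low end of the sweep (2 Hz, half-cycles
longer than a syllable) does not show the clean deficit seen in the
reference setting, since entire syllables fall into single high- or
low-precision phases whose effects average out across a corpus.

## Numerical conventions

Time is integer milliseconds, 0-based, half-open; all traces share the
1 kHz base. Winner ties break toward the lowest syllable index. Softmax is
computed with max subtraction; ω is re-centered each step (softmax is
shift-invariant), preventing drift. The state guard flags |state| > 10⁶ or
any non-finite value. All randomness flows through
`numpy.random.default_rng` seeds carried by the corpus, options and sweep
specifications; every pipeline output is a pure function of its seeds.

## Known limitations

The inversion is a first-order precision-weighted gradient flow, not a
generalized-coordinates filtering scheme; it exposes the same
precision-gating of bottom-up messages but makes no claim of Bayes
optimality. The theta→gamma couplings, though implemented, are disabled by
default (above), so speech-rate adaptation is not exercised in the default
study. Word- and phrase-level structure, learning of templates, and any
auditory-periphery modelling are out of scope.
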