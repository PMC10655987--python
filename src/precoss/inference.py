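"""Model inversion: online recognition by precision-weighted gradient flow.

The generative dynamics run forward while every inferred state also descends
the precision-weighted squared prediction errors:

    d(mu) = f_gen(mu) dt - eta * d/d(mu) [ sum_levels Pi_level(t) eps_level^2 ] dt

Bottom-level errors compare the observed spectrogram column (and envelope)
with the spectral state; the causal error between the spectral state and the
syllable/gamma-composed target drives the syllable accumulators (weighted by
V_omega(t)) and the gamma units (weighted by V_gamma(t)). V_omega and
V_gamma come from the variant's schedule evaluated on the concurrently
integrated precision-oscillator coordinate p2(t); the stationary baseline
freezes p2 = 0. The theta module is driven by the observed envelope and
paces the gamma sequence; the last gamma unit's dominance opens the reset
gate that clears accumulated evidence between syllables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import StimulusArrays, SyllableInventory
from .generative import (
    DT_MS,
    GAMMA_FLOOR,
    N_GAMMA,
    RESET_RATE,
    ThetaState,
    VariantConfig,
    gamma_init,
    gamma_step,
    precision_oscillator_simulate,
    theta_step,
    variant_config,
)

MARKER_THRESHOLD = 0.6


@dataclass(frozen=True)
class InferenceOptions:
    """Learning rates and numerical guards for the inversion.

    The rates were calibrated once on noiseless single-syllable stimuli
    (so that the stationary baseline commits to the correct syllable within
    one ~200 ms cycle) and are frozen; the integration step is fixed at
    1 ms to stay aligned with the stimulus.
    """

    eta_omega: float = 0.02  # syllable-evidence rate (per unit precision)
    eta_gamma: float = 0.001  # gamma correction rate
    eta_z: float = 0.4  # bottom-level assimilation rate
    eta_lambda: float = 0.016  # spectral top-down relaxation per unit precision
    onset_gain: float = 0.0  # theta onset pulse injection into gamma unit 1
    theta_drive_gain: float = 0.0  # theta drive per unit envelope deviation
    env_adapt_tau: float = 200.0  # ms; running-mean adaptation of the envelope
    rate_tau: float = 400.0  # ms; smoothing of the speech-rate signal
    gamma_clip: float = 0.3  # per-ms cap on multiplicative gamma corrections
    p_noise_sd: float = 0.0  # oscillator state noise
    seed: int = 0
    marker_threshold: float = MARKER_THRESHOLD
    state_guard: float = 1e6  # non-finite / blow-up detection bound

    def __post_init__(self) -> None:
        if min(self.eta_omega, self.eta_gamma, self.eta_z) <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class RecognitionTrace:
    """Full per-sample record of one recognition run (1 kHz time base)."""

    omega: np.ndarray  # (T, N) accumulated evidence
    softmax_omega: np.ndarray  # (T, N) instantaneous syllable beliefs
    y: np.ndarray  # (T, 8) gamma outputs
    z: np.ndarray  # (T, 6) spectral state
    z_pe: np.ndarray  # (T, N) signed bottom-up syllable prediction errors
    gamma_pe: np.ndarray  # (T, 8) gamma-level prediction errors
    input_pe: np.ndarray  # (T, 7) spectrogram (6) + envelope (1) errors
    logv_omega: np.ndarray  # (T,)
    logv_gamma: np.ndarray  # (T,)
    h: np.ndarray  # (T,) 1 outside active resetting, 0 inside
    reset_gate: np.ndarray  # (T,)
    markers: np.ndarray  # G: [0, ...T_gamma..., T] in samples
    status: str  # "ok" or "diverged"
    n_state_variables: int
    variant: str
    psi: float

    @property
    def n_samples(self) -> int:
        return self.omega.shape[0]

    @property
    def y8(self) -> np.ndarray:
        return self.y[:, N_GAMMA - 1]


def segmentation_markers(
    y8_trace: np.ndarray, threshold: float = MARKER_THRESHOLD
) -> np.ndarray:
    """Gamma-based segmentation boundaries G = [0, ...T_gamma..., T].

    T_gamma are the strict local maxima of the last gamma unit's output with
    amplitude >= threshold; a plateau of maximal value contributes a single
    marker at its first sample. Consecutive duplicates are removed; a trace
    without interior maxima yields the single window [0, T].
    """
    y = np.asarray(y8_trace, dtype=float)
    T = len(y)
    # run-length encode equal values so plateaus become single candidates
    starts = [0]
    for t in range(1, T):
        if y[t] != y[t - 1]:
            starts.append(t)
    markers = []
    for k in range(1, len(starts) - 1):
        v = y[starts[k]]
        if v >= threshold and v > y[starts[k - 1]] and v > y[starts[k + 1]]:
            markers.append(starts[k])
    G = [0] + markers + [T]
    G = [g for i, g in enumerate(G) if i == 0 or g > G[i - 1]]
    return np.asarray(G, dtype=int)


def invert(
    stimulus: StimulusArrays,
    sentence_inventory: SyllableInventory,
    config: VariantConfig,
    psi: float = 20.0,
    opts: InferenceOptions | None = None,
) -> RecognitionTrace:
    """Invert the generative model on a rendered stimulus.

    Returns the full recognition trace; if any state leaves the finite
    range the trace is truncated at the failing sample and flagged with
    status "diverged" so downstream analyses can exclude the sentence
    explicitly rather than silently.
    """
    if not 0 < psi < 500:
        raise ValueError("psi must lie in (0, 500) Hz")
    if opts is None:
        opts = InferenceOptions()
    T = stimulus.n_samples
    N = sentence_inventory.n_syllables
    stacked = sentence_inventory.stacked()  # (N, 6, 8)
    spec = stimulus.spectrogram
    env = stimulus.envelope

    if config.variant == "stationary":
        p2 = np.zeros(T)
    else:
        _, p2 = precision_oscillator_simulate(
            psi, T, noise_sd=opts.p_noise_sd, seed=opts.seed
        )

    tr = RecognitionTrace(
        omega=np.zeros((T, N)),
        softmax_omega=np.zeros((T, N)),
        y=np.zeros((T, N_GAMMA)),
        z=np.zeros((T, 6)),
        z_pe=np.zeros((T, N)),
        gamma_pe=np.zeros((T, N_GAMMA)),
        input_pe=np.zeros((T, 7)),
        logv_omega=np.zeros(T),
        logv_gamma=np.zeros(T),
        h=np.ones(T),
        reset_gate=np.zeros(T),
        markers=np.array([0, T]),
        status="ok",
        n_state_variables=config.n_state_variables,
        variant=config.variant,
        psi=psi,
    )

    # theta is driven by the envelope's excursion above its running mean
    # (the onset transient), not its standing level, so a loud-but-flat
    # stretch does not detune the intrinsic ~5 Hz rhythm
    theta = ThetaState(gain=opts.theta_drive_gain)
    env_mean = env[0]
    rate_smooth = 1.0
    gamma = gamma_init()
    omega = np.zeros(N)
    z = spec[:, 0].copy()
    a_om, b_om = config.logv_omega
    a_ga, b_ga = config.logv_gamma
    dt = DT_MS

    for t in range(T):
        logv_om = a_om + b_om * p2[t]
        logv_ga = a_ga + b_ga * p2[t]
        V_om, V_ga = np.exp(logv_om), np.exp(logv_ga)

        env_dev = max(env[t] - env_mean, 0.0)
        env_mean += (env[t] - env_mean) / opts.env_adapt_tau
        theta, pulse, rate_inst = theta_step(theta, env_dev)
        # gamma paces itself by the smoothed (speech-rate) signal; the
        # phasic alignment comes from the onset pulse instead
        rate_smooth += (rate_inst - rate_smooth) / opts.rate_tau
        rate = rate_smooth

        w = omega - omega.max()
        psi_vec = np.exp(w)
        psi_vec /= psi_vec.sum()
        y = gamma.x / gamma.x.sum()

        cols = stacked @ y  # (N, 6): each template mixed by gamma outputs
        u = psi_vec @ cols  # predicted spectral column
        B = np.einsum("n,ncb->cb", psi_vec, stacked)  # d(u)/d(y)

        eps_in = spec[:, t] - z
        eps_env = env[t] - z.sum()
        eps_z = z - u
        z_pe = V_om * psi_vec * ((cols - u) @ eps_z)
        g_pe = V_ga * (B.T @ eps_z)

        gate = 1.0 if y[N_GAMMA - 1] >= opts.marker_threshold else 0.0

        # record before updating (states at time t)
        tr.omega[t] = omega
        tr.softmax_omega[t] = psi_vec
        tr.y[t] = y
        tr.z[t] = z
        tr.z_pe[t] = z_pe
        tr.gamma_pe[t] = g_pe
        tr.input_pe[t, :6] = eps_in
        tr.input_pe[t, 6] = eps_env
        tr.logv_omega[t] = logv_om
        tr.logv_gamma[t] = logv_ga
        tr.reset_gate[t] = gate
        tr.h[t] = 0.0 if gate > 0 else 1.0

        # state updates
        gamma = gamma_step(gamma, rate)
        correction = np.clip(dt * opts.eta_gamma * g_pe, -opts.gamma_clip, opts.gamma_clip)
        x = gamma.x * (1.0 + correction)
        x[0] += dt * opts.onset_gain * pulse
        gamma = type(gamma)(x=np.maximum(x, GAMMA_FLOOR), kappa=gamma.kappa)

        # evidence integration pauses while the reset gate is open (the
        # resetting window is excluded from integration, as in the metrics)
        omega = omega + dt * opts.eta_omega * (1.0 - gate) * z_pe
        omega = omega - dt * RESET_RATE * gate * (omega - omega.mean())
        omega = omega - omega.mean()  # softmax-invariant centering

        # the top-down pull of z toward its prediction carries the same
        # precision V_omega as the causal error it descends, so high- and
        # low-precision phases alternate bottom-up and top-down regimes
        z = z + dt * (-opts.eta_lambda * V_om * eps_z + opts.eta_z * eps_in)

        if not (
            np.isfinite(omega).all()
            and np.isfinite(z).all()
            and np.isfinite(gamma.x).all()
            and np.abs(omega).max() < opts.state_guard
            and np.abs(z).max() < opts.state_guard
        ):
            tr.status = "diverged"
            for arr in (
                tr.omega,
                tr.softmax_omega,
                tr.y,
                tr.z,
                tr.z_pe,
                tr.gamma_pe,
                tr.input_pe,
            ):
                arr[t + 1:] = np.nan
            break

    end = T if tr.status == "ok" else min(t + 1, T)
    tr.markers = segmentation_markers(tr.y8[:end], opts.marker_threshold)
    if tr.markers[-1] != T:
        tr.markers = np.append(tr.markers, T) if tr.status == "diverged" else tr.markers
    return tr


def run_baseline(
    stimulus: StimulusArrays,
    inventory: SyllableInventory,
    opts: InferenceOptions | None = None,
) -> RecognitionTrace:
    """Recognition with the stationary-precision baseline (17 state variables)."""
    return invert(stimulus, inventory, variant_config("stationary"), psi=20.0, opts=opts)
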