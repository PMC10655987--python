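"""Hierarchical generative dynamics.

Top level: syllable units (evidence accumulators, one per candidate
syllable), an 8-unit gamma sequence (a stable-heteroclinic-channel network
indexing position within a syllable's spectrotemporal template; 40 Hz unit
rate at rest), and a theta module (a canonical theta neuron driven by the
stimulus envelope, emitting a syllable-onset pulse at a predefined phase and
a speech-rate signal). Bottom level: a 6-channel spectral state relaxing
toward the syllable/gamma-composed target column.

A two-dimensional harmonic oscillator in the hidden states (p1, p2) drives
the oscillating prediction-error precisions: the log-precisions of the
syllable- and gamma-level causal states are affine functions of p2, with
variant-specific intercepts and slopes.

All dynamics are integrated at 1 ms steps (1000 samples/s), aligned with
the stimulus time base.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .corpus import SyllableInventory

SAMPLE_RATE = 1000
DT_MS = 1.0

# --------------------------------------------------------------------------
# Precision oscillator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecisionState:
    """Coordinates of the precision oscillator and its angular increment."""

    p1: float
    p2: float
    psi: float  # modulation frequency, Hz

    @property
    def k1(self) -> float:
        return 2.0 * np.pi * self.psi / SAMPLE_RATE


def precision_oscillator_simulate(
    psi: float, n_samples: int, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the precision oscillator at 1000 samples/s.

    The deterministic part of each step rotates (p1, p2) by the angular
    increment k1 = 2*pi*psi/1000 — the exact unit-step propagator of the
    continuous oscillator dp1/dt = k1*p2, dp2/dt = -k1*p1, which agrees with
    forward Euler to O(k1^2) while conserving p1^2 + p2^2 exactly in the
    noise-free case (explicit Euler variants drift at the larger k1 values
    of the 2-60 Hz sweep). Gaussian noise of sd ``noise_sd`` is added to
    both coordinates after each rotation. Initial condition (p1, p2) =
    (0, 1), so p2 traces a unit-amplitude cosine at ``psi`` Hz.

    Returns (p1_trace, p2_trace), each of length ``n_samples`` with the
    initial state at index 0.
    """
    if psi <= 0:
        raise ValueError("psi must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    k1 = 2.0 * np.pi * psi / SAMPLE_RATE
    c, s = np.cos(k1), np.sin(k1)
    rng = np.random.default_rng(seed)
    p1 = np.empty(n_samples)
    p2 = np.empty(n_samples)
    p1[0], p2[0] = 0.0, 1.0
    for t in range(1, n_samples):
        a, b = p1[t - 1], p2[t - 1]
        p1[t] = c * a + s * b
        p2[t] = -s * a + c * b
        if noise_sd > 0:
            p1[t] += rng.normal(0.0, noise_sd)
            p2[t] += rng.normal(0.0, noise_sd)
    return p1, p2


# --------------------------------------------------------------------------
# Variant precision schedules
# --------------------------------------------------------------------------

VARIANT_NAMES = (
    "stationary",
    "identity",
    "timing",
    "full_antiphase",
    "full_samephase",
)


@dataclass(frozen=True)
class VariantConfig:
    """Precision constants and p2-dependent log-precision schedules.

    ``logv_omega`` / ``logv_gamma`` are (intercept, slope) pairs: the causal
    log-precision of the syllable / gamma level is intercept + slope * p2.
    ``W_omega``, ``W_gamma``, ``W_p`` are the stationary log-precisions of
    the hidden states. The stationary baseline has both slopes zero and no
    precision hidden states (17 state variables vs 19).
    """

    variant: str
    logv_omega: tuple[float, float]
    logv_gamma: tuple[float, float]
    W_omega: float = 3.0
    W_gamma: float = 5.0
    W_p: float = 5.0

    @property
    def n_state_variables(self) -> int:
        return 17 if self.variant == "stationary" else 19

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "logv_omega": list(self.logv_omega),
            "logv_gamma": list(self.logv_gamma),
            "W_omega": self.W_omega,
            "W_gamma": self.W_gamma,
            "W_p": self.W_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariantConfig":
        return cls(
            variant=d["variant"],
            logv_omega=tuple(d["logv_omega"]),
            logv_gamma=tuple(d["logv_gamma"]),
            W_omega=float(d.get("W_omega", 3.0)),
            W_gamma=float(d.get("W_gamma", 5.0)),
            W_p=float(d.get("W_p", 5.0)),
        )


_SCHEDULES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # variant: ((logV_omega intercept, slope), (logV_gamma intercept, slope))
    "stationary": ((2.5, 0.0), (1.5, 0.0)),
    "identity": ((2.5, 2.0), (1.5, 0.0)),
    "timing": ((5.0, 0.0), (1.5, 4.0)),
    "full_antiphase": ((2.5, 2.0), (1.5, -4.0)),
    "full_samephase": ((2.5, 2.0), (1.5, 4.0)),
}


def variant_config(variant: str) -> VariantConfig:
    """Return the canonical configuration for a named variant."""
    if variant not in _SCHEDULES:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANT_NAMES}")
    om, ga = _SCHEDULES[variant]
    return VariantConfig(variant=variant, logv_omega=om, logv_gamma=ga)


def precision_schedule(config: VariantConfig, p2: float) -> tuple[float, float]:
    """Causal precisions (V_omega, V_gamma) at oscillator coordinate p2."""
    a_om, b_om = config.logv_omega
    a_ga, b_ga = config.logv_gamma
    return float(np.exp(a_om + b_om * p2)), float(np.exp(a_ga + b_ga * p2))


# --------------------------------------------------------------------------
# Theta module
# --------------------------------------------------------------------------

THETA_BASELINE_DRIVE = 0.25
# pi / (free-running period * sqrt(baseline drive)): 200 ms cycle at rest
THETA_RATE_SCALE = np.pi / (200.0 * np.sqrt(THETA_BASELINE_DRIVE))
# gentle rate coupling: a typical envelope level (~3, the column sum of a
# mid-energy spectrogram) speeds the cycle by ~5%, well under the +-30% cap
THETA_ENVELOPE_GAIN = 0.0085
# the onset pulse sits in the fast half of the cycle, so it is swept
# through quickly (temporally sharp) when an envelope onset accelerates
# the neuron out of its slow region near phase 0
THETA_ONSET_PHASE = np.pi
THETA_PULSE_WIDTH = 0.35  # radians


@dataclass(frozen=True)
class ThetaState:
    """Canonical theta neuron tracking the stimulus envelope."""

    phase: float = 0.0
    baseline: float = THETA_BASELINE_DRIVE
    gain: float = THETA_ENVELOPE_GAIN
    onset_phase: float = THETA_ONSET_PHASE
    pulse_width: float = THETA_PULSE_WIDTH


def _wrap(phi: float) -> float:
    """Wrap to (-pi, pi]."""
    return (phi + np.pi) % (2.0 * np.pi) - np.pi


def theta_step(
    state: ThetaState, envelope_sample: float, dt: float = DT_MS
) -> tuple[ThetaState, float, float]:
    """One 1 ms update of the theta neuron.

    d(phase)/dt = r * [(1 - cos phi) + I (1 + cos phi)] with drive
    I = baseline + gain * envelope; the free-running cycle (zero envelope)
    is 200 ms (~5 Hz) and stronger envelope drive shortens it. Returns the
    new state, a Gaussian onset pulse of the wrapped phase distance to the
    predefined onset phase (maximal, 1, exactly at the onset phase), and a
    rate signal equal to the instantaneous cycle rate relative to rest
    (sqrt(I / baseline), i.e. 1 at rest).
    """
    drive = state.baseline + state.gain * max(envelope_sample, 0.0)
    phi = state.phase
    dphi = THETA_RATE_SCALE * ((1.0 - np.cos(phi)) + drive * (1.0 + np.cos(phi)))
    new_phase = (phi + dphi * dt) % (2.0 * np.pi)
    d = _wrap(new_phase - state.onset_phase)
    onset_pulse = float(np.exp(-(d**2) / (2.0 * state.pulse_width**2)))
    rate_signal = float(np.sqrt(drive / state.baseline))
    return replace(state, phase=new_phase), onset_pulse, rate_signal


# --------------------------------------------------------------------------
# Gamma sequence (stable heteroclinic channel)
# --------------------------------------------------------------------------

N_GAMMA = 8
GAMMA_SIGMA = 1.0
GAMMA_RHO_SELF = 1.0
GAMMA_RHO_NEXT = 0.5  # successor weakly inhibited by current winner
GAMMA_RHO_OTHER = 1.5
GAMMA_FLOOR = 1e-6
# growth gain per ms, calibrated once (bisection) to 40 dominance
# transitions per second at rest; see calibrate_gamma_gain()
GAMMA_KAPPA = 1.37847
_GAMMA_SUBSTEPS = 2


def _gamma_rho() -> np.ndarray:
    rho = np.full((N_GAMMA, N_GAMMA), GAMMA_RHO_OTHER)
    np.fill_diagonal(rho, GAMMA_RHO_SELF)
    for i in range(N_GAMMA):
        rho[(i + 1) % N_GAMMA, i] = GAMMA_RHO_NEXT
    return rho


_RHO = _gamma_rho()


@dataclass(frozen=True)
class GammaState:
    """8-unit winnerless-competition network; y is the normalized output."""

    x: np.ndarray
    kappa: float = GAMMA_KAPPA

    @property
    def y(self) -> np.ndarray:
        return self.x / self.x.sum()

    @property
    def dominant(self) -> int:
        """1-based index of the currently dominant unit."""
        return int(np.argmax(self.x)) + 1


def gamma_init(kappa: float = GAMMA_KAPPA) -> GammaState:
    x = np.full(N_GAMMA, GAMMA_FLOOR)
    x[0] = GAMMA_SIGMA
    return GammaState(x=x, kappa=kappa)


def gamma_step(
    state: GammaState, rate_signal: float = 1.0, dt: float = DT_MS
) -> GammaState:
    """One Lotka-Volterra step of the cyclic 8-unit sequence.

    dx_i/dt = kappa * rate * x_i * (sigma - sum_j rho_ij x_j) with the
    asymmetric inhibition matrix enforcing the order 1 -> 2 -> ... -> 8 -> 1;
    a small activity floor makes the saddle escapes deterministic. At
    rate_signal = 1 a new unit becomes dominant every 25 ms (40/s).
    """
    x = state.x.astype(float).copy()
    sub = dt / _GAMMA_SUBSTEPS
    for _ in range(_GAMMA_SUBSTEPS):
        growth = state.kappa * rate_signal * x * (GAMMA_SIGMA - _RHO @ x)
        x = np.maximum(x + sub * growth, GAMMA_FLOOR)
    return replace(state, x=x)


def _event_rate(times_ms: list[int]) -> float:
    """Events per second from event times: (n-1) / span, the unbiased
    rate estimate unaffected by endpoint truncation."""
    if len(times_ms) < 2:
        return 0.0
    return (len(times_ms) - 1) / ((times_ms[-1] - times_ms[0]) / 1000.0)


def gamma_rest_rate(
    duration_ms: int = 2000, kappa: float = GAMMA_KAPPA
) -> float:
    """Dominance-transition rate (per second) of the resting sequence."""
    state = gamma_init(kappa)
    dom = state.dominant
    times = []
    for t in range(duration_ms):
        state = gamma_step(state, 1.0)
        if state.dominant != dom:
            times.append(t)
            dom = state.dominant
    return _event_rate(times)


def syllable_cycle_rate(duration_ms: int = 4000, kappa: float = GAMMA_KAPPA) -> float:
    """Full 8-unit cycle completions (unit 8 -> unit 1) per second at rest."""
    state = gamma_init(kappa)
    dom = state.dominant
    times = []
    for t in range(duration_ms):
        state = gamma_step(state, 1.0)
        if state.dominant != dom:
            if dom == N_GAMMA and state.dominant == 1:
                times.append(t)
            dom = state.dominant
    return _event_rate(times)


def calibrate_gamma_gain(
    target_rate: float = 40.0, lo: float = 0.3, hi: float = 4.0, iters: int = 40
) -> float:
    """One-time bisection for the growth gain hitting ``target_rate`` at rest.

    The resting transition rate increases monotonically with kappa; the
    returned value is frozen as the module default.
    """
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if gamma_rest_rate(kappa=mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Syllable units and spectral level
# --------------------------------------------------------------------------

RESET_RATE = 0.2  # per ms; relaxation rate of evidence toward uniform
HOPFIELD_LAMBDA = 0.1  # per ms; spectral relaxation rate


@dataclass(frozen=True)
class SyllableState:
    """Accumulated log-evidence per candidate syllable (perfect integrators)."""

    omega: np.ndarray

    @property
    def softmax_omega(self) -> np.ndarray:
        w = self.omega - self.omega.max()
        e = np.exp(w)
        return e / e.sum()


def syllable_init(n: int) -> SyllableState:
    return SyllableState(omega=np.zeros(n))


def syllable_reset(
    state: SyllableState, reset_gate: float, dt: float = DT_MS
) -> SyllableState:
    """Relax accumulated evidence toward its mean at a gate-scaled rate.

    With the gate fully open the softmax relaxes to uniform (the state for
    the start of a new syllable); a zero gate leaves the evidence untouched;
    partial resets shrink all contrasts equally, preserving the ranking.
    """
    if not 0.0 <= reset_gate <= 1.0:
        raise ValueError("reset_gate must lie in [0, 1]")
    om = state.omega
    decay = RESET_RATE * reset_gate * dt
    return replace(state, omega=om - decay * (om - om.mean()))


def predict_spectral_target(
    state: SyllableState, y: np.ndarray, inventory: SyllableInventory
) -> np.ndarray:
    """Syllable-probability- and gamma-weighted blend of stored columns.

    target = sum_k softmax(omega)_k * (T_k @ y): each template's 8 columns
    are mixed by the gamma outputs, and templates by the current syllable
    beliefs. The result lies in the convex hull of all stored columns
    whenever y is a probability vector.
    """
    stacked = inventory.stacked()  # (n, 6, 8)
    if len(state.omega) != stacked.shape[0]:
        raise ValueError("inventory size must match omega length")
    y = np.asarray(y, dtype=float)
    if y.shape != (N_GAMMA,):
        raise ValueError(f"y must have length {N_GAMMA}")
    cols = stacked @ y  # (n, 6)
    return state.softmax_omega @ cols


@dataclass(frozen=True)
class SpectralState:
    """6-channel amplitude state of the bottom (Hopfield) level."""

    z: np.ndarray


def hopfield_step(
    state: SpectralState,
    target: np.ndarray,
    dt: float = DT_MS,
    lam: float = HOPFIELD_LAMBDA,
) -> SpectralState:
    """Stable linear relaxation dz/dt = -lam * (z - target)."""
    z = state.z + dt * (-lam) * (state.z - np.asarray(target, dtype=float))
    return replace(state, z=z)
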