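"""Synthetic syllable corpus generation.

Builds seeded inventories of spectrotemporal syllable templates (6 frequency
channels x 8 temporal bins), samples labelled "sentences" as tiled sequences
of syllables with Gamma-distributed durations (mean ~200 ms, matching the
syllabic rate of natural English speech), and renders each sentence into a
6-channel spectrogram at 1000 samples/s plus a slow amplitude-modulation
envelope whose peaks register with syllable onsets.

Time convention: integer-millisecond samples, 0-based, half-open windows
[start, end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SAMPLE_RATE = 1000  # samples per second (1 sample = 1 ms)
N_CHANNELS = 6
N_BINS = 8
MIN_DURATION_MS = 8  # >= 1 sample per temporal bin
ENVELOPE_BOXCAR_MS = 50


@dataclass(frozen=True)
class SyllableTemplate:
    """One syllable's stored spectrotemporal pattern.

    ``pattern`` is a 6x8 matrix of channel energies in [0, 1]: rows are
    frequency channels, columns are the 8 temporal bins read out by the
    gamma units.
    """

    id: int
    pattern: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern, dtype=float)
        if p.shape != (N_CHANNELS, N_BINS):
            raise ValueError(f"pattern must be {N_CHANNELS}x{N_BINS}, got {p.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pattern entries must lie in [0, 1]")
        object.__setattr__(self, "pattern", p)


@dataclass(frozen=True)
class SyllableInventory:
    """Ordered, seeded set of distinct syllable templates with ids 1..n."""

    templates: tuple[SyllableTemplate, ...]
    seed: int
    n_syllables: int

    def __len__(self) -> int:
        return self.n_syllables

    def pattern(self, syllable_id: int) -> np.ndarray:
        if not 1 <= syllable_id <= self.n_syllables:
            raise KeyError(f"unknown syllable id {syllable_id}")
        return self.templates[syllable_id - 1].pattern

    def stacked(self) -> np.ndarray:
        """All patterns as an (n, 6, 8) array."""
        return np.stack([t.pattern for t in self.templates])


@dataclass(frozen=True)
class SentenceStimulus:
    """A labelled syllable sequence tiling [0, total_duration_ms)."""

    syllable_ids: tuple[int, ...]
    onsets_ms: np.ndarray
    offsets_ms: np.ndarray
    seed: int

    @property
    def n_syl(self) -> int:
        return len(self.syllable_ids)

    @property
    def durations_ms(self) -> np.ndarray:
        return self.offsets_ms - self.onsets_ms

    @property
    def total_duration_ms(self) -> int:
        return int(self.offsets_ms[-1])

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets_ms, dtype=int)
        off = np.asarray(self.offsets_ms, dtype=int)
        if len(on) != len(self.syllable_ids) or len(off) != len(self.syllable_ids):
            raise ValueError("onsets/offsets must match syllable_ids in length")
        if on[0] != 0:
            raise ValueError("first syllable must start at 0")
        if np.any(off <= on):
            raise ValueError("durations must be positive")
        if np.any(on[1:] != off[:-1]):
            raise ValueError("syllables must tile the sentence without gaps/overlaps")
        object.__setattr__(self, "onsets_ms", on)
        object.__setattr__(self, "offsets_ms", off)


@dataclass(frozen=True)
class StimulusArrays:
    """Rendered input: 6xT spectrogram and length-T envelope at 1000 Hz."""

    spectrogram: np.ndarray
    envelope: np.ndarray
    sample_rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        s = np.asarray(self.spectrogram, dtype=float)
        e = np.asarray(self.envelope, dtype=float)
        if s.ndim != 2 or s.shape[0] != N_CHANNELS:
            raise ValueError("spectrogram must be 6xT")
        if e.shape != (s.shape[1],):
            raise ValueError("envelope length must equal spectrogram width")
        if not (np.isfinite(s).all() and np.isfinite(e).all()):
            raise ValueError("stimulus arrays must be finite")
        if e.min() < 0:
            raise ValueError("envelope must be nonnegative")
        object.__setattr__(self, "spectrogram", s)
        object.__setattr__(self, "envelope", e)

    @property
    def n_samples(self) -> int:
        return self.spectrogram.shape[1]


def _smooth3(a: np.ndarray, axis: int) -> np.ndarray:
    # 3-tap moving average with edge replication
    padded = np.concatenate(
        [a.take([0], axis=axis), a, a.take([-1], axis=axis)], axis=axis
    )
    kernel = np.ones(3) / 3.0
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"), axis, padded)


def make_inventory(n_syllables: int, seed: int) -> SyllableInventory:
    """Generate ``n_syllables`` distinct 6x8 templates, deterministic in seed.

    Each pattern is an i.i.d. uniform field smoothed by a 3-tap moving
    average along the temporal axis (adjacent bins are correlated, as in
    speech, while spectral contrast between channels is preserved). Each
    temporal column is then rescaled so that its total energy follows a
    declining onset profile — syllables carry most energy at their onset,
    which is what makes the rendered envelope peak once per syllable —
    while the channel distribution within each column stays fully random,
    so templates remain mutually discriminable. Entries lie in [0, 1].
    """
    if n_syllables < 1:
        raise ValueError("n_syllables must be >= 1")
    rng = np.random.default_rng(seed)
    # target per-column energy: sum over the 6 channels = 2 * profile
    onset_profile = np.linspace(1.0, 0.4, N_BINS) * 2.0
    templates = []
    for i in range(n_syllables):
        raw = rng.uniform(size=(N_CHANNELS, N_BINS))
        sm = _smooth3(raw, axis=1)
        pat = np.minimum(sm * onset_profile / sm.sum(axis=0), 1.0)
        templates.append(SyllableTemplate(id=i + 1, pattern=pat))
    return SyllableInventory(templates=tuple(templates), seed=seed, n_syllables=n_syllables)


def sample_sentence(
    inventory: SyllableInventory,
    n_syl: int,
    mean_dur_ms: float = 200.0,
    cv: float = 0.3,
    seed: int = 0,
) -> SentenceStimulus:
    """Draw a random syllable sequence with Gamma-distributed durations.

    Ids are uniform with replacement over the inventory; durations have the
    stated mean and coefficient of variation, rounded to integer ms and
    floored at 8 ms so every temporal bin spans at least one sample. ``cv=0``
    degenerates to constant durations.
    """
    if n_syl < 1:
        raise ValueError("n_syl must be >= 1")
    if mean_dur_ms <= 0:
        raise ValueError("mean_dur_ms must be positive")
    if not 0 <= cv < 1:
        raise ValueError("cv must lie in [0, 1)")
    if inventory.n_syllables < 1:
        raise ValueError("inventory must be non-empty")
    rng = np.random.default_rng(seed)
    ids = rng.integers(1, inventory.n_syllables + 1, size=n_syl)
    if cv * cv == 0.0:  # includes subnormal cv whose square underflows
        durations = np.full(n_syl, round(mean_dur_ms))
    else:
        shape = 1.0 / cv**2
        scale = mean_dur_ms * cv**2
        durations = np.round(rng.gamma(shape, scale, size=n_syl)).astype(int)
    durations = np.maximum(durations, MIN_DURATION_MS)
    offsets = np.cumsum(durations)
    onsets = offsets - durations
    return SentenceStimulus(
        syllable_ids=tuple(int(i) for i in ids),
        onsets_ms=onsets,
        offsets_ms=offsets,
        seed=seed,
    )


def render_stimulus(
    sentence: SentenceStimulus,
    inventory: SyllableInventory,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StimulusArrays:
    """Render a sentence into spectrogram + envelope arrays.

    Each syllable's 8 pattern columns are expanded piecewise-constant over 8
    equal sub-windows of its duration (the inverse of the temporal binning
    that produced the template). Rectified Gaussian noise of standard
    deviation ``noise_sd`` is added per sample/channel. The envelope is the
    per-sample spectrogram column sum low-passed by two causal 50 ms boxcar
    passes; together with the templates' declining energy profile it peaks
    once per syllable, shortly after the onset.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    T = sentence.total_duration_ms
    spec = np.empty((N_CHANNELS, T))
    for syl_id, on, off in zip(
        sentence.syllable_ids, sentence.onsets_ms, sentence.offsets_ms
    ):
        pat = inventory.pattern(int(syl_id))
        L = off - on
        # sample t within the syllable maps to bin floor(t * 8 / L)
        bins = (np.arange(L) * N_BINS) // L
        spec[:, on:off] = pat[:, bins]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spec = np.maximum(spec + rng.normal(0.0, noise_sd, size=spec.shape), 0.0)
    env = spec.sum(axis=0)
    k = ENVELOPE_BOXCAR_MS
    kernel = np.ones(k) / k
    for _ in range(2):  # two causal boxcar passes = triangular low-pass
        env = np.convolve(np.concatenate([np.zeros(k - 1), env]), kernel, mode="valid")
    return StimulusArrays(spectrogram=spec, envelope=env)


def binned_average(segment: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Average a 6xL segment into 6 x n_bins temporal bins.

    Bin b covers samples [floor(b*L/n), floor((b+1)*L/n)) — the binning that
    reduces a rendered syllable back to its stored template.
    """
    segment = np.asarray(segment, dtype=float)
    L = segment.shape[1]
    if L < n_bins:
        raise ValueError(f"segment length {L} shorter than {n_bins} bins")
    edges = (np.arange(n_bins + 1) * L) // n_bins
    return np.stack(
        [segment[:, edges[b]: edges[b + 1]].mean(axis=1) for b in range(n_bins)],
        axis=1,
    )


def make_corpus(
    n_sentences: int,
    inventory: SyllableInventory,
    n_syl: int = 8,
    mean_dur_ms: float = 200.0,
    cv: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[SentenceStimulus, StimulusArrays]]:
    """Generate a seeded list of (sentence, rendered arrays) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sentences):
        s_seed, r_seed = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
        sent = sample_sentence(inventory, n_syl, mean_dur_ms, cv, seed=s_seed)
        arrays = render_stimulus(sent, inventory, noise_sd=noise_sd, seed=r_seed)
        out.append((sent, arrays))
    return out
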