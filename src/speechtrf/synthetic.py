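"""Forward model: synthetic embeddings, corpora, transcripts and EEG cohorts.

Every generator is deterministic given its spec and seed. The EEG forward
model is the convolution of per-feature impulse series with N400-like kernels
weighted by a smooth centro-parietal topography, plus 1/f ("pink") noise,
white sensor noise, and a rank-1 artifact time course shared across subjects
(so group denoising has structure to find).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal, stats as sps

from .containers import (
    ChannelLayout,
    EEGRecording,
    centroparietal_gain,
    make_sphere_layout,
)
from .features import FeatureImpulseSeries
from .tokens import EmbeddingTable, WordToken

__all__ = [
    "LexiconSpec",
    "TranscriptSpec",
    "KernelSpec",
    "GroupParams",
    "FluencyLink",
    "NoiseSpec",
    "CohortSpec",
    "SimulationGroundTruth",
    "SimulatedSubject",
    "generate_embeddings",
    "generate_corpus",
    "generate_transcript",
    "kernel_waveform",
    "pink_noise",
    "simulate_subject_eeg",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LexiconSpec:
    """Category-structured random embedding lexicon (GloVe stand-in)."""

    vocab_size: int
    embed_dim: int = 300
    n_categories: int = 5
    within_category_similarity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vocab_size >= self.n_categories >= 1:
            raise ValueError("need vocab_size >= n_categories >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if not 0 < self.within_category_similarity <= 1:
            raise ValueError("within_category_similarity must be in (0, 1]")


@dataclass(frozen=True)
class TranscriptSpec:
    """Timing statistics of the simulated speech stream."""

    duration_s: float
    words_per_minute: float = 190.0
    word_dur_mean_s: float = 0.334
    word_dur_sd_s: float = 0.140
    mean_sentence_len: int = 8
    content_word_fraction: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.words_per_minute <= 0:
            raise ValueError("duration_s and words_per_minute must be > 0")
        if self.word_dur_mean_s <= 0:
            raise ValueError("word_dur_mean_s must be > 0")
        if not 0 <= self.content_word_fraction <= 1:
            raise ValueError("content_word_fraction must be in [0, 1]")


@dataclass(frozen=True)
class KernelSpec:
    """One feature's response kernel: a Gaussian trough (or peak) on the lag axis."""

    feature_name: str
    trough_latency_ms: float
    trough_width_ms: float
    amplitude: float
    topography: tuple[float, ...]
    fs: float | None = None  # grid the kernel is defined on, if fixed

    def __post_init__(self) -> None:
        if self.trough_width_ms <= 0:
            raise ValueError("trough_width_ms must be > 0")


@dataclass(frozen=True)
class GroupParams:
    latency_shift_ms: float = 0.0
    dissimilarity_gain: float = 1.0
    surprisal_gain: float = 1.0
    age_range: tuple[float, float] = (19.0, 38.0)
    dissimilarity_gain_sd: float = 0.0
    latency_jitter_ms: float = 0.0


@dataclass(frozen=True)
class FluencyLink:
    """fluency = intercept + slope * subject dissimilarity gain + noise."""

    intercept: float = 20.7
    slope: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 0.0
    pink_sd: float = 0.0
    shared_artifact_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.white_sd, self.pink_sd, self.shared_artifact_sd) < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass(frozen=True)
class BaseKernel:
    trough_latency_ms: float
    trough_width_ms: float
    amplitude: float


DEFAULT_BASE_KERNELS: dict[str, BaseKernel] = {
    "dissimilarity": BaseKernel(400.0, 60.0, -1.0),
    "surprisal": BaseKernel(400.0, 60.0, -1.0),
    "onset": BaseKernel(100.0, 40.0, 0.6),
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group synthetic cohort design."""

    n_per_group: int
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: {
            "younger": GroupParams(age_range=(19.0, 38.0)),
            "older": GroupParams(age_range=(55.0, 77.0)),
        }
    )
    fluency_link: FluencyLink = field(default_factory=FluencyLink)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_trials: int = 4
    fs: float = 128.0
    n_channels: int = 32
    kernel_support_ms: float = 800.0
    base_kernels: dict[str, BaseKernel] = field(
        default_factory=lambda: dict(DEFAULT_BASE_KERNELS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        for gname, gp in self.group_params.items():
            for kname, bk in self.base_kernels.items():
                lat = bk.trough_latency_ms + gp.latency_shift_ms
                if not 0 <= lat <= self.kernel_support_ms:
                    raise ValueError(
                        f"group {gname!r}: latency shift pushes kernel "
                        f"{kname!r} trough ({lat} ms) outside the modelled "
                        f"window [0, {self.kernel_support_ms}] ms"
                    )


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    age: float
    fluency_semantic: float
    dissimilarity_gain: float
    surprisal_gain: float
    latency_ms: dict[str, float]
    kernels: dict[str, dict]
    noise_seed: int


@dataclass
class SimulationGroundTruth:
    """Generating parameters retained for recovery tests."""

    spec_seed: int
    subjects: list[SubjectTruth]

    def by_group(self, group: str) -> list[SubjectTruth]:
        return [s for s in self.subjects if s.group == group]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec_seed": self.spec_seed,
            "subjects": [asdict(s) for s in self.subjects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationGroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            spec_seed=payload["spec_seed"],
            subjects=[SubjectTruth(**s) for s in payload["subjects"]],
        )


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    age: float
    fluency_semantic: float
    recordings: list[EEGRecording]
    kernels: list[KernelSpec]


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_embeddings(spec: LexiconSpec) -> EmbeddingTable:
    """Random embeddings with category structure.

    Word i belongs to category ``i % n_categories``; its vector is
    ``s * centroid + sqrt(1 - s^2) * noise`` with ``s`` the within-category
    similarity, so within-category cosine similarity exceeds between-category
    similarity by construction (and s -> 1 gives identical vectors).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.embed_dim
    centroids = rng.standard_normal((spec.n_categories, d)) / np.sqrt(d)
    s = spec.within_category_similarity
    words, rows = [], []
    for i in range(spec.vocab_size):
        cat = i % spec.n_categories
        eps = rng.standard_normal(d) / np.sqrt(d)
        rows.append(s * centroids[cat] + np.sqrt(max(0.0, 1 - s * s)) * eps)
        words.append(f"w{i:04d}")
    return EmbeddingTable(words, np.asarray(rows))


def generate_corpus(
    embeddings: EmbeddingTable,
    n_sentences: int,
    transition_temperature: float = 0.5,
    seed: int = 0,
    mean_sentence_len: int = 8,
    start_word: str | None = None,
) -> list[list[str]]:
    """Sample sentences from a similarity-biased word-level Markov chain.

    Transition logits are the cosine similarities between embedding vectors
    (plus a small seed-fixed tie-breaking perturbation), softmaxed at
    ``transition_temperature``; similar words therefore tend to follow each
    other, making some 5-grams recur and others never occur. At temperature 0
    the chain is deterministic (argmax) with fixed sentence length, so a fixed
    start word yields the same sentence repeated.
    """
    if n_sentences <= 0:
        raise ValueError("empty corpus: n_sentences must be >= 1")
    if len(embeddings) == 0:
        raise ValueError("empty vocabulary")
    rng = np.random.default_rng(seed)
    V = embeddings.vectors
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    cos = (V / norms) @ (V / norms).T
    np.fill_diagonal(cos, -np.inf)  # no self-loops
    tie_break = 0.01 * np.random.default_rng(seed + 1).standard_normal(cos.shape)
    logits = cos + tie_break
    words = embeddings.words
    n_words = len(words)

    deterministic = transition_temperature == 0
    sentences: list[list[str]] = []
    for _ in range(n_sentences):
        if start_word is not None:
            w = embeddings.words.index(start_word)
        else:
            w = int(rng.integers(n_words))
        length = (
            mean_sentence_len
            if deterministic
            else max(3, int(rng.poisson(mean_sentence_len)))
        )
        sent = [words[w]]
        used = {w}
        for _ in range(length - 1):
            z = logits[w].copy()
            if len(used) < n_words:  # no within-sentence repeats (no cycles)
                z[list(used)] = -np.inf
            if deterministic:
                w = int(np.argmax(z))
            else:
                z = z / transition_temperature
                p = np.exp(z - np.max(z[np.isfinite(z)]))
                p[~np.isfinite(p)] = 0.0
                p /= p.sum()
                w = int(rng.choice(n_words, p=p))
            used.add(w)
            sent.append(words[w])
        sentences.append(sent)
    return sentences


def generate_transcript(
    spec: TranscriptSpec,
    corpus: Sequence[Sequence[str]] | Callable[[int], Sequence[Sequence[str]]],
) -> list[WordToken]:
    """Time-align corpus sentences into a transcript.

    Inter-onset intervals are ``60 / wpm`` jittered uniformly by +/-20%, so
    the realized rate stays within 10% of the target; word durations are
    truncated-normal with a 50 ms floor; sentences are consumed in order
    (cycling). Content-word flags are Bernoulli draws at the configured
    fraction.
    """
    rng = np.random.default_rng(spec.seed)
    n_expected = int(np.ceil(spec.duration_s * spec.words_per_minute / 60.0)) + 10
    if callable(corpus):
        sentences = corpus(max(1, n_expected // max(1, spec.mean_sentence_len) + 2))
    else:
        sentences = list(corpus)
    if not sentences:
        raise ValueError("corpus supplied no sentences")

    floor = 0.05
    a = (floor - spec.word_dur_mean_s) / max(spec.word_dur_sd_s, 1e-12)
    mean_ioi = 60.0 / spec.words_per_minute

    tokens: list[WordToken] = []
    t = 0.0
    sentence_id = 0
    si = 0
    while t < spec.duration_s:
        sent = sentences[si % len(sentences)]
        si += 1
        for word in sent:
            if t >= spec.duration_s:
                break
            if spec.word_dur_sd_s > 0:
                dur = float(
                    sps.truncnorm.rvs(
                        a, np.inf, loc=spec.word_dur_mean_s,
                        scale=spec.word_dur_sd_s, random_state=rng,
                    )
                )
            else:
                dur = spec.word_dur_mean_s
            tokens.append(
                WordToken(
                    word=word,
                    onset_s=t,
                    offset_s=t + dur,
                    sentence_id=sentence_id,
                    is_content=bool(rng.random() < spec.content_word_fraction),
                )
            )
            t += mean_ioi * float(rng.uniform(0.8, 1.2))
        sentence_id += 1
    return tokens


def kernel_waveform(
    kernel: KernelSpec, fs: float, support_ms: float = 800.0
) -> np.ndarray:
    """Kernel sampled on the output lag grid [0, support_ms]."""
    if kernel.fs is not None and kernel.fs != fs:
        raise ValueError(
            f"kernel {kernel.feature_name!r} defined at {kernel.fs} Hz; "
            f"cannot place on a {fs} Hz grid without resampling"
        )
    if not 0 <= kernel.trough_latency_ms <= support_ms:
        raise ValueError(
            f"kernel {kernel.feature_name!r}: trough at "
            f"{kernel.trough_latency_ms} ms outside [0, {support_ms}] ms"
        )
    t_ms = np.arange(int(round(support_ms * fs / 1000.0)) + 1) * 1000.0 / fs
    return kernel.amplitude * np.exp(
        -0.5 * ((t_ms - kernel.trough_latency_ms) / kernel.trough_width_ms) ** 2
    )


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / f[1:]
    spec *= scale
    x = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_subject_eeg(
    impulses: Sequence[FeatureImpulseSeries],
    kernels: Sequence[KernelSpec],
    noise: NoiseSpec,
    fs: float,
    n_channels: int,
    seed: int = 0,
    kernel_support_ms: float = 800.0,
    shared_artifact: np.ndarray | None = None,
    channel_roles: Sequence[str] | None = None,
    subject_id: str = "",
    trial_id: int = 0,
) -> tuple[EEGRecording, np.ndarray]:
    """One trial of forward-modelled EEG.

    response = sum over features of (impulse series (*) kernel) x topography,
    plus pink noise, white noise and (optionally) a provided rank-1 shared
    artifact time course projected onto a seed-derived channel pattern.
    Returns the recording and the shared-artifact component (channels x
    samples; zeros when absent).
    """
    if len(impulses) != len(kernels):
        raise ValueError("impulses and kernels must align")
    n = impulses[0].n_samples
    rng = np.random.default_rng(seed)
    data = np.zeros((n_channels, n))
    for imp, kern in zip(impulses, kernels):
        if imp.fs != fs:
            raise ValueError(f"impulse series {imp.name!r} fs mismatch")
        topo = np.asarray(kern.topography, dtype=float)
        if topo.shape[0] != n_channels:
            raise ValueError("topography length must equal n_channels")
        wav = kernel_waveform(kern, fs, kernel_support_ms)
        if wav.size > n:
            raise ValueError("kernel support exceeds trial length")
        resp = signal.fftconvolve(imp.values, wav)[:n]
        data += topo[:, None] * resp[None, :]

    if noise.pink_sd > 0:
        data += noise.pink_sd * pink_noise(rng, (n_channels, n))
    if noise.white_sd > 0:
        data += noise.white_sd * rng.standard_normal((n_channels, n))
    shared = np.zeros((n_channels, n))
    if noise.shared_artifact_sd > 0 and shared_artifact is not None:
        if shared_artifact.shape[0] != n:
            raise ValueError("shared artifact length mismatch")
        pattern = rng.standard_normal(n_channels)
        pattern /= np.linalg.norm(pattern)
        shared = noise.shared_artifact_sd * np.outer(pattern, shared_artifact)
        data += shared

    rec = EEGRecording(
        data=data,
        fs=fs,
        channel_roles=list(channel_roles) if channel_roles else [],
        subject_id=subject_id,
        trial_id=trial_id,
    )
    return rec, shared


def _subject_kernels(
    spec: CohortSpec,
    gp: GroupParams,
    topography: np.ndarray,
    rng: np.random.Generator,
) -> tuple[list[KernelSpec], dict[str, float], float, float]:
    """Draw per-subject kernels; returns (kernels, latencies, d_gain, s_gain)."""
    jitter = (
        float(rng.normal(0.0, gp.latency_jitter_ms)) if gp.latency_jitter_ms else 0.0
    )
    d_gain = gp.dissimilarity_gain
    if gp.dissimilarity_gain_sd:
        d_gain = float(rng.normal(d_gain, gp.dissimilarity_gain_sd))
    s_gain = gp.surprisal_gain
    kernels: list[KernelSpec] = []
    latencies: dict[str, float] = {}
    for name, bk in spec.base_kernels.items():
        lat = bk.trough_latency_ms
        amp = bk.amplitude
        if name in ("dissimilarity", "surprisal"):
            lat = lat + gp.latency_shift_ms + jitter
            amp = amp * (d_gain if name == "dissimilarity" else s_gain)
        lat = float(np.clip(lat, 0.0, spec.kernel_support_ms))
        kernels.append(
            KernelSpec(
                feature_name=name,
                trough_latency_ms=lat,
                trough_width_ms=bk.trough_width_ms,
                amplitude=amp,
                topography=tuple(topography),
            )
        )
        latencies[name] = lat
    return kernels, latencies, d_gain, s_gain


def generate_cohort(
    spec: CohortSpec,
    trial_stimuli: Sequence[Sequence[FeatureImpulseSeries]],
    layout: ChannelLayout | None = None,
    channel_roles: Sequence[str] | None = None,
) -> tuple[list[SimulatedSubject], SimulationGroundTruth]:
    """Simulate a two-group cohort listening to the same stimulus.

    ``trial_stimuli[t]`` lists the impulse series of trial ``t`` in the order
    of ``spec.base_kernels`` (dissimilarity, surprisal, onset by default).
    All subjects share the stimulus; the "older" group's semantic kernels are
    the base kernels shifted and scaled per its :class:`GroupParams`, and each
    subject's fluency score follows the configured link to their individual
    dissimilarity gain.
    """
    if len(trial_stimuli) != spec.n_trials:
        raise ValueError("trial_stimuli length must equal n_trials")
    if layout is None:
        layout, roles = make_sphere_layout(spec.n_channels)
        channel_roles = channel_roles or roles
    topography = centroparietal_gain(layout)

    ss = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(ss)
    artifact_rng = np.random.default_rng(ss.spawn(1)[0])
    artifacts = [
        pink_noise(artifact_rng, (s[0].n_samples,)) for s in trial_stimuli
    ]

    subjects: list[SimulatedSubject] = []
    truths: list[SubjectTruth] = []
    sidx = 0
    for group, gp in spec.group_params.items():
        for _ in range(spec.n_per_group):
            sid = f"{group[0]}{sidx:03d}"
            noise_seed = int(master.integers(2**31 - 1))
            rng = np.random.default_rng(noise_seed)
            kernels, latencies, d_gain, s_gain = _subject_kernels(
                spec, gp, topography, rng
            )
            age = float(rng.uniform(*gp.age_range))
            fl = spec.fluency_link
            fluency = fl.intercept + fl.slope * d_gain
            if fl.noise_sd:
                fluency += float(rng.normal(0.0, fl.noise_sd))
            recs = []
            for t, stim in enumerate(trial_stimuli):
                rec, _ = simulate_subject_eeg(
                    stim,
                    kernels,
                    spec.noise,
                    spec.fs,
                    spec.n_channels,
                    seed=int(rng.integers(2**31 - 1)),
                    kernel_support_ms=spec.kernel_support_ms,
                    shared_artifact=artifacts[t],
                    channel_roles=channel_roles,
                    subject_id=sid,
                    trial_id=t,
                )
                recs.append(rec)
            subjects.append(
                SimulatedSubject(
                    subject_id=sid,
                    group=group,
                    age=age,
                    fluency_semantic=float(fluency),
                    recordings=recs,
                    kernels=kernels,
                )
            )
            truths.append(
                SubjectTruth(
                    subject_id=sid,
                    group=group,
                    age=age,
                    fluency_semantic=float(fluency),
                    dissimilarity_gain=float(d_gain),
                    surprisal_gain=float(s_gain),
                    latency_ms=latencies,
                    kernels={
                        k.feature_name: {
                            "trough_latency_ms": k.trough_latency_ms,
                            "trough_width_ms": k.trough_width_ms,
                            "amplitude": k.amplitude,
                        }
                        for k in kernels
                    },
                    noise_seed=noise_seed,
                )
            )
            sidx += 1
    return subjects, SimulationGroundTruth(spec_seed=spec.seed, subjects=truths)
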