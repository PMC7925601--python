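"""End-to-end synthetic experiments: simulate -> features -> preprocess ->
TRF -> statistics, with machine-readable reports.

The experiment mirrors the target analysis: a two-group cohort listens to one
stimulus; per subject, dissimilarity/surprisal/onset impulse regressors are
fit jointly by cross-validated lagged ridge regression; per-feature
permutation deltas and N400 trough latencies feed the gated group statistics
and the age-controlled fluency correlation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import mcca as mcca_mod
from . import preprocess as prep
from .containers import ChannelLayout, centroparietal_gain, make_sphere_layout
from .features import (
    FeatureImpulseSeries,
    ScoredFeatures,
    build_impulse_series,
    build_onset_regressor,
    normalize_match,
    score_transcript,
)
from .ngram import train_kneser_ney
from .stats import (
    SubjectMetrics,
    TestResult,
    compare,
    latency_contrast,
    partial_correlation,
)
from .synthetic import (
    CohortSpec,
    LexiconSpec,
    NoiseSpec,
    SimulationGroundTruth,
    TranscriptSpec,
    generate_cohort,
    generate_corpus,
    generate_embeddings,
    generate_transcript,
    simulate_subject_eeg,
)
from .tokens import WordToken
from .trf import (
    DEFAULT_LAMBDA_GRID,
    CVResult,
    LagWindow,
    TRFModel,
    cross_validate,
    fit_ridge,
    build_lagged_design,
    peak_latency,
    permutation_delta,
)

log = logging.getLogger("speechtrf")

__all__ = [
    "PreprocessOptions",
    "TRFOptions",
    "ExperimentConfig",
    "ExperimentReport",
    "default_config",
    "build_stimulus",
    "parietal_channel_set",
    "calibrate_white_noise",
    "analyze_subject",
    "run_experiment",
    "replicate_figure2_pattern",
    "replicate_window_robustness",
    "replicate_fluency_correlation",
]

FEATURES = ["dissimilarity", "surprisal", "onset"]
SEMANTIC_FEATURES = ["dissimilarity", "surprisal"]


@dataclass(frozen=True)
class PreprocessOptions:
    bandpass: bool = False
    band: tuple[float, float] = (0.5, 8.0)
    detect_bad: bool = False
    interpolate_bad: bool = False
    rereference: bool = False
    mcca_n_pc: int | None = None
    mcca_n_cc: int | None = None


@dataclass(frozen=True)
class TRFOptions:
    lag_min_ms: float = -200.0
    lag_max_ms: float = 800.0
    lambda_grid: tuple[float, ...] = tuple(DEFAULT_LAMBDA_GRID)
    n_perm: int = 5
    latency_window_ms: tuple[float, float] = (200.0, 600.0)


@dataclass(frozen=True)
class ExperimentConfig:
    lexicon: LexiconSpec
    transcript: TranscriptSpec
    cohort: CohortSpec
    corpus_sentences: int = 400
    corpus_temperature: float = 0.5
    corpus_seed: int = 0
    context: str | int = "sentence"
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    trf: TRFOptions = field(default_factory=TRFOptions)
    seed: int = 0

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["lexicon"] = LexiconSpec(**d["lexicon"])
        d["transcript"] = TranscriptSpec(**d["transcript"])
        cohort = dict(d["cohort"])
        from .synthetic import BaseKernel, FluencyLink, GroupParams

        cohort["group_params"] = {
            k: GroupParams(**{**v, "age_range": tuple(v["age_range"])})
            for k, v in cohort["group_params"].items()
        }
        cohort["fluency_link"] = FluencyLink(**cohort["fluency_link"])
        cohort["noise"] = NoiseSpec(**cohort["noise"])
        cohort["base_kernels"] = {
            k: BaseKernel(**v) for k, v in cohort["base_kernels"].items()
        }
        d["cohort"] = CohortSpec(**cohort)
        d["preprocess"] = PreprocessOptions(
            **{
                **d["preprocess"],
                "band": tuple(d["preprocess"]["band"]),
            }
        )
        d["trf"] = TRFOptions(
            **{
                **d["trf"],
                "lambda_grid": tuple(d["trf"]["lambda_grid"]),
                "latency_window_ms": tuple(d["trf"]["latency_window_ms"]),
            }
        )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def default_config(
    seed: int = 0,
    n_per_group: int = 8,
    n_channels: int = 32,
    n_trials: int = 4,
    trial_duration_s: float = 60.0,
    fs: float = 128.0,
    **cohort_overrides,
) -> ExperimentConfig:
    """Reduced-scale configuration (minutes on one CPU).

    A paper-scale profile is ``default_config(n_per_group=19, n_channels=128,
    trial_duration_s=180)``.
    """
    cohort_kwargs = dict(
        n_per_group=n_per_group,
        n_trials=n_trials,
        fs=fs,
        n_channels=n_channels,
        noise=NoiseSpec(white_sd=0.5, pink_sd=0.25, shared_artifact_sd=0.0),
        seed=seed,
    )
    cohort_kwargs.update(cohort_overrides)
    cohort = CohortSpec(**cohort_kwargs)
    return ExperimentConfig(
        lexicon=LexiconSpec(vocab_size=120, embed_dim=24, n_categories=6, seed=seed + 1),
        transcript=TranscriptSpec(
            duration_s=n_trials * trial_duration_s, seed=seed + 2
        ),
        cohort=cohort,
        corpus_seed=seed + 3,
        seed=seed,
    )


# --------------------------------------------------------------------------
# stimulus construction
# --------------------------------------------------------------------------

@dataclass
class StimulusBundle:
    tokens: list[WordToken]
    scored: ScoredFeatures
    trial_stimuli: list[list[FeatureImpulseSeries]]
    fs: float
    trial_len_samples: int
    layout: ChannelLayout
    channel_roles: list[str]


_STIMULUS_CACHE: dict[str, StimulusBundle] = {}


def _stimulus_key(config: ExperimentConfig) -> str:
    d = config.to_dict()
    relevant = {
        "lexicon": d["lexicon"],
        "transcript": d["transcript"],
        "corpus": [d["corpus_sentences"], d["corpus_temperature"], d["corpus_seed"]],
        "context": d["context"],
        "fs": config.cohort.fs,
        "n_trials": config.cohort.n_trials,
        "n_channels": config.cohort.n_channels,
    }
    return hashlib.sha256(json.dumps(relevant, sort_keys=True, default=str).encode()).hexdigest()


def build_stimulus(
    config: ExperimentConfig, context: str | int | None = None, cache: bool = True
) -> StimulusBundle:
    """Generate embeddings, corpus, transcript and per-trial impulse regressors.

    Surprisal is normalized to match the dissimilarity distribution over the
    whole stimulus before trials are cut. Results are cached on the stimulus-
    relevant part of the config so cohort sweeps can share one stimulus.
    """
    ctx = config.context if context is None else context
    key = _stimulus_key(replace(config, context=ctx))
    if cache and key in _STIMULUS_CACHE:
        return _STIMULUS_CACHE[key]

    embeddings = generate_embeddings(config.lexicon)
    corpus = generate_corpus(
        embeddings,
        n_sentences=config.corpus_sentences,
        transition_temperature=config.corpus_temperature,
        seed=config.corpus_seed,
    )
    model = train_kneser_ney(corpus, order=5)
    tokens = generate_transcript(config.transcript, corpus)
    scored = score_transcript(tokens, embeddings, model, context=ctx)
    norm_surprisal = normalize_match(scored.surprisal, scored.dissimilarity)

    fs = config.cohort.fs
    n_trials = config.cohort.n_trials
    trial_dur = config.transcript.duration_s / n_trials
    trial_len = int(round(trial_dur * fs))

    trial_stimuli: list[list[FeatureImpulseSeries]] = []
    for t in range(n_trials):
        t0, t1 = t * trial_dur, (t + 1) * trial_dur
        sel = np.flatnonzero((scored.onsets_s >= t0) & (scored.onsets_s < t1))
        toks = [
            dataclasses.replace(
                tokens[scored.token_indices[i]],
                onset_s=scored.onsets_s[i] - t0,
                offset_s=tokens[scored.token_indices[i]].offset_s - t0,
            )
            for i in sel
        ]
        local_idx = list(range(len(toks)))
        dis = build_impulse_series(
            toks, scored.dissimilarity[sel], fs, trial_len,
            token_indices=local_idx, name="dissimilarity",
        )
        sur = build_impulse_series(
            toks, norm_surprisal[sel], fs, trial_len,
            token_indices=local_idx, name="surprisal",
        )
        ons = build_onset_regressor(
            toks, scored.dissimilarity[sel], norm_surprisal[sel], fs, trial_len,
            token_indices=local_idx,
        )
        trial_stimuli.append([dis, sur, ons])

    layout, roles = make_sphere_layout(config.cohort.n_channels)
    bundle = StimulusBundle(
        tokens=tokens,
        scored=scored,
        trial_stimuli=trial_stimuli,
        fs=fs,
        trial_len_samples=trial_len,
        layout=layout,
        channel_roles=roles,
    )
    if cache:
        _STIMULUS_CACHE[key] = bundle
    return bundle


def parietal_channel_set(layout: ChannelLayout) -> list[int]:
    """Channels in the top quartile of the centro-parietal gain profile."""
    gain = centroparietal_gain(layout)
    thresh = np.quantile(gain, 0.75)
    return [int(i) for i in np.flatnonzero(gain >= thresh)]


def calibrate_white_noise(
    config: ExperimentConfig, target_snr: float, stimulus: StimulusBundle | None = None
) -> ExperimentConfig:
    """Set white noise so var(signal)/var(noise) over parietal channels = SNR."""
    stim = stimulus or build_stimulus(config)
    spec = config.cohort
    clean_spec = replace(spec, noise=NoiseSpec())
    from .synthetic import KernelSpec

    topo = centroparietal_gain(stim.layout)
    kernels = [
        KernelSpec(name, bk.trough_latency_ms, bk.trough_width_ms, bk.amplitude,
                   tuple(topo))
        for name, bk in spec.base_kernels.items()
    ]
    rec, _ = simulate_subject_eeg(
        stim.trial_stimuli[0], kernels, NoiseSpec(), spec.fs, spec.n_channels,
        seed=0, kernel_support_ms=spec.kernel_support_ms,
    )
    par = parietal_channel_set(stim.layout)
    sig_var = float(rec.data[par].var(axis=1).mean())
    white_sd = float(np.sqrt(sig_var / target_snr))
    return replace(config, cohort=replace(spec, noise=NoiseSpec(white_sd=white_sd)))


# --------------------------------------------------------------------------
# per-subject analysis
# --------------------------------------------------------------------------

def _preprocess_subject(
    recs: list, opts: PreprocessOptions, layout: ChannelLayout
) -> list:
    out = []
    for rec in recs:
        if opts.bandpass:
            rec = prep.bandpass(rec, *opts.band)
        if opts.detect_bad:
            mask = prep.detect_bad_channels(rec)
            if opts.interpolate_bad and mask.any():
                rec.bad_mask = mask
                rec = prep.interpolate_channels(rec, layout, mask)
        if opts.rereference:
            rec = prep.rereference(rec)
        out.append(rec)
    return out


@dataclass
class SubjectAnalysis:
    cv: CVResult
    final_model: TRFModel
    deltas: dict[str, np.ndarray]           # per channel
    latencies: dict[str, float]
    parietal: list[int]

    def metric_delta(self, feature: str) -> float:
        return float(np.mean(self.deltas[feature][self.parietal]))


def analyze_subject(
    trial_stimuli: Sequence[Sequence[FeatureImpulseSeries]],
    recordings: Sequence,
    options: TRFOptions,
    parietal: Sequence[int],
    seed: int = 0,
) -> SubjectAnalysis:
    """CV ridge fit, permutation deltas and trough latencies for one subject."""
    fs = trial_stimuli[0][0].fs
    lag_window = LagWindow(options.lag_min_ms, options.lag_max_ms, fs)
    responses = [r.data if hasattr(r, "data") else np.asarray(r) for r in recordings]
    cv = cross_validate(
        trial_stimuli, responses, lag_window,
        lambda_grid=np.asarray(options.lambda_grid), feature_names=FEATURES,
    )
    deltas = {
        feat: permutation_delta(
            cv, trial_stimuli, responses, feat,
            n_perm=options.n_perm, seed=seed,
        ).delta
        for feat in SEMANTIC_FEATURES
    }
    # final model on all trials at the selected lambda, for weight inspection
    X = np.vstack([build_lagged_design(s, lag_window) for s in trial_stimuli])
    Y = np.vstack([r.T for r in responses])
    final = fit_ridge(X, Y, cv.selected_lambda, lag_window, FEATURES)
    latencies = {
        feat: peak_latency(
            final, parietal, feat, window_ms=options.latency_window_ms
        ).latency_ms
        for feat in SEMANTIC_FEATURES
    }
    return SubjectAnalysis(
        cv=cv, final_model=final, deltas=deltas,
        latencies=latencies, parietal=list(parietal),
    )


# --------------------------------------------------------------------------
# experiment
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    config_hash: str
    subjects: list[SubjectMetrics]
    contrasts: dict[str, TestResult]
    latency_delay_ms: float
    ground_truth: SimulationGroundTruth
    software_version: str = ""

    def group(self, name: str) -> list[SubjectMetrics]:
        return [m for m in self.subjects if m.group == name]

    def delta_array(self, group: str, feature: str) -> np.ndarray:
        return np.array([m.delta_r[feature] for m in self.group(group)])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "software_version": self.software_version,
            "latency_delay_ms": self.latency_delay_ms,
            "subjects": [dataclasses.asdict(m) for m in self.subjects],
            "contrasts": {
                k: dataclasses.asdict(v) for k, v in self.contrasts.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _figure2_contrasts(report_subjects: list[SubjectMetrics]) -> dict[str, TestResult]:
    def deltas(group: str, feature: str) -> np.ndarray:
        return np.array(
            [m.delta_r[feature] for m in report_subjects if m.group == group]
        )

    return {
        "older_within": compare(
            deltas("older", "surprisal"), deltas("older", "dissimilarity"),
            paired=True,
        ),
        "younger_within": compare(
            deltas("younger", "surprisal"), deltas("younger", "dissimilarity"),
            paired=True,
        ),
        "between_dissimilarity": compare(
            deltas("younger", "dissimilarity"), deltas("older", "dissimilarity")
        ),
        "between_surprisal": compare(
            deltas("younger", "surprisal"), deltas("older", "surprisal")
        ),
    }


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentReport:
    """Execute the full synthetic experiment and collect the report."""
    from . import __version__

    log.info("stage: stimulus")
    stim = build_stimulus(config)
    log.info("stage: cohort simulation (%d scored words)", len(stim.scored))
    subjects, truth = generate_cohort(
        config.cohort, stim.trial_stimuli, layout=stim.layout,
        channel_roles=stim.channel_roles,
    )
    parietal = parietal_channel_set(stim.layout)

    mcca_models = {}
    if config.preprocess.mcca_n_pc:
        for group in config.cohort.group_params:
            grp = [s for s in subjects if s.group == group]
            mcca_models[group] = mcca_mod.mcca_fit(
                {s.subject_id: s.recordings for s in grp},
                n_pc=config.preprocess.mcca_n_pc,
                n_cc=config.preprocess.mcca_n_cc or 110,
            )

    metrics: list[SubjectMetrics] = []
    for subj in subjects:
        recs = _preprocess_subject(subj.recordings, config.preprocess, stim.layout)
        if subj.group in mcca_models:
            model = mcca_models[subj.group]
            recs = [
                mcca_mod.mcca_denoise(r, model, subject_id=subj.subject_id)
                for r in recs
            ]
        sid_key = zlib.crc32(subj.subject_id.encode()) % 10007
        ana = analyze_subject(
            stim.trial_stimuli, recs, config.trf, parietal,
            seed=config.seed * 10007 + sid_key,
        )
        metrics.append(
            SubjectMetrics(
                subject_id=subj.subject_id,
                group=subj.group,  # type: ignore[arg-type]
                age=subj.age,
                delta_r={f: ana.metric_delta(f) for f in SEMANTIC_FEATURES},
                peak_latency_ms=dict(ana.latencies),
                fluency_semantic=subj.fluency_semantic,
            )
        )
        log.info("subject %s analysed (lambda=%g)", subj.subject_id, ana.cv.selected_lambda)

    contrasts = _figure2_contrasts(metrics)
    lat_test, delay = latency_contrast(metrics, feature="surprisal")
    contrasts["latency"] = lat_test

    report = ExperimentReport(
        config_hash=config.config_hash,
        subjects=metrics,
        contrasts=contrasts,
        latency_delay_ms=delay,
        ground_truth=truth,
        software_version=__version__,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        report.to_json(out / "report.json")
        truth.to_json(out / "ground_truth.json")
        stim.scored.to_tsv(out / "features.tsv")
        from .tokens import write_transcript_tsv

        write_transcript_tsv(stim.tokens, out / "transcript.tsv")
    return report


def replicate_figure2_pattern(config: ExperimentConfig) -> dict[str, TestResult]:
    """The four within/between-group accuracy contrasts."""
    if config.cohort.n_per_group < 2:
        raise ValueError("groups need >= 2 subjects for the contrasts")
    report = run_experiment(config)
    return {k: v for k, v in report.contrasts.items() if k != "latency"}


def replicate_window_robustness(
    config: ExperimentConfig,
    modes: Sequence[str | int] = ("sentence", 3, 5, 7, 9, 11),
) -> dict:
    """Per-context-mode dissimilarity deltas + per-group Kruskal--Wallis."""
    base_stim = build_stimulus(config)
    subjects, _ = generate_cohort(
        config.cohort, base_stim.trial_stimuli, layout=base_stim.layout,
        channel_roles=base_stim.channel_roles,
    )
    parietal = parietal_channel_set(base_stim.layout)

    per_mode: dict[str | int, dict[str, float]] = {}
    for mode in modes:
        stim = build_stimulus(config, context=mode)
        per_subj = {}
        for subj in subjects:
            ana = analyze_subject(
                stim.trial_stimuli, subj.recordings, config.trf, parietal,
                seed=config.seed,
            )
            per_subj[subj.subject_id] = ana.metric_delta("dissimilarity")
        per_mode[mode] = per_subj

    from scipy import stats as sps

    omnibus = {}
    for group in config.cohort.group_params:
        ids = [s.subject_id for s in subjects if s.group == group]
        samples = [[per_mode[m][i] for i in ids] for m in modes]
        stat, p = sps.kruskal(*samples)
        omnibus[group] = TestResult(
            "kruskal-wallis", float(stat), float(p),
            n=sum(len(s) for s in samples), gating_path="nonparametric",
        )
    return {"per_mode": per_mode, "omnibus": omnibus}


def replicate_fluency_correlation(
    config: ExperimentConfig, group: str = "older"
) -> tuple[float, float]:
    """Age-controlled correlation of dissimilarity delta with semantic fluency."""
    report = run_experiment(config)
    members = report.group(group)
    if any(m.fluency_semantic is None for m in members):
        raise ValueError("fluency covariate missing")
    x = [m.delta_r["dissimilarity"] for m in members]
    y = [m.fluency_semantic for m in members]
    age = [m.age for m in members]
    return partial_correlation(x, y, age)
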