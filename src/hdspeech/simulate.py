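"""Synthetic inputs for end-to-end testing without clinical recordings.

Three generators:

* :func:`generate_cohort` draws visit-level feature tables whose
  per-group means and SDs reproduce the published cohort summaries
  (18 HD / 7 prodromal / 11 control participants).  Bounded features
  are drawn from *moment-matched* truncated normals: the underlying
  parameters are solved numerically so the post-truncation mean and SD
  equal the targets.  A per-subject latent severity factor links
  features to clinical scores through a Gaussian copula.
* :func:`synthesize_recording` renders a harmonic pulse train with a
  known F0 inside known word spans, so the acoustic and timing
  extractors can be checked against planted ground truth.
* :func:`corrupt_transcript` emulates a lower-capacity recognizer's
  error channel (letter substitutions, deletions, duplications) at a
  controllable rate.

Features are drawn independently given the latent factor (no empirical
cross-feature covariance is available), so synthetic classification
metrics calibrate the pipeline rather than reproduce clinical results.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .io import AudioSignal, TimedTranscript, VisitRecord, WordToken
from .counting import TASKS, number_to_words

__all__ = [
    "CohortSpec",
    "RecordingProfile",
    "SyntheticRecording",
    "default_cohort_spec",
    "load_cohort_spec",
    "generate_cohort",
    "synthesize_recording",
    "corrupt_transcript",
    "counting_profile",
    "PASSAGE_GROUP_PARAMS",
]

# ---------------------------------------------------------------------------
# Default cohort structure: published per-group summaries
#
# feature -> {group: (mean, sd)}; passage-reading features unprefixed,
# counting features prefixed with the task.  Prodromal values for the
# counting tasks are not published except for pitch; they are set midway
# between the HD and control values, consistent with the observation
# that the prodromal group sits between the two.

PASSAGE_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "speech_to_pause_ratio": {"HD": (0.92, 0.51), "pHD": (1.84, 0.64), "CTR": (1.91, 0.46)},
    "similarity_dtw": {"HD": (0.37, 0.24), "pHD": (0.74, 0.19), "CTR": (0.92, 0.14)},
    "articulatory_rate_w_s": {"HD": (1.73, 0.75), "pHD": (2.72, 0.44), "CTR": (3.16, 0.31)},
    "total_pause_time_s": {"HD": (15.91, 6.94), "pHD": (7.01, 2.43), "CTR": (6.01, 1.63)},
    "total_signal_time_s": {"HD": (27.53, 7.00), "pHD": (18.60, 2.43), "CTR": (16.90, 2.19)},
    "intelligibility_dtw": {"HD": (0.32, 0.19), "pHD": (0.59, 0.27), "CTR": (0.72, 0.19)},
    "mean_pause_length_s": {"HD": (0.60, 0.32), "pHD": (0.27, 0.04), "CTR": (0.26, 0.03)},
    "ratio_extra_words": {"HD": (0.13, 0.10), "pHD": (0.03, 0.02), "CTR": (0.01, 0.02)},
    "ratio_missing_words": {"HD": (0.20, 0.18), "pHD": (0.04, 0.03), "CTR": (0.01, 0.03)},
    "pitch_sd_hz": {"HD": (26.42, 9.06), "pHD": (36.32, 12.1), "CTR": (22.0, 12.1)},
    "loudness_sone": {"HD": (79.44, 7.6), "pHD": (86.78, 14.7), "CTR": (86.7, 10.2)},
    "number_of_pauses": {"HD": (28.39, 9.11), "pHD": (26.0, 6.24), "CTR": (22.5, 3.91)},
    "pitch_mean_hz": {"HD": (157.84, 33.82), "pHD": (166.63, 24.3), "CTR": (136.0, 30.2)},
    "total_voiced_time_s": {"HD": (11.62, 3.72), "pHD": (11.6, 1.41), "CTR": (10.9, 1.07)},
}

COUNTING_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "counting_forward__counts_per_second": {"HD": (1.69, 0.50), "pHD": (2.06, 0.47), "CTR": (2.42, 0.44)},
    "counting_forward__total_pause_time_s": {"HD": (15.0, 7.95), "pHD": (11.9, 5.6), "CTR": (8.86, 3.19)},
    "counting_forward__total_signal_time_s": {"HD": (23.47, 7.54), "pHD": (20.5, 5.9), "CTR": (17.5, 4.3)},
    "counting_forward__mean_pause_length_s": {"HD": (0.44, 0.31), "pHD": (0.33, 0.19), "CTR": (0.22, 0.06)},
    "counting_forward__speech_to_pause_ratio": {"HD": (0.72, 0.42), "pHD": (0.89, 0.36), "CTR": (1.05, 0.29)},
    "counting_forward__pitch_mean_hz": {"HD": (170.0, 35.0), "pHD": (180.03, 29.4), "CTR": (146.0, 26.0)},
    "counting_backward__correct_counts": {"HD": (4.53, 2.42), "pHD": (5.5, 1.5), "CTR": (6.55, 0.52)},
    "counting_backward__correct_counts_ratio": {"HD": (0.69, 0.30), "pHD": (0.80, 0.22), "CTR": (0.91, 0.14)},
    "counting_backward__pitch_mean_hz": {"HD": (185.0, 45.0), "pHD": (213.44, 47.7), "CTR": (157.0, 33.6)},
}

#: clinical score -> {group: (mean, sd)} (published participant table)
CLINICAL_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "moca": {"HD": (23.0, 2.8), "pHD": (27.3, 3.0), "CTR": (27.9, 1.1)},
    "uhdrs_functional": {"HD": (19.8, 3.1), "pHD": (23.6, 1.1), "CTR": (23.6, 1.2)},
    "uhdrs_motor": {"HD": (41.1, 16.6), "pHD": (1.7, 2.6), "CTR": (0.7, 1.4)},
}

#: HD dysarthria split: P(score 0), P(score 1), P(score 2) — 1/12/5 of 18,
#: matching the published severity strata (mean 1.22).
HD_DYSARTHRIA_PROBS = (1 / 18, 12 / 18, 5 / 18)

#: clinical score direction of worsening with severity (+1 = increases)
_SCORE_DIRECTION = {"moca": -1.0, "uhdrs_functional": -1.0, "uhdrs_motor": 1.0}
_SCORE_CLIP = {"moca": (0.0, 30.0), "uhdrs_functional": (0.0, 25.0),
               "uhdrs_motor": (0.0, 124.0)}


@dataclass
class CohortSpec:
    """Cohort structure: group sizes, feature summaries, linkage strengths.

    ``feature_params`` maps feature name -> group -> (mean, sd); all
    features are lower-bounded at 0.  ``rho`` is the within-group
    correlation loading of each feature on the per-subject latent
    severity factor; ``alpha`` the loading of clinical scores.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HD": 18, "pHD": 7, "CTR": 11}
    )
    visits_per_subject: int = 1
    feature_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {**PASSAGE_GROUP_PARAMS, **COUNTING_GROUP_PARAMS}
    )
    clinical_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLINICAL_GROUP_PARAMS.items()}
    )
    rho: float = 0.5
    alpha: float = 0.8

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs n >= 2, got {n}")
        for feat, per_group in self.feature_params.items():
            for g, (m, s) in per_group.items():
                if s < 0:
                    raise ValueError(f"negative SD for {feat}/{g}")
        if not 0 <= self.rho < 1 or not 0 <= self.alpha < 1:
            raise ValueError("rho and alpha must lie in [0, 1)")


def default_cohort_spec() -> CohortSpec:
    return CohortSpec()


# ---------------------------------------------------------------------------
# Moment-matched lower-truncated normal sampling


@lru_cache(maxsize=4096)
def _solve_truncnorm(mean: float, sd: float, lo: float) -> tuple[float, float]:
    """Underlying (mu, sigma) so the [lo, inf) truncated normal has the
    requested mean and SD.

    A lower-truncated normal is log-concave, so its SD cannot exceed its
    mean distance from the bound; requested SDs beyond 95% of that limit
    are capped (relevant only for near-zero features such as the control
    group's extra-word ratio).
    """
    if sd == 0:
        return mean, 0.0
    excess = mean - lo
    if excess <= 0:
        raise ValueError(f"target mean {mean} must exceed lower bound {lo}")
    if excess / sd >= 4.0:  # truncation negligible
        return mean, sd
    sd_eff = min(sd, 0.95 * excess)

    def residuals(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a = (lo - mu) / sigma
        m, v = sps.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd_eff])

    sol = optimize.least_squares(
        residuals, x0=np.array([mean, np.log(sd_eff)]), xtol=1e-12, ftol=1e-12
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return float(mu), sigma


def _sample_feature(
    e: np.ndarray, mean: float, sd: float, lo: float = 0.0
) -> np.ndarray:
    """Map standard-normal variates to the moment-matched distribution."""
    mu, sigma = _solve_truncnorm(round(mean, 10), round(sd, 10), lo)
    if sigma == 0:
        return np.full_like(e, mu)
    if (mean - lo) / sd >= 4.0:
        return mu + sigma * e
    a = (lo - mu) / sigma
    u = sps.norm.cdf(e)
    return sps.truncnorm.ppf(u, a, np.inf, loc=mu, scale=sigma)


# ---------------------------------------------------------------------------
# Cohort generation


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0) -> list[VisitRecord]:
    """Draw a synthetic cohort of visit records.

    Each subject carries a latent severity factor z ~ N(0,1); features
    load on z with weight ``rho`` (signed by each feature's direction of
    worsening, inferred from the HD-vs-control means) and clinical
    scores with weight ``alpha``, producing the published pattern of
    high motor/dysarthria and low MoCA scores in the HD group.
    Deterministic under ``seed``.
    """
    spec = spec or default_cohort_spec()
    spec.validate()
    rng = np.random.default_rng(seed)
    rho, alpha = spec.rho, spec.alpha

    directions: dict[str, float] = {}
    for feat, per_group in spec.feature_params.items():
        if "HD" in per_group and "CTR" in per_group:
            directions[feat] = 1.0 if per_group["HD"][0] >= per_group["CTR"][0] else -1.0
        else:
            directions[feat] = 1.0

    q0 = sps.norm.ppf(HD_DYSARTHRIA_PROBS[0])
    q1 = sps.norm.ppf(HD_DYSARTHRIA_PROBS[0] + HD_DYSARTHRIA_PROBS[1])

    visits: list[VisitRecord] = []
    n_vis = spec.visits_per_subject
    for group, n_subj in spec.group_sizes.items():
        z = rng.standard_normal(n_subj)
        z_rep = np.repeat(z, n_vis)  # one latent factor per subject
        n_rows = n_subj * n_vis

        feature_vals: dict[str, np.ndarray] = {}
        for feat, per_group in spec.feature_params.items():
            if group not in per_group:
                continue
            m, s = per_group[group]
            e = rho * directions[feat] * z_rep + np.sqrt(1 - rho**2) * rng.standard_normal(n_rows)
            feature_vals[feat] = _sample_feature(e, m, s, lo=0.0)

        clinical_vals: dict[str, np.ndarray] = {}
        for score, per_group in spec.clinical_params.items():
            m, s = per_group[group]
            e = (
                alpha * _SCORE_DIRECTION.get(score, 1.0) * z_rep
                + np.sqrt(1 - alpha**2) * rng.standard_normal(n_rows)
            )
            low, high = _SCORE_CLIP.get(score, (-np.inf, np.inf))
            clinical_vals[score] = np.clip(m + s * e, low, high)

        for s_idx in range(n_subj):
            subject_id = f"{group}{s_idx:03d}"
            if group == "HD":
                dysarthria = 0 if z[s_idx] < q0 else (1 if z[s_idx] < q1 else 2)
            else:
                dysarthria = 0
            for v_idx in range(n_vis):
                row = s_idx * n_vis + v_idx
                visits.append(
                    VisitRecord(
                        subject_id=subject_id,
                        visit_id=f"{subject_id}_v{v_idx}",
                        group=group,
                        moca=float(clinical_vals["moca"][row]),
                        uhdrs_functional=float(clinical_vals["uhdrs_functional"][row]),
                        uhdrs_motor=float(clinical_vals["uhdrs_motor"][row]),
                        dysarthria=dysarthria,
                        features={f: float(v[row]) for f, v in feature_vals.items()},
                    )
                )
    return visits


# ---------------------------------------------------------------------------
# Recording synthesis


@dataclass(frozen=True)
class RecordingProfile:
    """Ground-truth plan for one synthetic recording."""

    words: tuple[tuple[str, float, float], ...]  # (text, start, end) seconds
    f0_hz: float = 150.0
    gain: float = 0.3
    noise_rms: float = 0.0
    rate: int = 16000
    task: str = "passage"


@dataclass(frozen=True)
class SyntheticRecording:
    audio: AudioSignal
    truth: TimedTranscript
    true_f0: float
    task: str


def synthesize_recording(profile: RecordingProfile, seed: int = 0) -> SyntheticRecording:
    """Render harmonic speech-like audio with known voiced/pause structure.

    Word spans carry a harmonic pulse train at the profile F0 (10 ms
    onset/offset ramps); gaps are silence apart from an optional noise
    floor.  The attached transcript is the exact ground truth.
    """
    spans = sorted((s, e) for _, s, e in profile.words)
    for (s1, e1), (s2, e2) in zip(spans[:-1], spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping word spans: ({s1}, {e1}) and ({s2}, {e2})")
    rate = profile.rate
    duration = max(e for _, _, e in profile.words) + 0.05 if profile.words else 0.1
    n = int(np.ceil(duration * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    if profile.gain > 0:
        n_harm = max(1, min(10, int(0.45 * rate / profile.f0_hz)))
        tone = np.zeros(n)
        for k in range(1, n_harm + 1):
            tone += np.sin(2 * np.pi * k * profile.f0_hz * t) / k
        tone *= profile.gain / np.max(np.abs(tone))
        ramp_n = int(0.010 * rate)
        for _, s, e in profile.words:
            i0, i1 = int(round(s * rate)), min(int(round(e * rate)), n)
            if i1 <= i0:
                continue
            env = np.ones(i1 - i0)
            r = min(ramp_n, (i1 - i0) // 2)
            if r > 0:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
                env[:r] = ramp
                env[-r:] = ramp[::-1]
            x[i0:i1] += tone[i0:i1] * env
    if profile.noise_rms > 0:
        rng = np.random.default_rng(seed)
        x += rng.normal(0.0, profile.noise_rms, size=n)
    truth = TimedTranscript(
        tuple(WordToken(w.lower(), s, e) for w, s, e in profile.words),
        source_tag="truth",
    )
    return SyntheticRecording(
        audio=AudioSignal(x, rate), truth=truth, true_f0=profile.f0_hz,
        task=profile.task,
    )


def counting_profile(
    task: str,
    f0_hz: float = 150.0,
    word_s: float = 0.35,
    gap_s: float = 0.5,
    compound_gap_s: float = 0.05,
) -> RecordingProfile:
    """Ground-truth profile for a canonical (error-free) counting task."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    start, step = TASKS[task]
    stop = 20 if task == "forward_1_20" else 32
    values = list(range(start, stop + np.sign(step), step))
    words: list[tuple[str, float, float]] = []
    t = 0.0
    for v in values:
        parts = number_to_words(v).split()
        for k, p in enumerate(parts):
            if k > 0:
                t += compound_gap_s
            words.append((p, t, t + word_s))
            t += word_s
        t += gap_s
    return RecordingProfile(words=tuple(words), f0_hz=f0_hz, task=task)


# ---------------------------------------------------------------------------
# ASR error channel


def _perturb_word(word: str, rng: np.random.Generator) -> str:
    """Replace one random letter with a different random letter."""
    letters = string.ascii_lowercase
    if not word:
        return rng.choice(list(letters))
    i = int(rng.integers(len(word)))
    repl = letters[int(rng.integers(26))]
    while repl == word[i]:
        repl = letters[int(rng.integers(26))]
    return word[:i] + repl + word[i + 1 :]


def corrupt_transcript(
    truth: TimedTranscript, error_rate: float, seed: int = 0
) -> TimedTranscript:
    """Emulate a lower-capacity recognizer re-transcribing the speech.

    Each word is independently corrupted with probability ``error_rate``:
    a letter substitution (p=1/2), a deletion (p=1/4), or a duplication
    into two perturbed copies sharing the original span (p=1/4).  The
    result is tagged ``"small"``.  At rate 1 no word survives unchanged.
    """
    if not 0 <= error_rate <= 1:
        raise ValueError(f"error_rate must lie in [0, 1], got {error_rate}")
    rng = np.random.default_rng(seed)
    out: list[WordToken] = []
    for w in truth.words:
        if rng.random() >= error_rate:
            out.append(w)
            continue
        op = rng.random()
        if op < 0.5:  # substitute
            out.append(WordToken(_perturb_word(w.text, rng), w.start, w.end))
        elif op < 0.75:  # delete
            continue
        else:  # duplicate: two perturbed copies split the span
            mid = (w.start + w.end) / 2
            out.append(WordToken(_perturb_word(w.text, rng), w.start, mid))
            out.append(WordToken(_perturb_word(w.text, rng), mid, w.end))
    return TimedTranscript(tuple(out), source_tag="small")


def load_cohort_spec(path) -> CohortSpec:
    """Read a CohortSpec from a YAML file.

    Recognized keys (all optional; omitted ones keep the defaults that
    encode the published cohort): ``group_sizes``, ``visits_per_subject``,
    ``feature_params`` (feature -> group -> [mean, sd]),
    ``clinical_params``, ``rho``, ``alpha``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = CohortSpec()
    if "group_sizes" in raw:
        spec.group_sizes = {str(g): int(n) for g, n in raw["group_sizes"].items()}
    if "visits_per_subject" in raw:
        spec.visits_per_subject = int(raw["visits_per_subject"])
    for key in ("feature_params", "clinical_params"):
        if key in raw:
            setattr(
                spec, key,
                {
                    str(f): {str(g): (float(m), float(s)) for g, (m, s) in per.items()}
                    for f, per in raw[key].items()
                },
            )
    if "rho" in raw:
        spec.rho = float(raw["rho"])
    if "alpha" in raw:
        spec.alpha = float(raw["alpha"])
    spec.validate()
    return spec
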