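"""Synthetic dysarthric-speech corpus generation.

Real dysarthric corpora (clinical recordings of ~15 speech types — 14
dysarthric archetypes plus normal speech) cannot be redistributed, so
this module generates stand-in corpora with the same *statistical*
shape: cluster-structured per-frame feature vectors around well
separated type centroids, per-type phoneme-label distributions, an
80/10/10 train/test/validation split, and an optional waveform path
that emulates dysarthric degradation (jitter, shimmer, breath noise)
on a harmonic source.

Everything here is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

RATE_HZ = 16_000

# 14 dysarthric archetype names (6 classic types + qualitative variants)
# + "normal"; purely cosmetic labels for the generated speech types.
_ARCHETYPE_NAMES = [
    "flaccid", "spastic", "ataxic", "hyperkinetic", "hypokinetic", "mixed",
    "flaccid-breathy", "spastic-strained", "ataxic-irregular",
    "hyperkinetic-erratic", "hypokinetic-monotone", "mixed-severe",
    "flaccid-weak", "spastic-slow",
]

__all__ = [
    "SpeechTypeSpec",
    "CorpusConfig",
    "SyntheticUtterance",
    "SeparationError",
    "generate_feature_corpus",
    "synth_waveform",
    "attach_waveforms",
    "split_corpus",
    "largest_remainder_sizes",
    "write_corpus",
]


class SeparationError(RuntimeError):
    """Raised when separated centroids cannot be drawn in the given dimension."""


@dataclass
class SpeechTypeSpec:
    """One synthetic speech type (a dysarthric archetype or normal speech)."""

    type_id: int
    name: str
    is_normal: bool
    centroid: np.ndarray
    spread: float
    f0_hz: float
    jitter: float
    shimmer: float
    breath_noise: float

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=np.float64)
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        for nm in ("jitter", "shimmer", "breath_noise"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1], got {v}")
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")


@dataclass
class CorpusConfig:
    n_types: int = 15
    frames_per_utterance: tuple[int, int] = (40, 120)
    utterances_per_type: int = 10
    n_phonemes: int = 10
    feature_dim: int | None = None  # defaults to 39 + n_phonemes
    spread: float = 1.0
    min_separation: float = 6.0
    split_fractions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least two speech types (normal + dysarthric)")
        if self.feature_dim is None:
            self.feature_dim = 39 + self.n_phonemes
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        fr = np.asarray(self.split_fractions, dtype=np.float64)
        if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("split fractions must be nonnegative and sum to 1")
        lo, hi = self.frames_per_utterance
        if not 1 <= lo <= hi:
            raise ValueError("frames_per_utterance must be a valid (lo, hi) range")


@dataclass
class SyntheticUtterance:
    utterance_id: str
    type_id: int
    frames: np.ndarray
    phoneme_labels: list[str]
    split: str = "train"
    waveform: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x d matrix with T >= 1")
        if len(self.phoneme_labels) != self.frames.shape[0]:
            raise ValueError("phoneme label sequence length must equal frame count")


def _draw_centroids(
    rng: np.random.Generator,
    n: int,
    dim: int,
    min_dist: float,
    max_attempts: int = 100,
) -> np.ndarray:
    """Draw ``n`` centroids with all pairwise distances >= ``min_dist``."""
    from scipy.spatial.distance import pdist

    scale = min_dist  # typical pairwise distance ~ min_dist * sqrt(2 * dim)
    for attempt in range(1, max_attempts + 1):
        pts = rng.normal(0.0, scale, size=(n, dim))
        if n == 1 or pdist(pts).min() >= min_dist:
            return pts
    raise SeparationError(
        f"could not place {n} centroids at pairwise distance >= {min_dist:g} "
        f"in {dim} dimensions after {max_attempts} attempts"
    )


def generate_feature_corpus(
    config: CorpusConfig,
) -> tuple[list[SyntheticUtterance], list[SpeechTypeSpec]]:
    """Generate a cluster-structured feature-level corpus.

    Frames of each speech type are isotropic Gaussian around the type
    centroid; pairwise centroid distances are at least
    ``min_separation * spread``.  The last type is the normal-speech
    type.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    d = int(config.feature_dim)
    centroids = _draw_centroids(
        rng, config.n_types, d, config.min_separation * config.spread
    )
    specs: list[SpeechTypeSpec] = []
    for j in range(config.n_types):
        is_normal = j == config.n_types - 1
        name = (
            "normal"
            if is_normal
            else _ARCHETYPE_NAMES[j % len(_ARCHETYPE_NAMES)]
            + ("" if j < len(_ARCHETYPE_NAMES) else f"-{j // len(_ARCHETYPE_NAMES)}")
        )
        specs.append(
            SpeechTypeSpec(
                type_id=j,
                name=name,
                is_normal=is_normal,
                centroid=centroids[j],
                spread=config.spread,
                f0_hz=float(rng.uniform(90.0, 220.0)),
                jitter=0.0 if is_normal else float(rng.uniform(0.2, 0.8)),
                shimmer=0.0 if is_normal else float(rng.uniform(0.2, 0.8)),
                breath_noise=0.0 if is_normal else float(rng.uniform(0.2, 0.8)),
            )
        )

    phoneme_vocab = [f"p{i:02d}" for i in range(config.n_phonemes)]
    utterances: list[SyntheticUtterance] = []
    lo, hi = config.frames_per_utterance
    for spec in specs:
        # each type prefers its own subset of phonemes
        probs = rng.dirichlet(np.ones(config.n_phonemes))
        for u in range(config.utterances_per_type):
            t = int(rng.integers(lo, hi + 1))
            frames = spec.centroid + config.spread * rng.standard_normal((t, d))
            labels = [phoneme_vocab[i] for i in rng.choice(config.n_phonemes, t, p=probs)]
            utterances.append(
                SyntheticUtterance(
                    utterance_id=f"type{spec.type_id:02d}_utt{u:03d}",
                    type_id=spec.type_id,
                    frames=frames,
                    phoneme_labels=labels,
                )
            )

    split_seed = int(rng.integers(0, 2**31 - 1))
    for utt, split in zip(utterances, split_corpus(utterances, config.split_fractions, split_seed)):
        utt.split = split
    return utterances, specs


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Integer group sizes summing exactly to ``n`` (largest-remainder rounding)."""
    fr = np.asarray(fractions, dtype=np.float64)
    raw = fr * n
    sizes = np.floor(raw).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for k in range(remainder):
        sizes[order[k]] += 1
    return sizes.tolist()


def split_corpus(utterances, fractions, seed: int) -> list[str]:
    """Random train/test/validation assignment at the utterance level.

    Returns one of ``{"train", "test", "validation"}`` per utterance, in
    input order; sizes follow largest-remainder rounding of the
    fractions, so they sum exactly to the corpus size.
    """
    n = len(utterances)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    fr = np.asarray(fractions, dtype=np.float64)
    if fr.size != 3 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must be nonnegative and sum to 1")
    sizes = largest_remainder_sizes(n, fr)
    perm = np.random.default_rng(seed).permutation(n)
    out = [""] * n
    start = 0
    for name, size in zip(("train", "test", "validation"), sizes):
        for i in perm[start : start + size]:
            out[i] = name
        start += size
    return out


def synth_waveform(spec: SpeechTypeSpec, duration_s: float, seed: int) -> np.ndarray:
    """Render a 16 kHz harmonic voice signal with dysarthric degradations.

    A 6-partial harmonic series at ``spec.f0_hz`` with cycle-level
    frequency perturbation scaled by ``jitter``, cycle-level amplitude
    perturbation scaled by ``shimmer``, and additive broadband noise
    scaled by ``breath_noise``.  Peak amplitude <= 1; deterministic
    given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if spec.f0_hz >= RATE_HZ / 2:
        raise ValueError(f"f0 {spec.f0_hz:g} Hz is at or above Nyquist ({RATE_HZ // 2} Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * RATE_HZ))

    # per-cycle instantaneous frequency / amplitude, held over each glottal cycle
    freq = np.empty(n)
    amp = np.empty(n)
    pos = 0
    while pos < n:
        f_c = spec.f0_hz * (1.0 + 0.03 * spec.jitter * rng.standard_normal())
        f_c = max(f_c, 1.0)
        a_c = max(0.0, 1.0 + 0.2 * spec.shimmer * rng.standard_normal())
        period = max(1, int(round(RATE_HZ / f_c)))
        end = min(n, pos + period)
        freq[pos:end] = f_c
        amp[pos:end] = a_c
        pos = end

    phase = 2.0 * np.pi * np.cumsum(freq) / RATE_HZ
    harmonic = np.zeros(n)
    for h in range(1, 7):
        harmonic += np.sin(h * phase) / h
    x = 0.5 * amp * harmonic / 2.45  # sum of 1/h for h=1..6 bounds |harmonic|
    x = x + 0.25 * spec.breath_noise * rng.standard_normal(n)
    peak = np.abs(x).max()
    if peak > 0.99:
        x = x * (0.99 / peak)
    return x


def attach_waveforms(utterances, specs, seed: int, hop_s: float = 0.0116) -> None:
    """Synthesize a waveform per utterance, duration matching its frame count."""
    by_id = {s.type_id: s for s in specs}
    rng = np.random.default_rng(seed)
    for utt in utterances:
        dur = max(0.25, utt.frames.shape[0] * hop_s)
        utt.waveform = synth_waveform(by_id[utt.type_id], dur, int(rng.integers(0, 2**31 - 1)))


def write_corpus(utterances, specs, out_dir) -> list[Path]:
    """Write a corpus to disk: manifest CSV, per-utterance feature CSVs,
    phoneme-label JSON, and 16-bit PCM WAV files where waveforms exist.

    Returns the list of written paths (manifest first).
    """
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    rows = []
    labels = {}
    for utt in utterances:
        feat_path = out / "features" / f"{utt.utterance_id}.csv"
        cols = [f"f{j:03d}" for j in range(utt.frames.shape[1])]
        pd.DataFrame(utt.frames, columns=cols).to_csv(feat_path, index=False)
        written.append(feat_path)
        labels[utt.utterance_id] = utt.phoneme_labels
        wav_path = ""
        if utt.waveform is not None:
            (out / "wav").mkdir(exist_ok=True)
            wp = out / "wav" / f"{utt.utterance_id}.wav"
            wavfile.write(wp, RATE_HZ, (np.clip(utt.waveform, -1, 1) * 32767).astype(np.int16))
            written.append(wp)
            wav_path = str(wp.relative_to(out))
        rows.append(
            {
                "utterance_id": utt.utterance_id,
                "type_id": utt.type_id,
                "split": utt.split,
                "n_frames": utt.frames.shape[0],
                "features_path": str(feat_path.relative_to(out)),
                "wav_path": wav_path,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    labels_path = out / "labels.json"
    labels_path.write_text(json.dumps(labels, indent=1, sort_keys=True))
    types_path = out / "speech_types.json"
    types_path.write_text(
        json.dumps(
            {
                s.type_id: {
                    "name": s.name,
                    "is_normal": s.is_normal,
                    "f0_hz": s.f0_hz,
                    "jitter": s.jitter,
                    "shimmer": s.shimmer,
                    "breath_noise": s.breath_noise,
                }
                for s in specs
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [manifest, labels_path, types_path] + written
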