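"""End-to-end orchestration of the synthetic workflow.

``run_pipeline`` chains the package's stages on generated data:

1. **synth** — generate a cluster-structured synthetic corpus (and a
   few waveforms) and write it to disk;
2. **features** — extract Mel-spectrograms and MFCC+delta features for
   the utterances that carry waveforms;
3. **cluster** — fit the fuzzy EM model on the pooled training frames;
4. **gate** — run the membership-gated conversion loop (oracle centroid
   converter) on every dysarthric test/validation utterance;
5. **eval** — score intelligibility on synthetic transcript pairs whose
   error rate depends on the gate outcome, plus a MOS-style aggregation
   of simulated ratings, exercising the WER/MOS machinery end to end.

One global seed fans out to per-stage seeds through a documented
counter scheme (``SeedSequence([seed, stage_index])``), so each stage
is individually reproducible.  Every written file is recorded in the
run manifest with a SHA-256 content hash; repeated runs with the same
config and seed produce identical hashes (timing fields aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conversion_gate import (
    GateConfig,
    IdentityConverter,
    convert_until_normal,
    oracle_centroid_converter,
)
from .evaluation import TranscriptPair, mos_mean, wer_corpus
from .features import compute_mel_spectrogram, compute_mfcc_with_deltas, Waveform
from .fem_cluster import FemConfig, fit_fem
from .synthetic_corpus import (
    CorpusConfig,
    attach_waveforms,
    generate_feature_corpus,
    write_corpus,
)

logger = logging.getLogger(__name__)

_STAGES = ("synth", "features", "cluster", "gate", "eval")

# small word list for the synthetic transcript demo
_WORDS = (
    "the cat sat on a mat and the dog ran to the park while birds sang "
    "softly over green hills near still water under bright morning light"
).split()

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """Flat, JSON-serializable configuration of the full pipeline."""

    seed: int = 7
    out_dir: str = "femvoice_run"
    log_level: str = "INFO"
    # synth stage
    corpus_n_types: int = 15
    corpus_utterances_per_type: int = 6
    corpus_frames_min: int = 30
    corpus_frames_max: int = 60
    corpus_n_phonemes: int = 10
    corpus_min_separation: float = 6.0
    corpus_spread: float = 1.0
    corpus_split_train: float = 0.80
    corpus_split_test: float = 0.10
    corpus_split_validation: float = 0.10
    n_waveforms: int = 2
    # cluster stage
    cluster_m: float = 2.0
    cluster_tol: float = 1e-5
    cluster_max_iter: int = 200
    # gate stage
    gate_alpha: float = 0.2
    gate_max_iter: int = 50
    # eval stage
    eval_sentence_words: int = 8
    eval_error_rate_converted: float = 0.1
    eval_error_rate_unconverted: float = 0.6

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global seed and the stage's index."""
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: dict, stage: str, out_root: Path, paths, t0: float) -> None:
    manifest["stages"][stage] = {
        "seed": stage_seed(manifest["config"]["seed"], stage),
        "files": {str(Path(p).relative_to(out_root)): _sha256(Path(p)) for p in paths},
        "timing_s": round(time.perf_counter() - t0, 4),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic workflow; returns the run manifest."""
    logging.basicConfig(level=config.log_level, stream=sys.stderr)
    out = Path(config.out_dir)
    if not out.exists():
        out.mkdir(parents=True)
        logger.info("created output directory %s", out)
    manifest: dict = {
        "config": asdict(config),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "femvoice": __version__,
        },
        "stages": {},
    }

    # ---- synth ------------------------------------------------------
    t0 = time.perf_counter()
    corpus_cfg = CorpusConfig(
        n_types=config.corpus_n_types,
        frames_per_utterance=(config.corpus_frames_min, config.corpus_frames_max),
        utterances_per_type=config.corpus_utterances_per_type,
        n_phonemes=config.corpus_n_phonemes,
        min_separation=config.corpus_min_separation,
        spread=config.corpus_spread,
        split_fractions=(
            config.corpus_split_train,
            config.corpus_split_test,
            config.corpus_split_validation,
        ),
        seed=stage_seed(config.seed, "synth"),
    )
    try:
        utterances, specs = generate_feature_corpus(corpus_cfg)
        attach_waveforms(
            utterances[: config.n_waveforms], specs, stage_seed(config.seed, "synth") + 1
        )
        corpus_paths = write_corpus(utterances, specs, out / "corpus")
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"stage 'synth' failed ({out / 'corpus'}): {exc}") from exc
    _record(manifest, "synth", out, corpus_paths, t0)

    # ---- features ---------------------------------------------------
    t0 = time.perf_counter()
    feat_dir = out / "acoustic_features"
    feat_dir.mkdir(exist_ok=True)
    feat_paths = []
    try:
        for utt in utterances[: config.n_waveforms]:
            wav = Waveform(utt.waveform)
            mel = compute_mel_spectrogram(wav)
            mfcc = compute_mfcc_with_deltas(wav)
            mp = feat_dir / f"{utt.utterance_id}_mel.csv"
            cp = feat_dir / f"{utt.utterance_id}_mfcc.csv"
            pd.DataFrame(mel.values.T).to_csv(mp, index=False)
            pd.DataFrame(mfcc.values).to_csv(cp, index=False)
            feat_paths += [mp, cp]
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'features' failed ({feat_dir}): {exc}") from exc
    _record(manifest, "features", out, feat_paths, t0)

    # ---- cluster ----------------------------------------------------
    t0 = time.perf_counter()
    normal_type = next(s.type_id for s in specs if s.is_normal)
    train = [u for u in utterances if u.split == "train"]
    X = np.vstack([u.frames for u in train])
    mask = np.concatenate(
        [np.full(u.frames.shape[0], u.type_id == normal_type) for u in train]
    )
    try:
        fem = fit_fem(
            X,
            mask,
            FemConfig(
                n_clusters=config.corpus_n_types,
                m=config.cluster_m,
                tol_centers=config.cluster_tol,
                tol_memberships=config.cluster_tol,
                max_iter=config.cluster_max_iter,
                seed=stage_seed(config.seed, "cluster"),
            ),
        )
        model_path = out / "model.json"
        fem.model.to_json(model_path)
        u_path = out / "membership.csv"
        pd.DataFrame(fem.U).round(9).to_csv(u_path, index=False)
        fit_path = out / "fit_summary.json"
        fit_path.write_text(
            json.dumps(
                {
                    "n_iter": fem.n_iter,
                    "converged": fem.converged,
                    "converged_by": fem.converged_by,
                    "objective_first": fem.objective_trace[0],
                    "objective_last": fem.objective_trace[-1],
                },
                indent=1,
                sort_keys=True,
            )
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'cluster' failed ({out / 'model.json'}): {exc}") from exc
    _record(manifest, "cluster", out, [model_path, u_path, fit_path], t0)

    # ---- gate -------------------------------------------------------
    t0 = time.perf_counter()
    converter = oracle_centroid_converter(fem.model, config.gate_alpha)
    gate_cfg = GateConfig(max_iter=config.gate_max_iter)
    held_out = [
        u
        for u in utterances
        if u.split in ("test", "validation") and u.type_id != normal_type
    ]
    gate_rows = []
    try:
        for utt in held_out:
            res = convert_until_normal(utt.frames, converter, fem.model, gate_cfg)
            gate_rows.append(
                {
                    "utterance_id": utt.utterance_id,
                    "type_id": utt.type_id,
                    "n_iter": res.n_iter,
                    "terminated_by": res.terminated_by,
                    "final_normal_membership": float(
                        res.membership_trace[-1][fem.model.normal_index]
                    ),
                }
            )
        gate_path = out / "gate_results.json"
        gate_path.write_text(json.dumps(gate_rows, indent=1, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'gate' failed ({out / 'gate_results.json'}): {exc}") from exc
    _record(manifest, "gate", out, [gate_path], t0)

    # ---- eval -------------------------------------------------------
    t0 = time.perf_counter()
    rng = np.random.default_rng(stage_seed(config.seed, "eval"))
    pairs, ratings = [], []
    try:
        for row in gate_rows:
            ref = list(rng.choice(_WORDS, config.eval_sentence_words))
            converted = row["terminated_by"] == "normal_reached"
            p_err = (
                config.eval_error_rate_converted
                if converted
                else config.eval_error_rate_unconverted
            )
            hyp = [w if rng.random() > p_err else str(rng.choice(_WORDS)) for w in ref]
            pairs.append(TranscriptPair(ref, hyp))
            ratings.append(int(rng.integers(4, 6) if converted else rng.integers(2, 4)))
        eval_payload = {
            "n_gated_utterances": len(gate_rows),
            "gate_success_rate_percent": 100.0
            * sum(r["terminated_by"] == "normal_reached" for r in gate_rows)
            / max(1, len(gate_rows)),
            "pooled_wer_percent": wer_corpus(pairs).wer_percent if pairs else None,
            "macro_wer_percent": wer_corpus(pairs, "macro").wer_percent if pairs else None,
            "mos_mean": mos_mean(ratings) if ratings else None,
        }
        eval_path = out / "evaluation.json"
        eval_path.write_text(json.dumps(eval_payload, indent=1, sort_keys=True))
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'eval' failed ({out / 'evaluation.json'}): {exc}") from exc
    _record(manifest, "eval", out, [eval_path], t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
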