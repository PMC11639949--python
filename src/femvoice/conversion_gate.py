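"""Membership-gated iterative voice conversion.

At inference the framework repeatedly applies a conversion operator to
an utterance and re-evaluates its fuzzy membership under the fitted
cluster model; conversion stops as soon as the membership degree of the
normal-speech cluster *strictly exceeds* that of every dysarthric
cluster (ties are conservatively treated as not-normal).  The learned
diffusion converter itself is outside this package's scope — conversion
operators plug in through a simple shape-preserving callable contract —
but two reference operators are provided:

* :func:`oracle_centroid_converter` — a deterministic affine test
  double that moves every frame a fraction ``alpha`` toward the normal
  centroid (distance contracts by ``(1 - alpha)`` per application);
* :class:`IdentityConverter` — a no-op, useful to exercise the
  ``max_iter`` safeguard.

A forward-noising utility mirrors the corruption phase of a diffusion
model on Mel-spectrograms (Gaussian noise of scheduled magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fem_cluster import ClusterModel

__all__ = [
    "GateConfig",
    "GateResult",
    "GateError",
    "NoiseSchedule",
    "is_normal",
    "utterance_membership",
    "convert_until_normal",
    "forward_noise",
    "oracle_centroid_converter",
    "OracleCentroidConverter",
    "IdentityConverter",
]

ConversionOperator = Callable[[np.ndarray], np.ndarray]


class GateError(RuntimeError):
    """A conversion operator violated its contract mid-loop."""


@dataclass
class GateConfig:
    max_iter: int = 50
    normal_index: int | None = None  # default: the model's normal cluster
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise ValueError("aggregate must be 'mean' or 'median'")


@dataclass
class GateResult:
    output: np.ndarray
    n_iter: int
    terminated_by: str  # 'normal_reached' | 'max_iter'
    membership_trace: list[np.ndarray]  # length n_iter + 1 (includes pre-loop state)


@dataclass
class NoiseSchedule:
    """Nondecreasing per-step noise standard deviations."""

    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=np.float64)
        if self.sigmas.ndim != 1 or self.sigmas.size == 0:
            raise ValueError("schedule must be a nonempty 1-D sequence")
        if self.sigmas[0] < 0 or np.any(np.diff(self.sigmas) < 0):
            raise ValueError("sigmas must be nonnegative and nondecreasing")

    def __len__(self) -> int:
        return self.sigmas.size

    @classmethod
    def linear(cls, sigma_max: float, n_steps: int) -> "NoiseSchedule":
        return cls(np.linspace(0.0, sigma_max, n_steps))


def is_normal(membership: Sequence[float], normal_index: int) -> bool:
    """True iff the normal-cluster membership strictly exceeds every
    dysarthric-cluster membership (ties -> False)."""
    mu = np.asarray(membership, dtype=np.float64)
    if not 0 <= normal_index < mu.size:
        raise ValueError(f"normal_index {normal_index} out of range for K={mu.size}")
    others = np.delete(mu, normal_index)
    return bool(np.all(mu[normal_index] > others))


def utterance_membership(
    frames: np.ndarray, model: ClusterModel, aggregate: str = "mean"
) -> np.ndarray:
    """Aggregate per-frame memberships into one utterance-level K-vector.

    The default rule is the arithmetic mean of the frame membership
    rows, which preserves the sum-to-one property; ``median`` is
    renormalized."""
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[0] == 0:
        raise ValueError("cannot aggregate membership of an empty frame set")
    u = np.atleast_2d(model.predict_membership(frames))
    if aggregate == "mean":
        return u.mean(axis=0)
    if aggregate == "median":
        med = np.median(u, axis=0)
        s = med.sum()
        return med / s if s > 0 else np.full(u.shape[1], 1.0 / u.shape[1])
    raise ValueError(f"unknown aggregation rule {aggregate!r}")


def convert_until_normal(
    x: np.ndarray,
    converter: ConversionOperator,
    model: ClusterModel,
    cfg: GateConfig | None = None,
    feature_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> GateResult:
    """Apply ``converter`` until the utterance is normal-dominant.

    ``feature_fn`` maps the converter-domain state (e.g. a
    Mel-spectrogram) to the feature matrix the cluster model scores;
    identity by default, which covers feature-space conversion.
    """
    cfg = cfg or GateConfig()
    normal_index = cfg.normal_index if cfg.normal_index is not None else model.normal_index
    to_features = feature_fn or (lambda s: s)
    state = np.asarray(x, dtype=np.float64)

    mu = utterance_membership(to_features(state), model, cfg.aggregate)
    trace = [mu]
    if is_normal(mu, normal_index):
        return GateResult(state, 0, "normal_reached", trace)

    apply = converter.apply if hasattr(converter, "apply") else converter
    for it in range(1, cfg.max_iter + 1):
        new_state = np.asarray(apply(state), dtype=np.float64)
        if new_state.shape != state.shape:
            raise GateError(
                f"converter changed shape {state.shape} -> {new_state.shape} at iteration {it}"
            )
        if not np.all(np.isfinite(new_state)):
            raise GateError(f"converter produced non-finite values at iteration {it}")
        state = new_state
        mu = utterance_membership(to_features(state), model, cfg.aggregate)
        trace.append(mu)
        if is_normal(mu, normal_index):
            return GateResult(state, it, "normal_reached", trace)
    return GateResult(state, cfg.max_iter, "max_iter", trace)


def forward_noise(
    mel: np.ndarray, schedule: NoiseSchedule, step: int, seed: int
) -> np.ndarray:
    """Forward (corrupting) diffusion step: add zero-mean Gaussian noise
    of standard deviation ``schedule.sigmas[step]`` to every entry."""
    if not 0 <= step < len(schedule):
        raise ValueError(f"step {step} outside schedule of length {len(schedule)}")
    mel = np.asarray(mel, dtype=np.float64)
    sigma = schedule.sigmas[step]
    if sigma == 0.0:
        return mel.copy()
    rng = np.random.default_rng(seed)
    return mel + rng.normal(0.0, sigma, size=mel.shape)


class OracleCentroidConverter:
    """Deterministic affine converter: each frame moves a fraction
    ``alpha`` toward the normal centroid, so its distance to that
    centroid contracts by exactly ``(1 - alpha)`` per application."""

    def __init__(self, target: np.ndarray, alpha: float):
        if not 0.0 < alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        self.target = np.asarray(target, dtype=np.float64)
        self.alpha = float(alpha)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return x + self.alpha * (self.target - x)

    __call__ = apply


def oracle_centroid_converter(model: ClusterModel, alpha: float) -> OracleCentroidConverter:
    """Oracle converter pulling frames toward the model's normal centroid."""
    return OracleCentroidConverter(model.normal_center, alpha)


class IdentityConverter:
    """No-op converter (never changes the utterance)."""

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=np.float64).copy()

    __call__ = apply
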