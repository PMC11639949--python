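"""Intelligibility and quality metrics: WER and MOS aggregation.

Word error rate is computed from a minimal-cost word-level alignment
(Levenshtein distance with unit substitution/deletion/insertion costs):

    WER = (S + D + I) / N * 100%

with N the reference length.  Corpus-level WER pools the edit counts
over all pairs before applying the formula (a per-utterance macro
average is available as an option).  Severity-level results for mild
and severe dysarthria are combined into a "total" figure as their
unweighted mean, the convention used in published WER comparisons of
dysarthric voice-conversion systems; a weighted variant is provided for
unequal group sizes.  MOS is the arithmetic mean of 1-5 listener
ratings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TranscriptPair",
    "EditOps",
    "WerResult",
    "MosRatings",
    "tokenize",
    "align_edit_ops",
    "wer",
    "word_error_rate",
    "wer_corpus",
    "total_wer",
    "mos_mean",
    "PUBLISHED_WER_COMPARISON",
]

# Published WER comparison (mild, severe) of voice-conversion systems on
# dysarthric speech, used as worked-example input for total_wer.
PUBLISHED_WER_COMPARISON: dict[str, tuple[float, float]] = {
    "StarGAN-VC": (0.697, 0.751),
    "Auto-VC": (0.78, 0.867),
    "CycleGAN-VC": (0.781, 0.83),
    "VAE": (0.779, 0.867),
    "CycleVAE": (0.612, 0.695),
    "Duta-VC": (0.527, 0.554),
    "Diffusion-FEM": (0.507, 0.548),
}

_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace."""
    return _PUNCT.sub(" ", text.lower()).split()


@dataclass
class TranscriptPair:
    reference: Sequence[str]
    hypothesis: Sequence[str]

    def __post_init__(self) -> None:
        if isinstance(self.reference, str):
            self.reference = tokenize(self.reference)
        if isinstance(self.hypothesis, str):
            self.hypothesis = tokenize(self.hypothesis)
        self.reference = list(self.reference)
        self.hypothesis = list(self.hypothesis)


@dataclass
class EditOps:
    """Substitution / deletion / insertion counts against a reference of N words."""

    S: int
    D: int
    I: int
    N: int

    def __post_init__(self) -> None:
        if min(self.S, self.D, self.I) < 0 or self.N < 1:
            raise ValueError("S, D, I must be >= 0 and N >= 1")
        if self.S + self.D > self.N:
            raise ValueError("S + D cannot exceed the reference length")

    @property
    def total_errors(self) -> int:
        return self.S + self.D + self.I

    def __add__(self, other: "EditOps") -> "EditOps":
        return EditOps(self.S + other.S, self.D + other.D, self.I + other.I, self.N + other.N)


@dataclass
class WerResult:
    wer_percent: float

    def __post_init__(self) -> None:
        if self.wer_percent < 0:
            raise ValueError("WER cannot be negative")


@dataclass
class MosRatings:
    ratings: Sequence[int]

    def __post_init__(self) -> None:
        self.ratings = list(self.ratings)
        if not self.ratings:
            raise ValueError("MOS requires at least one rating")
        for r in self.ratings:
            if int(r) != r or not 1 <= r <= 5:
                raise ValueError(f"rating {r!r} outside the 1-5 opinion scale")


def align_edit_ops(pair: TranscriptPair) -> EditOps:
    """Minimal-cost word alignment with S/D/I accounting.

    Dynamic programming over the reference x hypothesis grid with unit
    costs; on equal cost the backtrace prefers substitution, then
    deletion, then insertion (a fixed, documented tie-break).
    """
    ref, hyp = list(pair.reference), list(pair.hypothesis)
    n, m = len(ref), len(hyp)
    if n == 0:
        raise ValueError("reference transcript must be nonempty")
    d = np.zeros((n + 1, m + 1), dtype=np.int64)
    d[:, 0] = np.arange(n + 1)
    d[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = d[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            d[i, j] = min(sub, d[i - 1, j] + 1, d[i, j - 1] + 1)
    s_cnt = d_cnt = i_cnt = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and d[i, j] == d[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            s_cnt += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and d[i, j] == d[i - 1, j] + 1:
            d_cnt += 1
            i -= 1
        else:
            i_cnt += 1
            j -= 1
    return EditOps(int(s_cnt), d_cnt, i_cnt, n)


def wer(ops: EditOps) -> WerResult:
    """WER = (S + D + I) / N x 100%."""
    return WerResult(100.0 * ops.total_errors / ops.N)


def word_error_rate(reference, hypothesis) -> float:
    """Convenience: percent WER between two transcripts (str or token lists)."""
    return wer(align_edit_ops(TranscriptPair(reference, hypothesis))).wer_percent


def wer_corpus(pairs: Iterable[TranscriptPair], mode: str = "pooled") -> WerResult:
    """Corpus WER: ``pooled`` sums S, D, I, N over all pairs before the
    formula; ``macro`` averages per-utterance percentages."""
    pairs = [p if isinstance(p, TranscriptPair) else TranscriptPair(*p) for p in pairs]
    if not pairs:
        raise ValueError("need at least one transcript pair")
    all_ops = [align_edit_ops(p) for p in pairs]
    if mode == "pooled":
        total = all_ops[0]
        for ops in all_ops[1:]:
            total = total + ops
        return wer(total)
    if mode == "macro":
        return WerResult(float(np.mean([wer(o).wer_percent for o in all_ops])))
    raise ValueError(f"unknown corpus WER mode {mode!r}")


def total_wer(mild: float, severe: float, weights: tuple[float, float] | None = None) -> float:
    """Combine mild- and severe-dysarthria WERs into a total figure.

    Unweighted arithmetic mean by default; pass ``weights`` (e.g. group
    sizes) for a weighted mean."""
    if mild < 0 or severe < 0:
        raise ValueError("WER values cannot be negative")
    if weights is None:
        return (mild + severe) / 2.0
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or w1 + w2 == 0:
        raise ValueError("weights must be nonnegative with positive sum")
    return (w1 * mild + w2 * severe) / (w1 + w2)


def mos_mean(ratings) -> float:
    """Mean opinion score: average of 1-5 listener ratings."""
    if not isinstance(ratings, MosRatings):
        ratings = MosRatings(ratings)
    return float(np.mean(ratings.ratings))
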