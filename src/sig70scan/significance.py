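"""Monte-Carlo significance of classifier scores.

The empirical p-value of a hit is the probability that a random 12-mer
scores at least as high as the hit: the tail fraction of a large seeded
sample of network outputs on random sequences. The published workflow used
10 million random sequences, giving a minimum resolvable p of 1e-7; the
sample size is configurable (tests use 1e4-1e5). The null sample is tied to
the exact model weights via a fingerprint so stale nulls cannot silently
mis-calibrate p-values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from . import seqcore
from .neuralmodel import TrainedClassifier

logger = logging.getLogger(__name__)

NULL_FORMAT_VERSION = 1
DEFAULT_SAMPLE_SIZE = 10_000_000
UNIFORM_BASES = (0.25, 0.25, 0.25, 0.25)

#: Per-candidate p-value cutoff used for genome scanning.
DEFAULT_P_CUTOFF = 2e-4


class SignificanceError(ValueError):
    """Raised for invalid null-distribution inputs or fingerprint mismatch."""


@dataclass(frozen=True)
class NullDistribution:
    """Sorted Monte-Carlo sample of model scores on random 12-mers.

    ``scores`` is ascending; p-values are tail counts over it. The minimum
    resolvable p is 1/sample_size — a reported 0.0 means "< 1/N".
    """

    scores: np.ndarray
    base_probabilities: np.ndarray
    seed: int
    model_fingerprint: str

    @property
    def sample_size(self) -> int:
        return int(self.scores.size)

    @property
    def min_resolvable_p(self) -> float:
        return 1.0 / self.sample_size

    def save(self, path: Union[str, Path]) -> None:
        """Versioned container: float32 scores + JSON metadata (npz)."""
        np.savez_compressed(
            path,
            scores=self.scores.astype(np.float32),
            meta=np.array(
                json.dumps(
                    {
                        "format_version": NULL_FORMAT_VERSION,
                        "base_probabilities": self.base_probabilities.tolist(),
                        "seed": self.seed,
                        "model_fingerprint": self.model_fingerprint,
                    }
                )
            ),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "NullDistribution":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta.get("format_version") != NULL_FORMAT_VERSION:
                raise SignificanceError(
                    f"unsupported null format version {meta.get('format_version')!r}"
                )
            return cls(
                scores=np.asarray(data["scores"], dtype=float),
                base_probabilities=np.asarray(meta["base_probabilities"]),
                seed=int(meta["seed"]),
                model_fingerprint=meta["model_fingerprint"],
            )


def build_null(
    model: TrainedClassifier,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    base_probabilities: Sequence[float] = UNIFORM_BASES,
    seed: int = 0,
    chunk_size: int = 200_000,
) -> NullDistribution:
    """Score *sample_size* random 12-mers and return the sorted sample.

    Random sequences are i.i.d. draws per ``base_probabilities`` (uniform
    A/C/G/T by default; pass a composition-matched distribution, e.g. 61%
    GC, for a background-matched null). Sampling and scoring stream in
    chunks so memory stays bounded at any sample size. Reproducible under
    *seed*.
    """
    if sample_size < 100:
        raise SignificanceError(
            f"sample_size {sample_size} < 100: p-value resolution too coarse"
        )
    probs = np.asarray(base_probabilities, dtype=float)
    if probs.shape != (4,) or not np.isclose(probs.sum(), 1.0):
        raise SignificanceError("base_probabilities must be 4 values summing to 1")
    rng = np.random.default_rng(seed)
    eye = np.eye(4)
    out = np.empty(sample_size)
    done = 0
    while done < sample_size:
        n = min(chunk_size, sample_size - done)
        idx = rng.choice(4, size=(n, seqcore.PAIR_LENGTH), p=probs)
        out[done : done + n] = model.score(eye[idx])
        done += n
    out.sort()
    return NullDistribution(
        scores=out,
        base_probabilities=probs,
        seed=seed,
        model_fingerprint=model.fingerprint,
    )


def p_value(
    null: NullDistribution,
    observed_score: Union[float, np.ndarray],
    model: Optional[TrainedClassifier] = None,
    conservative: bool = False,
) -> Union[float, np.ndarray]:
    """Empirical tail fraction: count(null scores >= observed) / N.

    Ties count into the tail. Computed by binary search on the sorted
    sample. An observed score above the sample maximum returns 0.0, to be
    read as "< 1/N" (see :attr:`NullDistribution.min_resolvable_p`); one
    below the minimum returns 1.0. With ``conservative`` the (k+1)/(N+1)
    estimator is used instead, which can never return exactly 0.

    If *model* is given, its fingerprint must match the null's.
    """
    if null.sample_size == 0:
        raise SignificanceError("null distribution is empty")
    if model is not None and model.fingerprint != null.model_fingerprint:
        raise SignificanceError(
            f"model fingerprint {model.fingerprint} does not match null "
            f"{null.model_fingerprint}; rebuild the null for these weights"
        )
    obs = np.asarray(observed_score, dtype=float)
    k = null.sample_size - np.searchsorted(null.scores, obs, side="left")
    if conservative:
        p = (k + 1) / (null.sample_size + 1)
    else:
        p = k / null.sample_size
    return float(p) if np.isscalar(observed_score) else p


def significance_filter(
    predictions: Sequence,
    null: NullDistribution,
    cutoff: float = DEFAULT_P_CUTOFF,
) -> List:
    """Keep predictions with p <= cutoff, annotating each with its p-value.

    *predictions* are objects with a ``score`` attribute and a ``with_p``
    method (see :class:`~sig70scan.scanner.Prediction`); the scanner default
    cutoff is 2e-4 per candidate, with no multiple-testing correction across
    candidates (a documented limitation).
    """
    if not 0.0 < cutoff <= 1.0:
        raise SignificanceError(f"cutoff must be in (0, 1], got {cutoff}")
    kept = []
    for pred in predictions:
        p = p_value(null, pred.score)
        if p <= cutoff:
            kept.append(pred.with_p(p))
    return kept
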