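"""Prediction distributions and Kullback-Leibler divergence in bits.

A participant's predictions for one agent over a trial window are tallied
into a 4-category count vector and normalized into a prediction
distribution, with additive (Laplace) smoothing to guarantee strict
positivity where needed.  Divergences are reported in bits (base-2
logarithm).

Direction convention: ``kl_divergence(p, q)`` is KL(P || Q) =
sum_x P(x) log2(P(x)/Q(x)), the information lost when Q is used to
approximate P.  In the analyses the reference preference distribution plays
the role of P and the participant's prediction distribution the role of Q,
so a prediction that never uses a vase the agent actually chooses is fatal
without smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_VASES = 4


class AbsoluteContinuityError(ValueError):
    """Q is zero where P has mass; smooth the prediction distribution."""


def smooth_counts(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Additively smoothed relative frequencies.

    Adds ``pseudocount`` to every category before normalizing:
    ``(counts + pc) / (sum(counts) + 4 * pc)``.  The result is strictly
    positive for any non-negative count vector.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (N_VASES,):
        raise ValueError(f"expected 4 counts, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("negative counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return (c + pseudocount) / (c.sum() + N_VASES * pseudocount)


@dataclass(frozen=True)
class PredictionDistribution:
    """Smoothed or raw relative frequencies of one participant's predictions
    for one agent over a presentation window."""

    counts: np.ndarray
    probs: np.ndarray
    smoothed: bool
    window: tuple[int, int]

    def __post_init__(self) -> None:
        assert abs(float(self.probs.sum()) - 1.0) < 1e-12


def prediction_distribution(
    records: pd.DataFrame,
    agent_id: str,
    participant_id: int | None = None,
    up_to_presentation: int | None = None,
    smoothing_mode: str = "if_zero",
    pseudocount: float = 1.0,
    block: int | None = None,
) -> PredictionDistribution:
    """Tally one participant's predictions for one agent into a distribution.

    Missed trials are excluded before counting.  ``smoothing_mode`` is
    ``"if_zero"`` (smooth only when some category was never predicted, the
    convention of the block-level analysis) or ``"always"`` (smooth
    unconditionally, the convention of the assimilation analysis).
    """
    if smoothing_mode not in ("if_zero", "always"):
        raise ValueError(f"unknown smoothing_mode {smoothing_mode!r}")
    sub = records
    if participant_id is not None:
        sub = sub[sub["participant_id"] == participant_id]
    sub = sub[(sub["agent_id"] == agent_id) & (~sub["missed"].astype(bool))]
    if block is not None:
        sub = sub[sub["block"] == block]
    if up_to_presentation is not None:
        sub = sub[sub["presentation_index"] <= up_to_presentation]
    if len(sub) == 0:
        raise ValueError(
            f"no usable (non-missed) trials for agent {agent_id!r}"
            + (f", participant {participant_id}" if participant_id is not None else "")
        )
    pred = sub["predicted_vase"].to_numpy(dtype=int)
    counts = np.bincount(pred, minlength=N_VASES).astype(float)
    lo = int(sub["presentation_index"].min())
    hi = int(sub["presentation_index"].max())

    if smoothing_mode == "always" or np.any(counts == 0):
        probs = smooth_counts(counts, pseudocount)
        smoothed = True
    else:
        probs = counts / counts.sum()
        smoothed = False
    return PredictionDistribution(counts=counts, probs=probs, smoothed=smoothed, window=(lo, hi))


def _validate_dist(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a 1-D probability vector")
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(float(p.sum()) - 1.0) > 1e-9:
        raise ValueError(f"{name} sums to {p.sum()!r}, not 1")
    return p


def kl_divergence(p, q) -> float:
    """KL(P || Q) in bits: information lost approximating P by Q.

    Terms with P(x) = 0 contribute zero.  Raises
    :class:`AbsoluteContinuityError` when Q(x) = 0 at some x with
    P(x) > 0 (the divergence would be infinite; smooth Q first).
    """
    p = _validate_dist(p, "P")
    q = _validate_dist(q, "Q")
    if p.shape != q.shape:
        raise ValueError("P and Q must have the same length")
    support = p > 0
    if np.any(q[support] <= 0):
        raise AbsoluteContinuityError(
            "Q has zero mass where P is positive; apply additive smoothing to "
            "the prediction distribution before computing the divergence"
        )
    ps = p[support]
    # Gibbs' inequality guarantees non-negativity; clamp the float residue
    # that appears when P and Q are numerically equal
    return max(float(np.sum(ps * np.log2(ps / q[support]))), 0.0)


def symmetric_kl(p, q) -> float:
    """Jeffreys divergence KL(P || Q) + KL(Q || P), in bits.

    Symmetric, non-negative, zero iff P = Q; requires both distributions to
    be mutually absolutely continuous (in practice: smoothed inputs).
    """
    return kl_divergence(p, q) + kl_divergence(q, p)
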