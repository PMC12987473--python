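"""Collapse a Pareto front to one recommended cultivation configuration.

The front's three objectives live on incommensurable scales (days,
t·hm⁻², a unitless closeness in [0, 1]), so each objective is first
min-max normalized over the front to [0, 1] with 1 always the preferred
end (shorter duration, higher yield, higher quality).  A weighted sum of
the normalized objectives — equal weights by default — then picks the
single recommended design.  A raw-units mode (no normalization) is kept
behind a flag for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nsga2 import ParetoFront, ParetoSolution

__all__ = ["DecisionResult", "normalize_front_objectives", "weighted_sum_select"]

EQUAL_WEIGHTS = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class DecisionResult:
    chosen: ParetoSolution
    scores: tuple[float, ...]  # one weighted-sum score per front solution
    weights: tuple[float, float, float]
    normalized: bool

    def to_json_dict(self) -> dict:
        return {
            "chosen": {
                "spacing_cm": self.chosen.design.spacing_cm,
                "pruning": self.chosen.design.pruning_label,
                "duration_days": self.chosen.duration_days,
                "yield_t_hm2": self.chosen.yield_t_hm2,
                "ci": self.chosen.ci,
            },
            "scores": list(self.scores),
            "weights": list(self.weights),
            "normalized": self.normalized,
        }


def normalize_front_objectives(front: ParetoFront) -> np.ndarray:
    """Per-objective min-max normalization over the front, oriented so 1 is
    always best (duration inverted).  A zero-range objective maps to 1 for
    every solution."""
    if not front.solutions:
        raise ValueError("empty Pareto front")
    raw = np.array(
        [[s.duration_days, s.yield_t_hm2, s.ci] for s in front.solutions]
    )
    out = np.ones_like(raw)
    for j, maximize in enumerate((False, True, True)):
        col = raw[:, j]
        rng = col.max() - col.min()
        if rng == 0:
            continue
        scaled = (col - col.min()) / rng
        out[:, j] = scaled if maximize else 1.0 - scaled
    return out


def weighted_sum_select(
    front: ParetoFront,
    weights: tuple[float, float, float] = EQUAL_WEIGHTS,
    normalize: bool = True,
) -> DecisionResult:
    """Score every front solution by Σ weight_k · objective_k and return the
    argmax.  Ties are broken deterministically in favour of shorter
    duration, then higher yield, then higher quality closeness — the order
    of the stated production goals (early maturity, high yield, quality)."""
    if not front.solutions:
        raise ValueError("empty Pareto front")
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or np.any(w <= 0):
        raise ValueError("weights must be three positive numbers")
    if normalize:
        mat = normalize_front_objectives(front)
    else:
        mat = np.array(
            [[-s.duration_days, s.yield_t_hm2, s.ci] for s in front.solutions]
        )
    scores = mat @ w
    best = np.max(scores)
    tied = np.flatnonzero(scores == best)
    candidates = sorted(
        tied,
        key=lambda i: (
            front.solutions[i].duration_days,
            -front.solutions[i].yield_t_hm2,
            -front.solutions[i].ci,
        ),
    )
    chosen = front.solutions[candidates[0]]
    return DecisionResult(
        chosen=chosen,
        scores=tuple(float(s) for s in scores),
        weights=tuple(float(x) for x in w),
        normalized=normalize,
    )
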