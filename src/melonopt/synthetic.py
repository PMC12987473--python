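"""Synthetic two-factor melon trials with known ground truth.

Generates treatment-mean datasets with the statistical structure the
analysis chain assumes: smooth response surfaces over (spacing, pruning)
plus independent Gaussian replicate noise.  The default surfaces encode
the directional findings of the field trial —

* yield strictly decreases with plant spacing, and the three-vine
  two-fruit (3V2F) mode out-yields the other pruning modes;
* the growth period lengthens with the number of retained vines
  (single-vine ≈ 101 d, double-vine ≈ 108 d, triple-vine ≈ 118 d);
* comprehensive quality closeness rises with spacing (a logistic in
  spacing, keeping targets inside [0, 1]) with pruning offsets ordered
  3V2F > 2V2F > 3V3F;
* the nine quality indicators rise gently with spacing with the same
  pruning-offset ordering.

Scenarios with a planted known optimum support end-to-end recovery tests:
``planted_optimum`` applies the exhaustive Pareto + weighted-sum decision
rule to the noiseless surfaces, giving the target the full pipeline should
find from noisy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import DecisionResult, weighted_sum_select
from .nsga2 import ParetoFront, ParetoSolution, decode_genome, dominates, feasible_genomes
from .trial_data import (
    INDICATOR_NAMES,
    PRUNING_LABELS,
    VINES_PER_CODE,
    TreatmentSpec,
    TrialDataset,
)

__all__ = [
    "Scenario",
    "paper_like_scenario",
    "full_grid_scenario",
    "generate_trial",
    "planted_optimum",
    "true_pareto_front",
    "fill_missing_yields",
]

#: Indicator magnitudes for the synthetic quality table (single-fruit-weight
#: kg ... vitamin C mg·kg⁻¹), matching the observed trial's scale.
_INDICATOR_BASE: dict[str, float] = {
    "single_fruit_weight_kg": 2.4,
    "fruit_shape_index": 1.35,
    "flesh_moisture_pct": 88.0,
    "hardness_N": 2.55,
    "flesh_thickness_mm": 38.0,
    "soluble_solids_pct": 13.7,
    "soluble_sugar_mg_g": 1.1,
    "soluble_sugar_pct": 13.5,
    "vitamin_c_mg_kg": 3.4,
}


@dataclass(frozen=True)
class Scenario:
    """Response surfaces, noise model and design for one synthetic trial.

    Surface parametrization (spacing s in cm, pruning code c):

    * duration(s, c) = duration_base[c] + duration_slope · (s − 55)
    * yield(s, c)    = yield_base[c] − yield_slope · (s − 55)
    * ci(s, c)       = logistic(ci_steepness · (s − ci_midpoint[c]))
    * indicator(k; s, c) = base_k · (1 + indicator_slope · (s − 55)
                                        + indicator_offset[c])

    ``design`` optionally fixes an explicit (spacing, code) treatment list;
    when None the full factorial of ``spacings`` × ``pruning_codes`` is
    built.  Replicate noise is independent Gaussian; the per-response sd is
    ``noise_frac`` times the range of that response's surface means over
    the design (``noise_frac`` times the mean magnitude for indicators).
    """

    spacings: tuple[int, ...] = (55, 65, 75)
    pruning_codes: tuple[int, ...] = (1, 2, 3, 4)
    design: tuple[tuple[int, int], ...] | None = None
    replicates: int = 3
    noise_frac: float = 0.03
    seed: int = 0

    duration_base: dict[int, float] = field(
        default_factory=lambda: {1: 101.0, 2: 108.5, 3: 118.3, 4: 118.0}
    )
    duration_slope: float = 0.0
    yield_base: dict[int, float] = field(
        default_factory=lambda: {1: 27.86, 2: 49.5, 3: 51.0, 4: 53.97}
    )
    yield_slope: float = 0.35
    ci_midpoint: dict[int, float] = field(
        default_factory=lambda: {1: 60.0, 2: 68.0, 3: 72.0, 4: 64.0}
    )
    ci_steepness: float = 0.08
    indicator_slope: float = 0.002
    indicator_offset: dict[int, float] = field(
        default_factory=lambda: {1: 0.01, 2: 0.02, 3: 0.0, 4: 0.04}
    )

    # -- validation ------------------------------------------------------
    def check(self) -> None:
        if self.design is None:
            if len(set(self.spacings)) < 2 or len(set(self.pruning_codes)) < 2:
                raise ValueError(
                    "need at least two spacing levels and two pruning codes"
                )
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.yield_slope <= 0:
            raise ValueError("yield must strictly decrease with spacing")
        by_vines: dict[int, list[float]] = {}
        for code, base in self.duration_base.items():
            by_vines.setdefault(VINES_PER_CODE[code], []).append(base)
        vines_sorted = sorted(by_vines)
        for va, vb in zip(vines_sorted, vines_sorted[1:]):
            if max(by_vines[va]) > min(by_vines[vb]):
                raise ValueError("duration must be non-decreasing in vine count")

    # -- surfaces --------------------------------------------------------
    def duration_mean(self, spacing: float, code: int) -> float:
        return self.duration_base[code] + self.duration_slope * (spacing - 55.0)

    def yield_mean(self, spacing: float, code: int) -> float:
        return self.yield_base[code] - self.yield_slope * (spacing - 55.0)

    def ci_mean(self, spacing: float, code: int) -> float:
        z = self.ci_steepness * (spacing - self.ci_midpoint[code])
        return 1.0 / (1.0 + math.exp(-z))

    def indicator_mean(self, name: str, spacing: float, code: int) -> float:
        base = _INDICATOR_BASE[name]
        return base * (
            1.0
            + self.indicator_slope * (spacing - 55.0)
            + self.indicator_offset[code]
        )

    def objective_triple(self, spacing: float, code: int) -> tuple[float, float, float]:
        """Noiseless (duration, yield, ci) at one design point."""
        return (
            self.duration_mean(spacing, code),
            self.yield_mean(spacing, code),
            self.ci_mean(spacing, code),
        )

    def design_points(self) -> list[tuple[int, int]]:
        if self.design is not None:
            return list(self.design)
        return [(s, c) for s in self.spacings for c in self.pruning_codes]


def paper_like_scenario(seed: int = 0, noise_frac: float = 0.03) -> Scenario:
    """The 10-treatment two-factor design of the observed trial (1V1F kept
    only at 55 cm as the conventional-practice control)."""
    design = (
        (55, 1),
        (55, 2), (55, 3), (55, 4),
        (65, 2), (65, 3), (65, 4),
        (75, 2), (75, 3), (75, 4),
    )
    return Scenario(design=design, seed=seed, noise_frac=noise_frac)


def full_grid_scenario(seed: int = 0, noise_frac: float = 0.03) -> Scenario:
    """All 11 spacing levels × 4 pruning codes: the design whose treatments
    cover the whole feasible optimization grid."""
    return Scenario(
        spacings=tuple(range(30, 85, 5)),
        pruning_codes=(1, 2, 3, 4),
        seed=seed,
        noise_frac=noise_frac,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _label(spacing: int, code: int) -> str:
    return f"S{spacing}-{PRUNING_LABELS[code]}"


def generate_trial(sc: Scenario) -> TrialDataset:
    """Build a trial dataset from the scenario: treatment means of the three
    responses and nine indicators, averaged over seeded Gaussian replicate
    draws (so noise_frac = 0 returns the surface means exactly)."""
    sc.check()
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 101]))
    points = sc.design_points()
    specs = [
        TreatmentSpec(label=_label(s, c), spacing_cm=s, pruning_code=c)
        for s, c in points
    ]
    labels = [t.label for t in specs]

    # per-response noise sd from the range of surface means over the design
    resp_means = {
        "duration_days": np.array([sc.duration_mean(s, c) for s, c in points]),
        "yield_t_hm2": np.array([sc.yield_mean(s, c) for s, c in points]),
        "ci": np.array([sc.ci_mean(s, c) for s, c in points]),
    }
    resp_sd = {
        k: sc.noise_frac * (v.max() - v.min() if v.max() > v.min() else abs(v).max())
        for k, v in resp_means.items()
    }

    resp = pd.DataFrame(
        index=pd.Index(labels, name="treatment"),
        columns=["duration_days", "yield_t_hm2", "ci"],
        dtype=float,
    )
    ind_means = pd.DataFrame(
        index=pd.Index(labels, name="treatment"),
        columns=list(INDICATOR_NAMES),
        dtype=float,
    )
    ind_sds = ind_means.copy()

    for i, (s, c) in enumerate(points):
        for col, surface in resp_means.items():
            reps = surface[i] + resp_sd[col] * rng.standard_normal(sc.replicates)
            mean = float(reps.mean())
            if col == "ci":
                mean = float(np.clip(mean, 0.0, 1.0))
            if col == "duration_days":
                mean = max(mean, 1.0)
            resp.loc[labels[i], col] = mean
        for name in INDICATOR_NAMES:
            mu = sc.indicator_mean(name, s, c)
            reps = mu + sc.noise_frac * abs(mu) * rng.standard_normal(sc.replicates)
            reps = np.maximum(reps, 1e-6)  # indicators are strictly positive
            ind_means.loc[labels[i], name] = float(reps.mean())
            ind_sds.loc[labels[i], name] = float(reps.std(ddof=1)) if sc.replicates > 1 else 0.0

    return TrialDataset(
        treatments=specs,
        indicators=ind_means,
        indicator_sds=ind_sds,
        responses=resp,
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


def true_pareto_front(sc: Scenario) -> ParetoFront:
    """Exact Pareto front of the noiseless scenario surfaces over the full
    44-design feasible grid (enumeration, no surrogate)."""
    sc.check()
    sols = []
    for g in feasible_genomes():
        spec = decode_genome(g)
        dur, yld, ci = sc.objective_triple(spec.spacing_cm, spec.pruning_code)
        sols.append(
            ParetoSolution(
                design=spec, duration_days=dur, yield_t_hm2=yld, ci=ci
            )
        )
    objs = [s.objectives_min for s in sols]
    keep = [
        s
        for i, s in enumerate(sols)
        if not any(dominates(objs[j], objs[i]) for j in range(len(sols)) if j != i)
    ]
    return ParetoFront(
        solutions=keep, provenance={"algorithm": "scenario-enumeration"}
    )


def planted_optimum(
    sc: Scenario, weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> TreatmentSpec:
    """The design the decision rule selects on the noiseless surfaces —
    the recovery target for end-to-end pipeline tests."""
    result: DecisionResult = weighted_sum_select(true_pareto_front(sc), weights)
    return result.chosen.design


def fill_missing_yields(ds: TrialDataset, sc: Scenario) -> TrialDataset:
    """Complete missing yield responses from the scenario's noiseless yield
    surface (observed yields are left untouched)."""
    resp = ds.ensure_responses()
    for t in ds.treatments:
        if pd.isna(resp.loc[t.label, "yield_t_hm2"]):
            resp.loc[t.label, "yield_t_hm2"] = sc.yield_mean(
                t.spacing_cm, t.pruning_code
            )
    return ds
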