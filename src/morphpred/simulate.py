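"""Synthetic two-arm randomized-cohort generator.

Real trial data are not redistributable, so every downstream stage of the
pipeline is exercised on synthetic cohorts with the statistical structure
the analysis assumes:

* a two-arm flow (recruited → excluded at baseline MRI → randomized →
  lost to follow-up → analyzed);
* YMRS trajectories whose week-6 reductions realize a latent responder
  status exactly (responder reductions are drawn well above 50%,
  non-responder reductions well below, so the ≥50% rule recovers the
  latent status with probability 1 by construction);
* baseline and week-1 feature matrices with arm-specific planted
  discriminative patterns and within-subject baseline–week-1 correlation.

Generative model, per analyzed subject with latent status ``s = ±1/2``
(responder = +1/2) and per feature ``j`` with per-measure scale
``(μ_j, σ_j)``:

    baseline_j ~ Normal(μ_j + s·d_j·σ_j, σ_j²)
    week1_j    = μ_j + ρ·(baseline_j − μ_j) − s·δ_j·σ_j + ε_j,
                 ε_j ~ Normal(0, τ²·σ_j²)

``d_j`` is nonzero only for the arm's *baseline* effect features and
``δ_j`` only for its *change* effect features (so baseline − week1 carries
a ``+s·δ_j·σ_j`` signal). With the default noise scale τ = √(1−ρ²) the
week-1 marginal variance equals the baseline variance and the empirical
baseline–week-1 correlation converges to ρ.

The per-measure scale profile defaults (thickness 2.5 ± 0.15 mm, area
2500 ± 400 mm², volume 4000 ± 600 mm³) are physiologically plausible
conventions chosen so binarization and scaling code is exercised across
three orders of magnitude; they are conventions, not claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SpecError
from .features import FeatureTable
from .outcomes import ARMS, SubjectRecord, label_responders
from .schema import RegionSchema, build_default_schema

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_paper_flow",
    "default_effect_features",
    "DEFAULT_SCALE_PROFILE",
]

#: (mean, sd) per measure; see module docstring.
DEFAULT_SCALE_PROFILE = {
    "thickness": (2.5, 0.15),
    "area": (2500.0, 400.0),
    "volume": (4000.0, 600.0),
}

# regions carrying the default planted patterns; disjoint between arms,
# echoing the qualitative finding that predictors differ by drug:
# temporal/subcortical features for the quetiapine-like arm,
# frontal/parietal for the lithium-like arm.
_QUETIAPINE_THICKNESS = ("superiortemporal", "middletemporal", "inferiortemporal")
_QUETIAPINE_VOLUMES = ("hippocampus", "amygdala")
_LITHIUM_THICKNESS = (
    "superiorfrontal",
    "rostralmiddlefrontal",
    "precuneus",
    "superiorparietal",
    "inferiorparietal",
)


def default_effect_features(schema: Optional[RegionSchema] = None) -> dict[str, list[int]]:
    """Default arm-specific planted feature indices (10 per arm, disjoint)."""
    schema = schema or build_default_schema()
    names = schema.feature_names
    quetiapine = [
        names.index(f"{h}_{r}_thickness") for r in _QUETIAPINE_THICKNESS for h in ("lh", "rh")
    ] + [names.index(f"{h}_{s}_volume") for s in _QUETIAPINE_VOLUMES for h in ("lh", "rh")]
    lithium = [
        names.index(f"{h}_{r}_thickness") for r in _LITHIUM_THICKNESS for h in ("lh", "rh")
    ]
    return {"quetiapine": quetiapine, "lithium": lithium}


@dataclass
class SyntheticCohortSpec:
    """Full description of one synthetic trial dataset.

    ``n_per_arm`` is either a single count (both arms equal) or a
    ``(quetiapine, lithium)`` pair of randomized counts. Effects are given
    per arm as ``[(feature index, standardized effect size), ...]``:
    ``baseline_effects`` shift the baseline mean, ``change_effects`` plant
    a signal in the baseline − week-1 difference.
    """

    n_per_arm: int | tuple[int, int] = 60
    responder_proportion: float = 0.5
    baseline_effects: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    change_effects: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    baseline_week1_correlation: float = 0.5
    feature_noise_sd: Optional[float] = None  # default: sqrt(1 - rho^2)
    region_scale_profile: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_PROFILE)
    )
    n_excluded_baseline: int = 0
    n_lost: tuple[int, int] = (0, 0)  # (quetiapine, lithium)
    ymrs_baseline_range: tuple[int, int] = (20, 40)
    responder_reduction_range: tuple[float, float] = (0.60, 0.95)
    nonresponder_reduction_range: tuple[float, float] = (0.05, 0.40)
    seed: int = 0

    @property
    def arm_sizes(self) -> dict[str, int]:
        if isinstance(self.n_per_arm, int):
            return {arm: self.n_per_arm for arm in ARMS}
        return dict(zip(ARMS, self.n_per_arm))

    def resolved_noise_sd(self) -> float:
        if self.feature_noise_sd is not None:
            return self.feature_noise_sd
        return math.sqrt(1.0 - self.baseline_week1_correlation**2)

    def validate(self, schema: RegionSchema) -> None:
        sizes = self.arm_sizes
        lost = dict(zip(ARMS, self.n_lost))
        for arm in ARMS:
            if lost[arm] >= sizes[arm]:
                raise SpecError(
                    f"{arm}: n_lost ({lost[arm]}) must be smaller than the "
                    f"randomized arm size ({sizes[arm]})"
                )
        if not 0.0 < self.responder_proportion < 1.0:
            raise SpecError("responder_proportion must be in (0, 1)")
        if not 0.0 <= self.baseline_week1_correlation < 1.0:
            raise SpecError("baseline_week1_correlation must be in [0, 1)")
        for effects in (self.baseline_effects, self.change_effects):
            for arm, pairs in effects.items():
                if arm not in ARMS:
                    raise SpecError(f"unknown arm {arm!r} in effect map")
                for idx, _ in pairs:
                    if not 0 <= idx < len(schema):
                        raise SpecError(f"effect feature index {idx} outside schema")
        # integer rounding of week-6 scores can shift the reduction by at most
        # 0.5 / ymrs_baseline; the reduction ranges must clear 0.5 by that margin
        # so labels realize the latent status with probability 1.
        slack = 0.5 / self.ymrs_baseline_range[0]
        if self.responder_reduction_range[0] - slack < 0.5:
            raise SpecError(
                "responder reduction range must stay >= 50% after integer rounding"
            )
        if self.nonresponder_reduction_range[1] + slack >= 0.5:
            raise SpecError(
                "non-responder reduction range must stay < 50% after integer rounding"
            )


@dataclass
class SyntheticCohort:
    """Output bundle: all recruited records, analyzed feature tables, truth."""

    records: list[SubjectRecord]  # full recruited cohort, all flow statuses
    baseline: FeatureTable  # analyzed subjects only
    week1: FeatureTable  # analyzed subjects only
    truth: dict[str, bool]  # analyzed subject id -> latent responder status
    schema: RegionSchema
    spec: SyntheticCohortSpec

    @property
    def analyzed_records(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.flow_status == "analyzed"]

    def labels(self) -> np.ndarray:
        """Responder labels of analyzed subjects, in table row order."""
        by_id = {
            lab.subject_id: lab.responder
            for lab in label_responders(self.analyzed_records)
        }
        return np.array([by_id[s] for s in self.baseline.subject_ids], dtype=int)

    def arm_of(self) -> np.ndarray:
        by_id = {r.subject_id: r.arm for r in self.analyzed_records}
        return np.array([by_id[s] for s in self.baseline.subject_ids])


def _feature_scales(schema: RegionSchema, profile) -> tuple[np.ndarray, np.ndarray]:
    mu = np.empty(len(schema))
    sigma = np.empty(len(schema))
    for j, entry in enumerate(schema.entries):
        mu[j], sigma[j] = profile[entry.measure]
    return mu, sigma


def simulate_cohort(
    spec: SyntheticCohortSpec, schema: Optional[RegionSchema] = None
) -> SyntheticCohort:
    """Draw one synthetic cohort; deterministic given ``spec.seed``."""
    schema = schema or build_default_schema()
    spec.validate(schema)
    rng = np.random.default_rng(spec.seed)
    mu, sigma = _feature_scales(schema, spec.region_scale_profile)
    rho = spec.baseline_week1_correlation
    tau = spec.resolved_noise_sd()
    sizes = spec.arm_sizes
    lost = dict(zip(ARMS, spec.n_lost))

    records: list[SubjectRecord] = []
    analyzed_ids: list[str] = []
    baseline_rows: list[np.ndarray] = []
    week1_rows: list[np.ndarray] = []
    truth: dict[str, bool] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:04d}"

    # subjects excluded before randomization: recruited (so they satisfy the
    # YMRS >= 20 inclusion), but no usable scans and no follow-up
    lo, hi = spec.ymrs_baseline_range
    for _ in range(spec.n_excluded_baseline):
        records.append(
            SubjectRecord(
                subject_id=next_id(),
                arm=None,
                ymrs_baseline=float(rng.integers(lo, hi + 1)),
                ymrs_week1=None,
                ymrs_week6=None,
                age_years=float(np.round(rng.uniform(10, 18), 1)),
                sex="M" if rng.random() < 0.5 else "F",
                flow_status="excluded_baseline_mri",
            )
        )

    for arm in ARMS:
        d = np.zeros(len(schema))
        delta = np.zeros(len(schema))
        for idx, eff in spec.baseline_effects.get(arm, []):
            d[idx] = eff
        for idx, eff in spec.change_effects.get(arm, []):
            delta[idx] = eff
        n_arm = sizes[arm]
        # which randomized subjects drop out: a seeded choice without replacement
        lost_positions = set(rng.choice(n_arm, size=lost[arm], replace=False).tolist())
        for pos in range(n_arm):
            sid = next_id()
            status = bool(rng.random() < spec.responder_proportion)
            s = 0.5 if status else -0.5
            ymrs0 = int(rng.integers(lo, hi + 1))
            if status:
                r6 = rng.uniform(*spec.responder_reduction_range)
            else:
                r6 = rng.uniform(*spec.nonresponder_reduction_range)
            ymrs6 = int(np.round(ymrs0 * (1.0 - r6)))
            ymrs1 = int(np.round(ymrs0 * (1.0 - r6 / 3.0)))
            base = mu + s * d * sigma + rng.standard_normal(len(schema)) * sigma
            week1 = (
                mu
                + rho * (base - mu)
                - s * delta * sigma
                + rng.standard_normal(len(schema)) * tau * sigma
            )
            if pos in lost_positions:
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        arm=arm,
                        ymrs_baseline=float(ymrs0),
                        ymrs_week1=float(ymrs1),
                        ymrs_week6=None,
                        age_years=float(np.round(rng.uniform(10, 18), 1)),
                        sex="M" if rng.random() < 0.5 else "F",
                        flow_status="lost_followup",
                    )
                )
                continue
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    arm=arm,
                    ymrs_baseline=float(ymrs0),
                    ymrs_week1=float(ymrs1),
                    ymrs_week6=float(ymrs6),
                    age_years=float(np.round(rng.uniform(10, 18), 1)),
                    sex="M" if rng.random() < 0.5 else "F",
                    flow_status="analyzed",
                )
            )
            analyzed_ids.append(sid)
            baseline_rows.append(base)
            week1_rows.append(week1)
            truth[sid] = status

    baseline = FeatureTable(
        analyzed_ids, np.array(baseline_rows), schema.feature_names, "baseline"
    )
    week1 = FeatureTable(analyzed_ids, np.array(week1_rows), schema.feature_names, "week1")
    return SyntheticCohort(records, baseline, week1, truth, schema, spec)


def simulate_paper_flow(
    seed: int = 0,
    effect_size: float = 1.5,
    schema: Optional[RegionSchema] = None,
) -> SyntheticCohort:
    """Preset wiring the published trial flow onto the generator.

    149 recruited, 9 excluded at baseline MRI, 79/61 randomized to the
    quetiapine/lithium arms, 8/11 lost to follow-up — leaving 71 and 50
    analyzed (121 total). The default disjoint arm-specific patterns are
    planted at ``effect_size`` in both baseline and change features.
    """
    schema = schema or build_default_schema()
    effects = default_effect_features(schema)
    spec = SyntheticCohortSpec(
        n_per_arm=(79, 61),
        n_excluded_baseline=9,
        n_lost=(8, 11),
        baseline_effects={a: [(i, effect_size) for i in idx] for a, idx in effects.items()},
        change_effects={a: [(i, effect_size) for i in idx] for a, idx in effects.items()},
        seed=seed,
    )
    return simulate_cohort(spec, schema)
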