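"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a three-group cortical thickness study (two patient
groups and a normative control group) at the level of already-extracted
regional thickness tables:

* a shared anatomical profile: per-region mean thickness drawn uniformly
  from ``region_mean_range`` (default 1.5-4.5 mm), common to all subjects;
* a per-subject global scale factor (brain-size/scanner gain variation);
* clipped-Gaussian region noise (between-subject anatomical variability,
  bounded at 2.5 SD so single regions cannot drift arbitrarily far);
* patient pathology as *increased regional heterogeneity*: zero-mean
  region-specific offsets, resampled per subject, on a configured set of
  affected regions.  A uniform thinning would vanish under within-subject
  standardization, so heterogeneity is the mechanism that propagates to
  the similarity kernel and lowers network strength and clustering while
  raising path length;
* group-structured covariates (premorbid IQ, medication dose, illness
  duration) and clinical scores, with one named score optionally
  constructed to correlate at ``score_effect`` with a named network index.

``deviation_sd`` is expressed in within-subject z units (the scale on
which regional thickness profiles are standardized); offsets are clipped
at 2 SD.  Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import destrieux_registry, toy_atlas
from .cohort import CohortTable, SubjectRecord
from .errors import ValidationError

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "make_worked_fixture"]

GROUP_A = "schizophrenia"
GROUP_B = "bipolar"
GROUP_CONTROL = "control"

#: Nodal regions highlighted by the default planted-correlation target.
DEFAULT_TARGET_REGION = "left superior occipital gyrus"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a 39/37/32 three-group design on the 148-region
    Destrieux atlas with moderate patient deviation heterogeneity on 30
    regions per patient group, and a mania-scale score correlated at 0.45
    with the nodal clustering coefficient of the left superior occipital
    gyrus in the bipolar-like group.
    """

    n_per_group: tuple[int, int, int] = (39, 37, 32)  # (group A, group B, control)
    n_regions: int = 148
    region_mean_range: tuple[float, float] = (1.5, 4.5)  # mm
    subject_scale_sd: float = 0.05
    region_noise_sd: float = 0.2  # mm
    deviation_sd: dict[str, float] = field(
        default_factory=lambda: {GROUP_A: 0.25, GROUP_B: 0.18, GROUP_CONTROL: 0.0}
    )
    # per group: "all", an int (that many regions drawn from the seed),
    # or an explicit list of region ids
    affected_regions: dict[str, object] = field(
        default_factory=lambda: {GROUP_A: 30, GROUP_B: 30, GROUP_CONTROL: []}
    )
    score_effect: float = 0.45
    score_name: str = "ymrs"
    score_group: str = GROUP_B
    target_index: str = f"nodal_cc:{DEFAULT_TARGET_REGION}"
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise ValidationError("each group needs at least 2 subjects")
        if self.n_regions < 3:
            raise ValidationError("need at least 3 regions")
        lo, hi = self.region_mean_range
        if not (0 < lo < hi):
            raise ValidationError("region_mean_range must be increasing and positive")
        if self.region_noise_sd <= 0 or self.subject_scale_sd < 0:
            raise ValidationError("noise parameters must be positive")
        for g, d in self.deviation_sd.items():
            if d < 0:
                raise ValidationError(f"deviation_sd[{g!r}] must be >= 0")
        if not -1 < self.score_effect < 1:
            raise ValidationError("score_effect must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """Everything needed to recompute the planted effects."""

    region_means: np.ndarray
    affected_regions: dict[str, np.ndarray]
    deviation_sd: dict[str, float]
    planted_offsets: np.ndarray  # subjects x regions, mm
    score_effect: float
    score_name: str
    score_group: str
    target_index: str


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    ground_truth: GroundTruth
    config: SimulationConfig


# Table-1-like score and covariate distributions per group:
# (mean, sd, lower truncation bound) keyed by (field, group)
_COVARIATE_MODEL = {
    ("premorbid_iq", GROUP_A): (100.6, 10.2, None),
    ("premorbid_iq", GROUP_B): (97.7, 8.2, None),
    ("premorbid_iq", GROUP_CONTROL): (107.0, 9.4, None),
    ("medication_dose", GROUP_A): (396.0, 481.0, 0.0),
    ("medication_dose", GROUP_B): (254.0, 317.0, 0.0),
    ("illness_duration", GROUP_A): (13.5, 9.5, 0.5),
    ("illness_duration", GROUP_B): (9.5, 6.9, 0.5),
}

_SCORE_MODEL = {
    ("panss_positive", GROUP_A): (13.7, 7.2, 7.0),
    ("ymrs", GROUP_B): (5.8, 3.0, 0.0),
    ("verbal_fluency", GROUP_A): (15.2, 5.0, 0.0),
    ("verbal_fluency", GROUP_B): (14.6, 5.4, 0.0),
    ("verbal_fluency", GROUP_CONTROL): (18.9, 6.0, 0.0),
    ("kavlt_trial5", GROUP_A): (8.8, 2.8, 0.0),
    ("kavlt_trial5", GROUP_B): (10.2, 2.8, 0.0),
    ("kavlt_trial5", GROUP_CONTROL): (11.5, 1.8, 0.0),
}


def _truncated_normal(rng, mean, sd, lower, size):
    out = mean + sd * rng.standard_normal(size)
    if lower is not None:
        out = np.maximum(out, lower)
    return out


def _resolve_affected(
    selector: object, rng: np.random.Generator, R: int
) -> np.ndarray:
    if isinstance(selector, str):
        if selector != "all":
            raise ValidationError(f"affected_regions must be 'all', int or list, got {selector!r}")
        return np.arange(R)
    if isinstance(selector, (int, np.integer)):
        k = int(selector)
        if not 0 <= k <= R:
            raise ValidationError(f"cannot affect {k} of {R} regions")
        return np.sort(rng.choice(R, size=k, replace=False))
    ids = np.asarray(list(selector), dtype=int)
    if ids.size and (ids.min() < 0 or ids.max() >= R):
        raise ValidationError("affected region id out of range")
    return np.sort(np.unique(ids))


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Draw one synthetic cohort under ``config`` (deterministic per seed)."""
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = config.n_regions
    atlas = destrieux_registry() if R == 148 else toy_atlas(R)

    mu = rng.uniform(*config.region_mean_range, size=R)
    sd_mu = mu.std(ddof=1)

    group_sizes = {
        GROUP_A: config.n_per_group[0],
        GROUP_B: config.n_per_group[1],
        GROUP_CONTROL: config.n_per_group[2],
    }
    affected = {
        g: _resolve_affected(config.affected_regions.get(g, []), rng, R)
        for g in group_sizes
    }

    prefixes = {GROUP_A: "sz", GROUP_B: "bd", GROUP_CONTROL: "hc"}
    subjects: list[SubjectRecord] = []
    offsets_rows: list[np.ndarray] = []
    for group, n_g in group_sizes.items():
        dev = float(config.deviation_sd.get(group, 0.0))
        aff = affected[group]
        for s in range(n_g):
            scale = max(0.5, 1.0 + config.subject_scale_sd * rng.standard_normal())
            noise = config.region_noise_sd * np.clip(
                rng.standard_normal(R), -2.5, 2.5
            )
            t = mu * scale + noise
            offsets = np.zeros(R)
            if dev > 0 and aff.size:
                offsets[aff] = (
                    dev * scale * sd_mu * np.clip(rng.standard_normal(aff.size), -2.0, 2.0)
                )
                t = t + offsets
            t = np.maximum(t, 0.2)  # thickness stays physically positive
            covariates = {
                name: float(
                    _truncated_normal(rng, *params, size=None)
                )
                for (name, g), params in _COVARIATE_MODEL.items()
                if g == group
            }
            subjects.append(
                SubjectRecord(
                    subject_id=f"{prefixes[group]}{s + 1:03d}",
                    group=group,
                    thickness=t,
                    covariates=covariates,
                    clinical_scores={},
                )
            )
            offsets_rows.append(offsets)

    cohort = CohortTable(subjects=subjects, atlas=atlas)
    _attach_scores(cohort, config, rng)
    truth = GroundTruth(
        region_means=mu,
        affected_regions=affected,
        deviation_sd={g: float(config.deviation_sd.get(g, 0.0)) for g in group_sizes},
        planted_offsets=np.vstack(offsets_rows),
        score_effect=config.score_effect,
        score_name=config.score_name,
        score_group=config.score_group,
        target_index=config.target_index,
    )
    return SimulatedCohort(cohort=cohort, ground_truth=truth, config=config)


def _target_index_values(cohort: CohortTable, target: str) -> "np.ndarray":
    """Evaluate the named network index for every subject (pipeline path)."""
    from .metrics import GLOBAL_INDEX_NAMES, metrics_tables
    from .network import build_cohort_scns

    matrices, _ = build_cohort_scns(cohort)
    global_df, nodal_df = metrics_tables(matrices)
    kind, _, name = target.partition(":")
    if kind == "global":
        if name not in GLOBAL_INDEX_NAMES:
            raise ValidationError(f"unknown global index {name!r}")
        return global_df[name].to_numpy()
    if kind == "nodal_cc":
        region = cohort.atlas.names[cohort.atlas.index_of(name)]
        return nodal_df[region].to_numpy()
    raise ValidationError(f"unknown target index {target!r}")


def _attach_scores(
    cohort: CohortTable, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Generate clinical scores; the named score tracks the named index."""
    rho = config.score_effect
    target_vals = None
    if rho != 0.0:
        idx_all = _target_index_values(cohort, config.target_index)
        members = [
            i for i, s in enumerate(cohort.subjects) if s.group == config.score_group
        ]
        v = idx_all[members]
        sd = v.std(ddof=1)
        z = (v - v.mean()) / sd if sd > 0 else np.zeros(len(v))
        target_vals = dict(zip(members, z))

    for i, s in enumerate(cohort.subjects):
        for (name, g), (mean, sd, lower) in _SCORE_MODEL.items():
            if g != s.group:
                continue
            noise = rng.standard_normal()
            if (
                target_vals is not None
                and name == config.score_name
                and s.group == config.score_group
            ):
                latent = rho * target_vals[i] + np.sqrt(1 - rho**2) * noise
            else:
                latent = noise
            value = mean + sd * latent
            if lower is not None:
                value = max(value, lower)
            s.clinical_scores[name] = float(value)


def make_worked_fixture() -> SimulatedCohort:
    """A tiny hand-checkable cohort: 5 regions, groups of 3/3/4.

    Synthetic by construction.  Control thickness vectors are chosen so
    the within-subject profiles and the control reference are simple
    numbers; one patient deviates on a single region, so each similarity
    matrix can be verified with a pocket calculator.
    """
    atlas = toy_atlas(5)
    base = np.array([2.0, 2.5, 3.0, 3.5, 4.0])
    subjects = [
        SubjectRecord("sz001", GROUP_A, base + np.array([0.0, 0.3, 0.0, 0.0, 0.0]),
                      {"premorbid_iq": 100.0}, {"panss_positive": 14.0}),
        SubjectRecord("sz002", GROUP_A, base * 1.1,
                      {"premorbid_iq": 102.0}, {"panss_positive": 12.0}),
        SubjectRecord("sz003", GROUP_A, base + np.array([0.2, 0.0, 0.0, -0.2, 0.0]),
                      {"premorbid_iq": 98.0}, {"panss_positive": 16.0}),
        SubjectRecord("bd001", GROUP_B, base + np.array([0.0, 0.0, 0.1, 0.0, 0.0]),
                      {"premorbid_iq": 97.0}, {"ymrs": 6.0}),
        SubjectRecord("bd002", GROUP_B, base * 0.9,
                      {"premorbid_iq": 99.0}, {"ymrs": 4.0}),
        SubjectRecord("bd003", GROUP_B, base + np.array([-0.1, 0.0, 0.0, 0.1, 0.0]),
                      {"premorbid_iq": 96.0}, {"ymrs": 8.0}),
        SubjectRecord("hc001", GROUP_CONTROL, base + np.array([0.0, 0.05, -0.05, 0.1, -0.1]),
                      {"premorbid_iq": 108.0}, {}),
        SubjectRecord("hc002", GROUP_CONTROL, base + np.array([0.1, -0.05, 0.05, -0.1, 0.0]),
                      {"premorbid_iq": 106.0}, {}),
        SubjectRecord("hc003", GROUP_CONTROL, base + np.array([-0.1, 0.1, 0.0, 0.05, -0.05]),
                      {"premorbid_iq": 105.0}, {}),
        SubjectRecord("hc004", GROUP_CONTROL, base + np.array([0.05, -0.1, 0.1, 0.0, 0.05]),
                      {"premorbid_iq": 109.0}, {}),
    ]
    config = SimulationConfig(
        n_per_group=(3, 3, 4),
        n_regions=5,
        deviation_sd={GROUP_A: 0.0, GROUP_B: 0.0, GROUP_CONTROL: 0.0},
        affected_regions={GROUP_A: [], GROUP_B: [], GROUP_CONTROL: []},
        score_effect=0.0,
        seed=0,
    )
    truth = GroundTruth(
        region_means=base,
        affected_regions={g: np.array([], dtype=int) for g in (GROUP_A, GROUP_B, GROUP_CONTROL)},
        deviation_sd={GROUP_A: 0.0, GROUP_B: 0.0, GROUP_CONTROL: 0.0},
        planted_offsets=np.zeros((10, 5)),
        score_effect=0.0,
        score_name="ymrs",
        score_group=GROUP_B,
        target_index=f"nodal_cc:{DEFAULT_TARGET_REGION}",
    )
    return SimulatedCohort(cohort=CohortTable(subjects, atlas), ground_truth=truth, config=config)
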