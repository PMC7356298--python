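"""Construction of individualized structural covariance networks (ISCN).

Edges quantify how similarly two cortical regions deviate from a normative
reference.  The construction is a two-stage normalization followed by an
exponential similarity kernel:

1. *Within-subject* standardization: each subject's regional thickness vector
   is z-scored across their own R regions, removing global thickness scale.
2. *Reference* standardization: each within-subject profile is z-scored
   per region against the control-group distribution of those profiles,
   producing a deviation profile ``n``.
3. Kernel: ``W[i, j] = exp(-(n[i] - n[j])**2)`` for region pairs ``i != j``.

Weights lie in (0, 1]; a pair of regions that deviate identically from the
reference gets weight 1.  The diagonal is set to 0 (self-connections are
excluded from all network indices).  Sample standard deviations use the
``n - 1`` denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import RegionAtlas
from .cohort import CONTROL_GROUP, CohortTable, SubjectRecord
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "WithinSubjectProfile",
    "ReferenceModel",
    "DeviationProfile",
    "SCNMatrix",
    "within_subject_normalize",
    "fit_reference",
    "deviation_profile",
    "build_scn",
    "build_cohort_scns",
]


@dataclass
class WithinSubjectProfile:
    """A subject's thickness standardized across their own regions."""

    subject_id: str
    z: np.ndarray


@dataclass
class ReferenceModel:
    """Per-region mean/SD of within-subject profiles over the control group."""

    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.mu.shape != self.sigma.shape:
            raise ValidationError("reference mu/sigma shape mismatch")
        if self.n_controls < 2:
            raise DegenerateInputError(
                f"reference needs >= 2 controls, got {self.n_controls}"
            )
        if not (self.sigma > 0).all():
            raise DegenerateInputError("reference sigma must be strictly positive")


@dataclass
class DeviationProfile:
    """Region-wise deviation from the normative reference (the kernel input)."""

    subject_id: str
    n: np.ndarray


@dataclass
class SCNMatrix:
    """One subject's symmetric R x R edge-weight matrix."""

    subject_id: str
    weights: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        R = self.atlas.n_regions
        if W.shape != (R, R):
            raise ValidationError(
                f"matrix for {self.subject_id!r} has shape {W.shape}, "
                f"expected ({R}, {R})"
            )
        if not np.array_equal(W, W.T):
            raise ValidationError(f"matrix for {self.subject_id!r} is not symmetric")
        if np.diagonal(W).any():
            raise ValidationError(f"matrix for {self.subject_id!r} has nonzero diagonal")
        if not np.isfinite(W).all() or (W < 0).any() or (W > 1).any():
            raise ValidationError(
                f"matrix for {self.subject_id!r} has weights outside [0, 1]"
            )
        self.weights = W

    @property
    def n_unique_pairs(self) -> int:
        R = self.atlas.n_regions
        return R * (R - 1) // 2


def within_subject_normalize(record: SubjectRecord) -> WithinSubjectProfile:
    """Z-score a subject's thickness across their own regions (sample SD)."""
    t = np.asarray(record.thickness, dtype=float)
    sd = t.std(ddof=1)
    if not sd > 0:
        raise DegenerateInputError(
            f"subject {record.subject_id!r}: constant thickness across regions"
        )
    return WithinSubjectProfile(subject_id=record.subject_id, z=(t - t.mean()) / sd)


def fit_reference(controls: list[WithinSubjectProfile]) -> ReferenceModel:
    """Per-region sample mean/SD of control within-subject profiles."""
    if len(controls) < 2:
        raise DegenerateInputError(
            f"reference fitting needs >= 2 controls, got {len(controls)}"
        )
    Z = np.vstack([p.z for p in controls])
    mu = Z.mean(axis=0)
    sigma = Z.std(axis=0, ddof=1)
    zero = np.flatnonzero(~(sigma > 0))
    if zero.size:
        raise DegenerateInputError(
            f"zero control SD at region index {int(zero[0])}"
        )
    return ReferenceModel(mu=mu, sigma=sigma, n_controls=len(controls))


def deviation_profile(
    profile: WithinSubjectProfile, ref: ReferenceModel
) -> DeviationProfile:
    """Score a profile against the reference: ``n = (z - mu) / sigma``."""
    z = np.asarray(profile.z, dtype=float)
    if z.shape != ref.mu.shape:
        raise ValidationError(
            f"profile length {z.shape} does not match reference {ref.mu.shape}"
        )
    return DeviationProfile(subject_id=profile.subject_id, n=(z - ref.mu) / ref.sigma)


def build_scn(dev: DeviationProfile, atlas: RegionAtlas) -> SCNMatrix:
    """Evaluate the similarity kernel ``exp(-(n_i - n_j)^2)`` for all pairs.

    The matrix is symmetric by construction; the diagonal is zeroed.  Extreme
    deviations (|n_i - n_j| above ~27) underflow to weight 0 and are treated
    as absent edges downstream.
    """
    n = np.asarray(dev.n, dtype=float)
    if n.shape != (atlas.n_regions,):
        raise ValidationError(
            f"deviation profile for {dev.subject_id!r} has length {n.shape}, "
            f"atlas has {atlas.n_regions} regions"
        )
    if not np.isfinite(n).all():
        raise ValidationError(f"non-finite deviation for {dev.subject_id!r}")
    diff = n[:, None] - n[None, :]
    W = np.exp(-(diff * diff))
    np.fill_diagonal(W, 0.0)
    return SCNMatrix(subject_id=dev.subject_id, weights=W, atlas=atlas)


def build_cohort_scns(
    cohort: CohortTable,
    control_group: str = CONTROL_GROUP,
    normalization: str = "two_stage",
    reference_scoring: str = "leave_one_out",
) -> tuple[list[SCNMatrix], ReferenceModel]:
    """Fit the control reference and build one network per subject.

    The returned :class:`ReferenceModel` is always fitted on the full
    control group.  How control subjects themselves are scored is governed
    by ``reference_scoring``:

    ``"leave_one_out"`` (default)
        Each control is scored against a reference refitted on the other
        controls; non-controls are scored against the full reference.  This
        keeps control and patient deviation scales comparable: a control
        scored against a reference containing itself is standardized
        in-sample (its deviations are shrunk relative to an out-of-sample
        subject), which would bias every control-vs-patient comparison even
        in the absence of any group difference.

    ``"in_sample"``
        Every subject, controls included, is scored against the full
        reference.  Control deviations then have per-region mean 0 and
        sample SD 1 exactly.

    ``normalization="single_stage"`` skips the within-subject
    standardization and z-scores raw thickness per region against the
    control raw thickness distribution — provided for sensitivity analysis.
    """
    if normalization not in ("two_stage", "single_stage"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if reference_scoring not in ("leave_one_out", "in_sample"):
        raise ValueError(f"unknown reference_scoring {reference_scoring!r}")
    controls = cohort.select(control_group)
    if not controls:
        raise ValidationError(f"cohort has no {control_group!r} subjects")

    if normalization == "two_stage":
        profiles = {
            s.subject_id: within_subject_normalize(s) for s in cohort.subjects
        }
    else:
        profiles = {
            s.subject_id: WithinSubjectProfile(
                subject_id=s.subject_id,
                z=np.asarray(s.thickness, dtype=float),
            )
            for s in cohort.subjects
        }
    control_profiles = [profiles[s.subject_id] for s in controls]
    ref = fit_reference(control_profiles)
    matrices = []
    for s in cohort.subjects:
        if reference_scoring == "leave_one_out" and s.group == control_group:
            others = [p for p in control_profiles if p.subject_id != s.subject_id]
            subject_ref = fit_reference(others)
        else:
            subject_ref = ref
        matrices.append(
            build_scn(
                deviation_profile(profiles[s.subject_id], subject_ref), cohort.atlas
            )
        )
    return matrices, ref
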