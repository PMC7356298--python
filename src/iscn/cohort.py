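"""Subject-level containers: one participant's morphometry plus metadata.

A :class:`CohortTable` is the unit of work for the whole pipeline: an ordered
collection of :class:`SubjectRecord` sharing one :class:`~iscn.atlas.RegionAtlas`.
Thickness values are mean regional cortical thickness in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .errors import ValidationError

__all__ = ["SubjectRecord", "CohortTable", "COVARIATE_COLUMNS", "CONTROL_GROUP"]

#: Metadata columns interpreted as covariates; any other numeric metadata
#: column is treated as a clinical score.
COVARIATE_COLUMNS = frozenset(
    {"premorbid_iq", "medication_dose", "illness_duration", "age", "education_years"}
)

#: Group label identifying the normative reference group.
CONTROL_GROUP = "control"


@dataclass
class SubjectRecord:
    """One participant: regional thickness vector, group and metadata."""

    subject_id: str
    group: str
    thickness: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)
    clinical_scores: dict[str, float] = field(default_factory=dict)

    def validate(self, atlas: RegionAtlas) -> None:
        t = np.asarray(self.thickness, dtype=float)
        if t.shape != (atlas.n_regions,):
            raise ValidationError(
                f"subject {self.subject_id!r}: thickness has {t.shape} entries, "
                f"expected ({atlas.n_regions},)"
            )
        bad = ~np.isfinite(t) | (t <= 0)
        if bad.any():
            region = atlas.names[int(np.flatnonzero(bad)[0])]
            raise ValidationError(
                f"subject {self.subject_id!r}: non-finite or non-positive "
                f"thickness at region {region!r}"
            )


@dataclass
class CohortTable:
    """Ordered subjects sharing one atlas and region ordering."""

    subjects: list[SubjectRecord]
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate subject_id: {dup!r}")
        counts: dict[str, int] = {}
        for s in self.subjects:
            s.validate(self.atlas)
            counts[s.group] = counts.get(s.group, 0) + 1
        for g, c in counts.items():
            if c < 2:
                raise ValidationError(
                    f"group {g!r} has only {c} subject(s); at least 2 required"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def groups(self) -> list[str]:
        """Group label per subject, in subject order."""
        return [s.group for s in self.subjects]

    def group_order(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def select(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def thickness_matrix(self) -> pd.DataFrame:
        """Subjects x regions thickness table in atlas order (mm)."""
        data = np.vstack([np.asarray(s.thickness, dtype=float) for s in self.subjects])
        return pd.DataFrame(
            data, index=self.subject_ids, columns=list(self.atlas.names)
        )

    def metadata_frame(self) -> pd.DataFrame:
        """Group, covariates and clinical scores, one row per subject."""
        rows = []
        for s in self.subjects:
            row: dict[str, object] = {"group": s.group}
            row.update(s.covariates)
            row.update(s.clinical_scores)
            rows.append(row)
        return pd.DataFrame(rows, index=self.subject_ids)

    def covariate_vector(self, name: str) -> np.ndarray:
        return np.array(
            [float(s.covariates.get(name, np.nan)) for s in self.subjects]
        )

    def score_vector(self, name: str) -> np.ndarray:
        return np.array(
            [float(s.clinical_scores.get(name, np.nan)) for s in self.subjects]
        )
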