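"""Region registry for cortical parcellations.

The default registry is the Destrieux sulco-gyral parcellation: 74 cortical
areas per hemisphere, 148 in total.  Region order is fixed (all left-hemisphere
regions first, then the right hemisphere) and every downstream table, matrix
and metric vector follows that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

__all__ = ["RegionAtlas", "destrieux_registry", "toy_atlas"]

# Destrieux nomenclature, one entry per sulco-gyral area of one hemisphere.
_DESTRIEUX_BASE_NAMES: tuple[str, ...] = (
    "fronto-marginal gyrus and sulcus",
    "inferior occipital gyrus and sulcus",
    "paracentral lobule and sulcus",
    "subcentral gyrus and sulci",
    "transverse frontopolar gyri and sulci",
    "anterior cingulate gyrus and sulcus",
    "middle-anterior cingulate gyrus and sulcus",
    "middle-posterior cingulate gyrus and sulcus",
    "posterior-dorsal cingulate gyrus",
    "posterior-ventral cingulate gyrus",
    "cuneus",
    "opercular part of the inferior frontal gyrus",
    "orbital part of the inferior frontal gyrus",
    "triangular part of the inferior frontal gyrus",
    "middle frontal gyrus",
    "superior frontal gyrus",
    "long insular gyrus and central insular sulcus",
    "short insular gyri",
    "middle occipital gyrus",
    "superior occipital gyrus",
    "lateral occipito-temporal gyrus",
    "lingual gyrus",
    "parahippocampal gyrus",
    "orbital gyri",
    "angular gyrus",
    "supramarginal gyrus",
    "superior parietal lobule",
    "postcentral gyrus",
    "precentral gyrus",
    "precuneus",
    "straight gyrus",
    "subcallosal gyrus",
    "anterior transverse temporal gyrus",
    "lateral superior temporal gyrus",
    "planum polare",
    "planum temporale",
    "inferior temporal gyrus",
    "middle temporal gyrus",
    "horizontal ramus of the anterior lateral sulcus",
    "vertical ramus of the anterior lateral sulcus",
    "posterior ramus of the lateral sulcus",
    "occipital pole",
    "temporal pole",
    "calcarine sulcus",
    "central sulcus",
    "marginal branch of the cingulate sulcus",
    "anterior circular insular sulcus",
    "inferior circular insular sulcus",
    "superior circular insular sulcus",
    "anterior transverse collateral sulcus",
    "posterior transverse collateral sulcus",
    "inferior frontal sulcus",
    "middle frontal sulcus",
    "superior frontal sulcus",
    "sulcus intermedius primus",
    "intraparietal and transverse parietal sulci",
    "middle occipital and lunate sulci",
    "superior occipital and transverse occipital sulci",
    "anterior occipital sulcus",
    "lateral occipito-temporal sulcus",
    "medial occipito-temporal and lingual sulci",
    "lateral orbital sulcus",
    "medial orbital sulcus",
    "orbital sulci",
    "parieto-occipital sulcus",
    "pericallosal sulcus",
    "postcentral sulcus",
    "inferior precentral sulcus",
    "superior precentral sulcus",
    "suborbital sulcus",
    "subparietal sulcus",
    "inferior temporal sulcus",
    "superior temporal sulcus",
    "transverse temporal sulcus",
)


def _canon(name: str) -> str:
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered set of named cortical regions with hemisphere labels.

    Parameters
    ----------
    names
        Full region names, unique after whitespace-trimming and case-folding.
    hemispheres
        One of ``"left"``/``"right"`` per region, aligned with ``names``.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    _lookup: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise SchemaError(
                f"{len(self.names)} region names but "
                f"{len(self.hemispheres)} hemisphere labels"
            )
        bad = sorted({h for h in self.hemispheres} - {"left", "right"})
        if bad:
            raise SchemaError(f"unknown hemisphere labels: {bad}")
        lookup = {}
        for idx, name in enumerate(self.names):
            key = _canon(name)
            if key in lookup:
                raise SchemaError(f"duplicate region name: {name!r}")
            lookup[key] = idx
        object.__setattr__(self, "_lookup", lookup)

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        """Return the region id for ``name`` (whitespace/case-insensitive)."""
        key = _canon(name)
        if key not in self._lookup:
            raise KeyError(f"region {name!r} not in atlas")
        return self._lookup[key]

    def __contains__(self, name: str) -> bool:
        return _canon(name) in self._lookup

    def __len__(self) -> int:
        return len(self.names)

    def hemisphere_counts(self) -> dict[str, int]:
        counts = {"left": 0, "right": 0}
        for h in self.hemispheres:
            counts[h] += 1
        return counts

    def match_columns(self, columns: list[str]) -> list[int]:
        """Map a header of region columns onto atlas ids.

        Requires exactly one column per atlas region (any order); raises
        :class:`SchemaError` naming the first missing or unknown column.
        """
        seen: dict[int, str] = {}
        ids = []
        for col in columns:
            key = _canon(col)
            if key not in self._lookup:
                raise SchemaError(f"unknown region column: {col!r}")
            idx = self._lookup[key]
            if idx in seen:
                raise SchemaError(f"duplicate region column: {col!r}")
            seen[idx] = col
            ids.append(idx)
        if len(ids) != self.n_regions:
            missing = [n for i, n in enumerate(self.names) if i not in seen]
            raise SchemaError(f"missing region column: {missing[0]!r}")
        return ids


def destrieux_registry() -> RegionAtlas:
    """The 148-region Destrieux registry, left hemisphere first."""
    names = tuple(
        f"{hemi} {base}"
        for hemi in ("left", "right")
        for base in _DESTRIEUX_BASE_NAMES
    )
    hemis = ("left",) * len(_DESTRIEUX_BASE_NAMES) + ("right",) * len(
        _DESTRIEUX_BASE_NAMES
    )
    return RegionAtlas(names=names, hemispheres=hemis)


def toy_atlas(n_regions: int) -> RegionAtlas:
    """A small synthetic atlas for demonstrations and tests.

    Regions alternate hemispheres so both labels appear whenever
    ``n_regions >= 2``.
    """
    if n_regions < 1:
        raise SchemaError("toy atlas needs at least one region")
    names = tuple(
        f"{'left' if i % 2 == 0 else 'right'} toy region {i:03d}"
        for i in range(n_regions)
    )
    hemis = tuple("left" if i % 2 == 0 else "right" for i in range(n_regions))
    return RegionAtlas(names=names, hemispheres=hemis)
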