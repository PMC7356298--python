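"""Tab-separated I/O for cohorts, matrices, reference models and results.

File dialect: TSV, UTF-8, ``.`` decimal separator, mandatory header rows.
Floats are written with 17 significant digits so read(write(x)) round-trips
bit-for-bit.  Region-name matching is exact after whitespace trimming and
case-folding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cohort import COVARIATE_COLUMNS, CohortTable, SubjectRecord
from .errors import SchemaError, ValidationError
from .network import ReferenceModel, SCNMatrix

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_matrix",
    "write_matrix",
    "read_reference",
    "write_reference",
    "write_comparison_table",
    "write_correlation_table",
]

_FLOAT_FMT = "%.17g"


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # malformed file
        raise SchemaError(f"cannot parse {path}: {exc}") from exc


def read_cohort(
    thickness_path: str | Path,
    metadata_path: str | Path,
    atlas: RegionAtlas,
) -> CohortTable:
    """Load a cohort from a thickness TSV and a metadata TSV.

    The thickness file has one row per subject: ``subject_id`` followed by
    one column per atlas region (any column order; re-ordered to atlas
    order).  The metadata file is keyed by ``subject_id`` with a ``group``
    column; known covariate columns become covariates, all other numeric
    columns become clinical scores.  Subjects are returned in thickness-file
    order; every thickness subject must appear in the metadata.
    """
    tdf = _read_tsv(thickness_path)
    if tdf.columns[0] != "subject_id":
        raise SchemaError(
            f"first thickness column must be 'subject_id', got {tdf.columns[0]!r}"
        )
    region_cols = list(tdf.columns[1:])
    ids = atlas.match_columns(region_cols)
    order = np.argsort(ids)  # permutation mapping file columns -> atlas order
    ordered_cols = [region_cols[int(i)] for i in order]

    mdf = _read_tsv(metadata_path)
    if "subject_id" not in mdf.columns or "group" not in mdf.columns:
        raise SchemaError("metadata needs 'subject_id' and 'group' columns")
    if mdf["subject_id"].duplicated().any():
        dup = mdf.loc[mdf["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"duplicate metadata subject_id: {dup!r}")
    meta = mdf.set_index("subject_id")
    extra_cols = [c for c in mdf.columns if c not in ("subject_id", "group")]

    subjects = []
    for _, row in tdf.iterrows():
        sid = str(row["subject_id"])
        if sid not in meta.index:
            raise ValidationError(f"subject {sid!r} missing from metadata")
        values = np.empty(atlas.n_regions)
        for j, col in enumerate(ordered_cols):
            raw = row[col]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"subject {sid!r}, region {col!r}: non-numeric thickness {raw!r}"
                ) from None
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"subject {sid!r}, region {col!r}: non-positive thickness {v}"
                )
            values[j] = v
        covariates: dict[str, float] = {}
        scores: dict[str, float] = {}
        for col in extra_cols:
            raw = meta.loc[sid, col]
            if pd.isna(raw) or raw == "":
                continue  # score/covariate not collected for this subject
            try:
                val = float(raw)
            except (TypeError, ValueError):
                continue  # non-numeric annotation column
            (covariates if col in COVARIATE_COLUMNS else scores)[col] = val
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(meta.loc[sid, "group"]),
                thickness=values,
                covariates=covariates,
                clinical_scores=scores,
            )
        )
    return CohortTable(subjects=subjects, atlas=atlas)


def write_cohort(
    cohort: CohortTable,
    thickness_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the thickness and metadata TSVs read back by :func:`read_cohort`."""
    tdf = cohort.thickness_matrix()
    tdf.index.name = "subject_id"
    tdf.to_csv(thickness_path, sep="\t", float_format=_FLOAT_FMT)
    mdf = cohort.metadata_frame()
    mdf.index.name = "subject_id"
    mdf.to_csv(metadata_path, sep="\t", float_format=_FLOAT_FMT)


def write_matrix(matrix: SCNMatrix, path: str | Path) -> None:
    """Write one subject's edge-weight matrix with region-name header/column."""
    df = pd.DataFrame(
        matrix.weights,
        index=list(matrix.atlas.names),
        columns=list(matrix.atlas.names),
    )
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path, atlas: RegionAtlas, subject_id: str = "") -> SCNMatrix:
    """Read a matrix TSV; validates shape, symmetry and the zero diagonal."""
    df = _read_tsv(path)
    if df.shape[0] != atlas.n_regions or df.shape[1] != atlas.n_regions + 1:
        raise SchemaError(
            f"matrix in {path} has shape {(df.shape[0], df.shape[1] - 1)}, "
            f"atlas expects ({atlas.n_regions}, {atlas.n_regions})"
        )
    col_ids = np.asarray(atlas.match_columns(list(df.columns[1:])))
    row_ids = np.asarray(atlas.match_columns(df.iloc[:, 0].tolist()))
    try:
        W = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric weight in {path}: {exc}") from exc
    # permute file order back to atlas order
    out = np.empty_like(W)
    out[np.ix_(row_ids, col_ids)] = W
    sid = subject_id or Path(path).stem
    return SCNMatrix(subject_id=sid, weights=out, atlas=atlas)


def write_reference(ref: ReferenceModel, atlas: RegionAtlas, path: str | Path) -> None:
    df = pd.DataFrame(
        {"region": list(atlas.names), "mu": ref.mu, "sigma": ref.sigma}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n_controls\t{ref.n_controls}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_reference(path: str | Path, atlas: RegionAtlas) -> ReferenceModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        if len(header) != 2 or header[0] != "# n_controls":
            raise SchemaError(f"missing n_controls header in {path}")
        n_controls = int(header[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    atlas.match_columns(df["region"].tolist())
    return ReferenceModel(
        mu=df["mu"].to_numpy(dtype=float),
        sigma=df["sigma"].to_numpy(dtype=float),
        n_controls=n_controls,
    )


def write_comparison_table(results, path: str | Path) -> None:
    """Emit GroupComparisonResults as a TSV (one row per index/region)."""
    rows = []
    for r in results:
        row = {
            "index": r.index_name,
            "F": r.F,
            "df1": r.df[0],
            "df2": r.df[1],
            "p_raw": r.p_raw,
            "p_fdr": r.p_fdr,
            "partial_eta_squared": r.partial_eta_squared,
        }
        for ph in r.posthoc:
            tag = f"{ph.pair[0]}_vs_{ph.pair[1]}"
            row[f"diff_{tag}"] = ph.mean_difference
            row[f"p_{tag}"] = ph.p
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_correlation_table(results, path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "index": r.var_x,
                "score": r.var_y,
                "covariates": ",".join(r.covariates),
                "n": r.n,
                "r": r.r,
                "p_parametric": r.p_parametric,
                "p_bootstrap": r.p_bootstrap,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_boot": r.n_boot,
                "n_redrawn": r.n_redrawn,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
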