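"""Readers and writers for matrix exports, images, manifests and results.

FLIO matrices travel as plain-text TSV/CSV (one row of the image per
line, row 0 at the top); OCT-A slabs as 8-bit grayscale PNG/TIFF; the
cohort manifest as a CSV with one row per (subject, eye) sample; feature
tables as CSV; cross-validation results as JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .model import (
    CANONICAL_SLABS,
    CHANNELS,
    CohortDataset,
    CvResult,
    FeatureTable,
    FlioMeasurement,
    OctaSlabStack,
    SubjectRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_slab_image",
    "write_slab_image",
    "read_feature_table",
    "write_feature_table",
    "save_cv_result",
    "load_cv_result",
    "load_cohort",
    "MANIFEST_META_COLUMNS",
    "flio_path_columns",
    "octa_path_column",
]

_DELIMITERS = ("\t", ",", ";")


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=lambda d: counts[d])
    return best if counts[best] > 0 else "\t"


def read_matrix(path, expected_shape: tuple[int, int] | None = (256, 256)) -> np.ndarray:
    """Read a numeric matrix from TSV/CSV with delimiter auto-detection.

    Non-numeric or empty cells become NaN.  Ragged rows are fatal; a shape
    other than ``expected_shape`` is fatal unless ``expected_shape`` is None.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    width = None
    for i, ln in enumerate(lines):
        cells = ln.split(delim)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {i} (expected {width} cells, got {len(cells)})"
            )
        row = np.empty(width)
        for j, cell in enumerate(cells):
            try:
                row[j] = float(cell)
            except ValueError:
                row[j] = np.nan
        rows.append(row)
    matrix = np.vstack(rows)
    if expected_shape is not None and matrix.shape != tuple(expected_shape):
        raise ValueError(
            f"{path}: matrix shape {matrix.shape} != expected {tuple(expected_shape)}"
        )
    return matrix


def write_matrix(matrix: np.ndarray, path, delimiter: str = "\t") -> Path:
    """Write a matrix as delimited text with full float precision."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g", delimiter=delimiter)
    return path


def read_slab_image(path) -> np.ndarray:
    """Read an 8-bit grayscale slab image (PNG/TIFF)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    return arr


def write_slab_image(image: np.ndarray, path) -> Path:
    path = Path(path)
    arr = np.asarray(image)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("slab image values must lie in [0, 255]")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
    return path


def write_feature_table(table: FeatureTable, path) -> Path:
    """Serialize a feature table to CSV (metadata columns then features)."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path, expected_features: list[str] | None = None) -> FeatureTable:
    """Read a feature table CSV written by :func:`write_feature_table`.

    If ``expected_features`` is given, any unknown feature column is fatal.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str, "eye": str, "label": str})
    table = FeatureTable.from_frame(frame)
    if expected_features is not None:
        unknown = [c for c in table.feature_names if c not in expected_features]
        if unknown:
            raise ValueError(f"{path}: unknown feature columns {unknown}")
    return table


def save_cv_result(result: CvResult, path, extra_config: Mapping | None = None) -> Path:
    """Write a cross-validation result (and its run configuration) as JSON."""
    path = Path(path)
    payload = result.to_dict()
    if extra_config:
        payload["config"] = {**payload.get("config", {}), **dict(extra_config)}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_cv_result(path) -> CvResult:
    return CvResult.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_META_COLUMNS = (
    "subject_id",
    "eye",
    "age",
    "sex",
    "years_smoked",
    "cumulative_packs",
)


def flio_path_columns() -> list[str]:
    return [f"{kind}_{ch.lower()}_path" for kind in ("tau", "intensity") for ch in CHANNELS]


def octa_path_column(slab: str) -> str:
    return "octa_" + slab.replace(" ", "_") + "_path"


_SLAB_BY_COLUMN = {octa_path_column(s): s for s in CANONICAL_SLABS}


def _resolve(cell, data_dir: Path) -> Path | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
        return None
    p = Path(str(cell))
    return p if p.is_absolute() else data_dir / p


def load_cohort(
    manifest_path,
    data_dir=None,
    flio_shape: tuple[int, int] | None = None,
    octa_shape: tuple[int, int] | None = None,
) -> CohortDataset:
    """Load a cohort from a manifest CSV referencing matrix and image files.

    One manifest row per (subject, eye).  FLIO requires all four matrix
    paths on a row; OCT-A slab columns are independently optional.  Matrix
    and slab shapes default to those of the first loaded sample and must
    be consistent across the cohort.  Missing files, duplicate samples and
    shape mismatches are fatal; smoking status is derived from history.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    frame = pd.read_csv(manifest_path, dtype={"subject_id": str, "eye": str, "sex": str})
    missing_meta = [c for c in MANIFEST_META_COLUMNS if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"{manifest_path}: manifest missing columns {missing_meta}")

    subjects: dict[str, SubjectRecord] = {}
    flio: list[FlioMeasurement] = []
    octa: list[OctaSlabStack] = []
    seen_rows: set[tuple[str, str]] = set()
    n_rows = 0

    for _, row in frame.iterrows():
        n_rows += 1
        sid, eye = str(row["subject_id"]), str(row["eye"])
        if (sid, eye) in seen_rows:
            raise ValueError(f"{manifest_path}: duplicate sample row {(sid, eye)}")
        seen_rows.add((sid, eye))
        rec = SubjectRecord(
            subject_id=sid,
            age=float(row["age"]),
            sex=str(row["sex"]),
            years_smoked=float(row["years_smoked"]),
            cumulative_packs=float(row["cumulative_packs"]),
        )
        if sid in subjects and subjects[sid] != rec:
            raise ValueError(f"{manifest_path}: inconsistent metadata for subject {sid}")
        subjects[sid] = rec

        flio_cols = [c for c in flio_path_columns() if c in frame.columns]
        paths = {c: _resolve(row.get(c), data_dir) for c in flio_cols}
        present = [c for c, p in paths.items() if p is not None]
        if present:
            if len(present) != 4:
                raise ValueError(
                    f"sample {sid}/{eye}: FLIO requires all four matrices, "
                    f"found only {present}"
                )
            mats = {}
            for c in flio_path_columns():
                p = paths[c]
                if not p.exists():
                    raise FileNotFoundError(f"sample {sid}/{eye}: missing file {p}")
                mats[c] = read_matrix(p, expected_shape=flio_shape)
                if flio_shape is None:
                    flio_shape = mats[c].shape
            flio.append(
                FlioMeasurement(
                    subject_id=sid,
                    eye=eye,
                    tau_m={ch: mats[f"tau_{ch.lower()}_path"] for ch in CHANNELS},
                    intensity={
                        ch: mats[f"intensity_{ch.lower()}_path"] for ch in CHANNELS
                    },
                )
            )

        slabs = {}
        for col, slab in _SLAB_BY_COLUMN.items():
            if col not in frame.columns:
                continue
            p = _resolve(row.get(col), data_dir)
            if p is None:
                continue
            if not p.exists():
                raise FileNotFoundError(f"sample {sid}/{eye}: missing file {p}")
            img = read_slab_image(p)
            if octa_shape is None:
                octa_shape = img.shape
            elif img.shape != tuple(octa_shape):
                raise ValueError(
                    f"sample {sid}/{eye}: slab {slab!r} shape {img.shape} != "
                    f"declared {tuple(octa_shape)}"
                )
            slabs[slab] = img
        if slabs:
            octa.append(
                OctaSlabStack(
                    subject_id=sid, eye=eye, slabs=slabs, image_shape=tuple(octa_shape)
                )
            )

    cohort = CohortDataset(subjects=list(subjects.values()), flio=flio, octa=octa)
    logger.info(
        "loaded cohort: %d manifest rows -> %d subjects, %d FLIO, %d OCT-A samples",
        n_rows,
        len(cohort.subjects),
        len(cohort.flio),
        len(cohort.octa),
    )
    return cohort
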