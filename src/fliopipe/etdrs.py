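"""ETDRS grid geometry and FLIO feature extraction.

The macular ETDRS grid is a central disc of 1 mm diameter (C), an inner
ring out to 3 mm and an outer ring out to 6 mm, with each ring split into
nasal (N), superior (S), temporal (T) and inferior (I) quadrants along the
+/-45 degree diagonals.  Applied to a 30-degree 256x256 lifetime matrix
with the standard emmetropic conversion of 0.3 mm per degree, the ring
radii are 0.5 / 1.5 / 3.0 mm = 14.2 / 42.7 / 85.3 pixels around the image
center (the fixation target, taken as the fovea).

A FLIO measurement is summarized by the missing-aware mean of each of its
four matrices over the nine sectors: 2 quantities (tau_m, intensity) x 2
spectral channels (SSC, LSC) x 9 sectors = 36 named features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CHANNELS, FeatureTable, FlioMeasurement

__all__ = [
    "SECTORS",
    "FEATURE_NAMES",
    "GridGeometry",
    "SectorMasks",
    "build_masks",
    "sector_mean",
    "extract_features",
    "build_feature_table",
    "SUBSETS",
    "subset_columns",
    "select_subset",
    "TTestResult",
    "ttest_rank",
]

#: Canonical sector order: center, then inner ring N/S/T/I, then outer ring.
SECTORS = ("C", "N1", "S1", "T1", "I1", "N2", "S2", "T2", "I2")

#: Canonical 36-feature order: quantity-major, then channel, then sector.
FEATURE_NAMES = tuple(
    f"{kind}_{ch}_{sec}"
    for kind in ("tau_m", "intensity")
    for ch in CHANNELS
    for sec in SECTORS
)


@dataclass(frozen=True)
class GridGeometry:
    """Pixel geometry of the circular sector grid on a fundus image.

    ``mm_per_degree`` is the standard emmetropic fundus approximation
    (30 degrees of field span about 9 mm of retina); it is a configuration
    field, not a constant of the method.
    """

    image_shape: tuple[int, int] = (256, 256)
    field_of_view_deg: float = 30.0
    mm_per_degree: float = 0.3
    center: tuple[float, float] | None = None  # (row, col); image center if None
    ring_diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0)
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        d = self.ring_diameters_mm
        if not (0 < d[0] < d[1] < d[2]):
            raise ValueError("ring diameters must be strictly increasing")
        if self.image_shape[0] != self.image_shape[1]:
            raise ValueError("grid geometry requires a square image")
        if self.outer_radius_px > min(self.image_shape) / 2:
            raise ValueError(
                f"outer ring radius {self.outer_radius_px:.1f} px exceeds half "
                f"the image extent {min(self.image_shape) / 2:.1f} px"
            )

    @property
    def mm_per_pixel(self) -> float:
        extent_mm = self.field_of_view_deg * self.mm_per_degree
        return extent_mm / self.image_shape[0]

    @property
    def center_px(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        n = self.image_shape
        return ((n[0] - 1) / 2.0, (n[1] - 1) / 2.0)

    @property
    def ring_radii_mm(self) -> tuple[float, float, float]:
        d = self.ring_diameters_mm
        return (d[0] / 2.0, d[1] / 2.0, d[2] / 2.0)

    @property
    def outer_radius_px(self) -> float:
        return self.ring_radii_mm[2] / self.mm_per_pixel

    def radius_mm(self) -> np.ndarray:
        """Per-pixel Euclidean distance from the grid center, in mm."""
        cy, cx = self.center_px
        rows = np.arange(self.image_shape[0])[:, None] - cy
        cols = np.arange(self.image_shape[1])[None, :] - cx
        return np.hypot(rows, cols) * self.mm_per_pixel


@dataclass
class SectorMasks:
    """Nine pairwise-disjoint boolean masks keyed by sector name."""

    masks: dict[str, np.ndarray]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if set(self.masks) != set(SECTORS):
            raise ValueError(f"masks must have exactly keys {SECTORS}")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.masks[key]

    def label_image(self) -> np.ndarray:
        """Integer label image (0 = outside grid, 1..9 = sector order)."""
        out = np.zeros(self.geometry.image_shape, dtype=np.uint8)
        for i, sec in enumerate(SECTORS, start=1):
            out[self.masks[sec]] = i
        return out


def build_masks(geometry: GridGeometry) -> SectorMasks:
    """Partition the grid disc into the nine ETDRS sectors.

    Ring membership uses half-open radius intervals (lo, hi] in mm.
    Quadrants split along the +/-45 degree diagonals: superior is up,
    inferior is down, and the horizontal pair maps to temporal/nasal by
    laterality (OD: temporal on the image left; OS mirrored).  Pixels on
    an exact diagonal go to the vertical quadrant (S or I), a tie-break
    that is symmetric under horizontal mirroring.
    """
    cy, cx = geometry.center_px
    r_mm = geometry.radius_mm()
    r_c, r_ir, r_or = geometry.ring_radii_mm

    dy = cy - np.arange(geometry.image_shape[0])[:, None]  # up positive
    dx = np.arange(geometry.image_shape[1])[None, :] - cx  # right positive
    dy = np.broadcast_to(dy, geometry.image_shape)
    dx = np.broadcast_to(dx, geometry.image_shape)

    vertical = np.abs(dy) >= np.abs(dx)  # ties to S/I
    up = vertical & (dy > 0)
    down = vertical & (dy <= 0)
    left = ~vertical & (dx < 0)
    right = ~vertical & (dx > 0)

    if geometry.laterality == "OD":
        temporal, nasal = left, right
    else:
        temporal, nasal = right, left

    center = r_mm <= r_c
    inner = (r_mm > r_c) & (r_mm <= r_ir)
    outer = (r_mm > r_ir) & (r_mm <= r_or)

    masks = {
        "C": center,
        "N1": inner & nasal,
        "S1": inner & up,
        "T1": inner & temporal,
        "I1": inner & down,
        "N2": outer & nasal,
        "S2": outer & up,
        "T2": outer & temporal,
        "I2": outer & down,
    }
    return SectorMasks(masks={k: v.copy() for k, v in masks.items()}, geometry=geometry)


def sector_mean(matrix: np.ndarray, masks: SectorMasks) -> dict[str, float]:
    """Missing-aware mean of ``matrix`` over each sector.

    NaN pixels are excluded; a sector with no valid pixel yields NaN.
    """
    if matrix.shape != masks.geometry.image_shape:
        raise ValueError(
            f"matrix shape {matrix.shape} does not match mask shape "
            f"{masks.geometry.image_shape}"
        )
    out: dict[str, float] = {}
    for sec in SECTORS:
        vals = matrix[masks[sec]]
        valid = vals[np.isfinite(vals)]
        out[sec] = float(valid.mean()) if valid.size else math.nan
    return out


def extract_features(
    measurement: FlioMeasurement, geometry: GridGeometry | None = None
) -> pd.Series:
    """The 36 named sector means of one FLIO measurement, canonical order.

    Laterality for nasal/temporal orientation is taken from the
    measurement's eye; any explicitly passed geometry must agree.
    """
    if geometry is None:
        geometry = GridGeometry(
            image_shape=measurement.shape, laterality=measurement.eye
        )
    elif geometry.laterality != measurement.eye:
        geometry = replace(geometry, laterality=measurement.eye)
    masks = build_masks(geometry)
    values: dict[str, float] = {}
    for kind, matrices in (("tau_m", measurement.tau_m), ("intensity", measurement.intensity)):
        for ch in CHANNELS:
            means = sector_mean(matrices[ch], masks)
            for sec in SECTORS:
                values[f"{kind}_{ch}_{sec}"] = means[sec]
    return pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))


def build_feature_table(cohort, geometry: GridGeometry | None = None) -> FeatureTable:
    """Extract the 36-feature vector for every FLIO sample of a cohort."""
    status = cohort.status_by_subject
    rows, sids, eyes, labels = [], [], [], []
    for m in cohort.flio:
        rows.append(extract_features(m, geometry))
        sids.append(m.subject_id)
        eyes.append(m.eye)
        labels.append(status[m.subject_id])
    feats = pd.DataFrame(rows).reset_index(drop=True) if rows else pd.DataFrame(
        columns=list(FEATURE_NAMES)
    )
    return FeatureTable(subject_ids=sids, eyes=eyes, labels=labels, features=feats)


_RING_INNER = ("N1", "S1", "T1", "I1")
_RING_OUTER = ("N2", "S2", "T2", "I2")


def _names(kind: str, channels: Sequence[str], sectors: Sequence[str]) -> list[str]:
    return [f"{kind}_{ch}_{sec}" for ch in channels for sec in sectors]


#: Named feature subsets used in the classification experiments.  Ring
#: subsets exclude the central disc (4 sectors x 2 channels = 8 features).
SUBSETS: dict[str, list[str] | None] = {
    "all": list(FEATURE_NAMES),
    "intensity": _names("intensity", CHANNELS, SECTORS),
    "tau_m": _names("tau_m", CHANNELS, SECTORS),
    "tau_ssc": _names("tau_m", ["SSC"], SECTORS),
    "tau_lsc": _names("tau_m", ["LSC"], SECTORS),
    "tau_ir": _names("tau_m", CHANNELS, _RING_INNER),
    "tau_or": _names("tau_m", CHANNELS, _RING_OUTER),
    "tau_ir_ssc_or_lsc": _names("tau_m", ["SSC"], _RING_INNER)
    + _names("tau_m", ["LSC"], _RING_OUTER),
    "tau_or_ssc_ir_lsc": _names("tau_m", ["SSC"], _RING_OUTER)
    + _names("tau_m", ["LSC"], _RING_INNER),
    "ttest_top3": None,  # data-dependent: top 3 of the 18 tau_m features
}


def subset_columns(
    name: str,
    table: FeatureTable | None = None,
    binary_labels: np.ndarray | None = None,
) -> list[str]:
    """Resolve a subset name to feature column names.

    ``ttest_top3`` ranks the 18 lifetime features by two-sample t-test
    p-value on the given labels and keeps the three most significant; it
    therefore requires ``table`` and ``binary_labels``.
    """
    if name not in SUBSETS:
        raise KeyError(
            f"unknown feature subset {name!r}; valid names: {sorted(SUBSETS)}"
        )
    cols = SUBSETS[name]
    if cols is not None:
        return list(cols)
    if table is None or binary_labels is None:
        raise ValueError("subset 'ttest_top3' needs a table and binary labels")
    tau = table.select_columns(SUBSETS["tau_m"])
    ranked = ttest_rank(tau, binary_labels)
    return [r.feature for r in ranked[:3]]


def select_subset(
    table: FeatureTable,
    name: str,
    binary_labels: np.ndarray | None = None,
) -> FeatureTable:
    """Column-filter a feature table to a named subset.

    For ``ttest_top3`` the selection is computed on the rows of ``table``
    itself (a whole-dataset selection; leakage-safe per-fold selection is
    handled inside the cross-validation loop).
    """
    if name == "ttest_top3" and binary_labels is None:
        binary_labels = table.binary_labels("smoker")
    cols = subset_columns(name, table, binary_labels)
    return table.select_columns(cols)


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test summary for one feature."""

    feature: str
    t: float
    p: float
    mean_a: float
    mean_b: float
    pooled_sd: float


def ttest_rank(
    table: FeatureTable | pd.DataFrame,
    binary_labels: np.ndarray,
) -> list[TTestResult]:
    """Rank features by two-sample t-test significance between two groups.

    Classic pooled-variance (equal-variance) Student t per feature,
    two-sided p from the t distribution with n1 + n2 - 2 df.  Sorted by
    p ascending; ties broken by |t| descending, then canonical column
    order.  Group A is label 0, group B label 1 (t = (mean_A - mean_B) / SE).
    """
    feats = table.features if isinstance(table, FeatureTable) else table
    y = np.asarray(binary_labels)
    if feats.shape[0] != y.size:
        raise ValueError("labels length does not match table rows")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("exactly two classes (0 and 1) are required")
    a = feats.loc[y == 0]
    b = feats.loc[y == 1]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 rows for a t-test")

    results = []
    for order, col in enumerate(feats.columns):
        xa, xb = a[col].to_numpy(float), b[col].to_numpy(float)
        t, p = stats.ttest_ind(xa, xb, equal_var=True)
        n1, n2 = xa.size, xb.size
        sp2 = ((n1 - 1) * xa.var(ddof=1) + (n2 - 1) * xb.var(ddof=1)) / (n1 + n2 - 2)
        if t != t:  # zero pooled variance: identical constant groups
            t, p = 0.0, 1.0
        results.append(
            (
                float(p),
                -abs(float(t)),
                order,
                TTestResult(
                    feature=str(col),
                    t=float(t),
                    p=float(p),
                    mean_a=float(xa.mean()),
                    mean_b=float(xb.mean()),
                    pooled_sd=float(np.sqrt(sp2)),
                ),
            )
        )
    results.sort(key=lambda r: r[:3])
    return [r[3] for r in results]
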