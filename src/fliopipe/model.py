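"""Domain types shared by every stage of the pipeline.

The unit of analysis is one eye of one subject.  A FLIO measurement of an
eye consists of four 256x256 matrices: the amplitude-weighted mean
fluorescence lifetime (tau_m, picoseconds) and the photon-count intensity,
each recorded in a short (SSC, 498-560 nm) and a long (560-720 nm, LSC)
spectral channel.  OCT angiography contributes en-face slab images (8-bit
grayscale) at up to 15 named segmentations.  Subjects carry smoking
metadata; the class of interest is smoking status, with heavy smokers
defined by a cumulative lifetime consumption strictly above 2500 packs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "EYES",
    "CANONICAL_SLABS",
    "SMOKING_STATUSES",
    "HEAVY_PACK_THRESHOLD",
    "smoking_status_from_history",
    "SubjectRecord",
    "FlioMeasurement",
    "OctaSlabStack",
    "CohortDataset",
    "FeatureTable",
    "CvResult",
]

CHANNELS = ("SSC", "LSC")
EYES = ("OD", "OS")

#: The 15 canonical en-face segmentation slab names exported by the OCT-A device.
CANONICAL_SLABS = (
    "Full",
    "Vitreoretinal interface",
    "Retina",
    "SVC",
    "NFLVP",
    "SVP",
    "DVC",
    "ICP",
    "DCP",
    "Avascular complex",
    "CC",
    "Choroid",
    "HL",
    "ILMtoBM40",
    "SL",
)

SMOKING_STATUSES = ("non_smoker", "light_smoker", "heavy_smoker")

#: Cumulative lifetime packs strictly above this count make a heavy smoker.
HEAVY_PACK_THRESHOLD = 2500.0

#: Plausibility bounds for fitted mean fluorescence lifetimes, picoseconds.
TAU_BOUNDS_PS = (0.0, 5000.0)


def smoking_status_from_history(years_smoked: float, cumulative_packs: float) -> str:
    """Derive the smoking-status class from exposure history.

    Non-smokers have zero exposure on both axes; among smokers, the
    heavy/light split is strictly above 2500 cumulative packs.
    """
    if years_smoked < 0 or cumulative_packs < 0:
        raise ValueError("years_smoked and cumulative_packs must be non-negative")
    if years_smoked == 0 and cumulative_packs == 0:
        return "non_smoker"
    if cumulative_packs > HEAVY_PACK_THRESHOLD:
        return "heavy_smoker"
    return "light_smoker"


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant with smoking metadata."""

    subject_id: str
    age: float
    sex: str
    years_smoked: float
    cumulative_packs: float
    smoking_status: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        derived = smoking_status_from_history(self.years_smoked, self.cumulative_packs)
        if not self.smoking_status:
            object.__setattr__(self, "smoking_status", derived)
        elif self.smoking_status != derived:
            raise ValueError(
                f"subject {self.subject_id}: declared status {self.smoking_status!r} "
                f"inconsistent with history (derived {derived!r})"
            )

    @property
    def is_smoker(self) -> bool:
        return self.smoking_status != "non_smoker"


def _check_matrix_map(name: str, matrices: Mapping[str, np.ndarray], sid: str) -> None:
    if set(matrices) != set(CHANNELS):
        raise ValueError(f"{sid}: {name} must have exactly channels {CHANNELS}")
    shapes = {m.shape for m in matrices.values()}
    if len(shapes) != 1:
        raise ValueError(f"{sid}: {name} channel matrices have differing shapes")
    (shape,) = shapes
    if len(shape) != 2 or shape[0] != shape[1]:
        raise ValueError(f"{sid}: {name} matrices must be square 2-D, got {shape}")


@dataclass
class FlioMeasurement:
    """One eye's FLIO export: tau_m and intensity per spectral channel.

    Invalid (unfitted) pixels are NaN; finite tau_m values must lie inside
    the physical range (0, 5000) ps and intensities must be non-negative.
    """

    subject_id: str
    eye: str
    tau_m: dict[str, np.ndarray]
    intensity: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        sid = f"{self.subject_id}/{self.eye}"
        _check_matrix_map("tau_m", self.tau_m, sid)
        _check_matrix_map("intensity", self.intensity, sid)
        if self.tau_m[CHANNELS[0]].shape != self.intensity[CHANNELS[0]].shape:
            raise ValueError(f"{sid}: tau_m and intensity shapes differ")
        lo, hi = TAU_BOUNDS_PS
        for ch, m in self.tau_m.items():
            finite = m[np.isfinite(m)]
            if finite.size and (finite.min() <= lo or finite.max() >= hi):
                raise ValueError(
                    f"{sid}: tau_m[{ch}] has values outside ({lo}, {hi}) ps"
                )
        for ch, m in self.intensity.items():
            finite = m[np.isfinite(m)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"{sid}: intensity[{ch}] has negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau_m[CHANNELS[0]].shape


@dataclass
class OctaSlabStack:
    """One eye's OCT-A en-face slabs: 8-bit grayscale images by slab name."""

    subject_id: str
    eye: str
    slabs: dict[str, np.ndarray]
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        for name, img in self.slabs.items():
            if name not in CANONICAL_SLABS:
                raise ValueError(
                    f"{self.subject_id}/{self.eye}: unknown slab {name!r}; "
                    f"canonical names: {CANONICAL_SLABS}"
                )
            if img.shape != tuple(self.image_shape):
                raise ValueError(
                    f"{self.subject_id}/{self.eye}: slab {name!r} has shape "
                    f"{img.shape}, declared {self.image_shape}"
                )
            if not np.issubdtype(img.dtype, np.integer):
                raise ValueError(f"slab {name!r} must be an integer image")
            if img.size and (img.min() < 0 or img.max() > 255):
                raise ValueError(f"slab {name!r} has values outside [0, 255]")


@dataclass
class CohortDataset:
    """Validated cohort: subjects plus per-eye FLIO and OCT-A samples."""

    subjects: list[SubjectRecord]
    flio: list[FlioMeasurement] = field(default_factory=list)
    octa: list[OctaSlabStack] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in subjects")
        known = set(ids)
        for modality, samples in (("flio", self.flio), ("octa", self.octa)):
            seen: set[tuple[str, str]] = set()
            per_subject: dict[str, int] = {}
            for m in samples:
                key = (m.subject_id, m.eye)
                if key in seen:
                    raise ValueError(f"duplicate {modality} sample {key}")
                seen.add(key)
                if m.subject_id not in known:
                    raise ValueError(
                        f"{modality} sample references unknown subject {m.subject_id!r}"
                    )
                per_subject[m.subject_id] = per_subject.get(m.subject_id, 0) + 1
            if per_subject and max(per_subject.values()) > 2:
                raise ValueError(f"more than 2 eyes for a subject in {modality}")

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def status_by_subject(self) -> dict[str, str]:
        return {s.subject_id: s.smoking_status for s in self.subjects}

    def counts(self) -> dict[str, int]:
        out = {st: 0 for st in SMOKING_STATUSES}
        for s in self.subjects:
            out[s.smoking_status] += 1
        return out


#: Metadata columns of a serialized feature table, in order.
META_COLUMNS = ("subject_id", "eye", "label")


@dataclass
class FeatureTable:
    """Per-sample feature matrix with sample identity and class labels.

    ``label`` holds the three-level smoking status (the stratification
    variable); binary classification labels are derived from it against a
    chosen positive class.  ``subject_id`` doubles as the grouping key that
    keeps both eyes of a subject on the same side of any train/test split.
    """

    subject_ids: list[str]
    eyes: list[str]
    labels: list[str]
    features: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if not (len(self.eyes) == len(self.labels) == len(self.features) == n):
            raise ValueError("feature table columns have inconsistent lengths")
        keys = list(zip(self.subject_ids, self.eyes))
        if len(set(keys)) != n:
            raise ValueError("duplicate (subject_id, eye) row in feature table")
        names = list(self.features.columns)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature column names")
        if any(not lab for lab in self.labels):
            raise ValueError("every row must have a label")
        self.features = self.features.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def groups(self) -> list[str]:
        return list(self.subject_ids)

    def binary_labels(self, positive_class: str = "smoker") -> np.ndarray:
        """0/1 labels against ``positive_class`` in {smoker, heavy_smoker}.

        For ``heavy_smoker`` the caller is expected to have dropped light
        smokers first (see :func:`FeatureTable.restrict_statuses`).
        """
        if positive_class == "smoker":
            return np.array([lab != "non_smoker" for lab in self.labels], dtype=int)
        if positive_class == "heavy_smoker":
            return np.array([lab == "heavy_smoker" for lab in self.labels], dtype=int)
        raise ValueError(f"unknown positive_class {positive_class!r}")

    def restrict_statuses(self, statuses: Iterable[str]) -> "FeatureTable":
        keep = [i for i, lab in enumerate(self.labels) if lab in set(statuses)]
        return self.select_rows(keep)

    def select_rows(self, idx: Sequence[int]) -> "FeatureTable":
        return FeatureTable(
            subject_ids=[self.subject_ids[i] for i in idx],
            eyes=[self.eyes[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            features=self.features.iloc[list(idx)].reset_index(drop=True),
        )

    def select_columns(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"unknown feature columns: {missing}")
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            eyes=list(self.eyes),
            labels=list(self.labels),
            features=self.features.loc[:, list(names)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "eye": self.eyes,
                "label": self.labels,
            }
        )
        return pd.concat([meta, self.features.reset_index(drop=True)], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        for col in META_COLUMNS:
            if col not in frame.columns:
                raise ValueError(f"feature table is missing required column {col!r}")
        feats = frame.drop(columns=list(META_COLUMNS))
        return cls(
            subject_ids=[str(x) for x in frame["subject_id"]],
            eyes=[str(x) for x in frame["eye"]],
            labels=[str(x) for x in frame["label"]],
            features=feats.astype(float),
        )


@dataclass
class CvResult:
    """Aggregate of a repeated grouped stratified cross-validation run.

    Confusion cells are summed over the k folds within a repeat (each
    sample predicted exactly once per repeat) and then averaged over
    repeats, so mean_tp + mean_fn equals the positive sample count exactly.
    Rates are percentages of the mean cells; the +/- SDs are sample
    standard deviations over the per-repeat percentages.
    """

    mean_tp: float
    mean_fn: float
    mean_fp: float
    mean_tn: float
    tpr: float
    fpr: float
    accuracy: float
    sd_tpr: float
    sd_fpr: float
    sd_accuracy: float
    per_repeat: list[tuple[int, int, int, int]] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("mean_tp", "mean_fn", "mean_fp", "mean_tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tpr", "fpr", "accuracy"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must be a percentage in [0, 100]")
        self.per_repeat = [tuple(int(x) for x in row) for row in self.per_repeat]

    @property
    def positives(self) -> float:
        return self.mean_tp + self.mean_fn

    @property
    def negatives(self) -> float:
        return self.mean_fp + self.mean_tn

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_repeat"] = [list(row) for row in self.per_repeat]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CvResult":
        d = dict(d)
        d["per_repeat"] = [tuple(row) for row in d.get("per_repeat", [])]
        return cls(**d)
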