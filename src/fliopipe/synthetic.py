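"""Synthetic cohort generator emulating the smoking FLIO/OCT-A study design.

The emulated design: 26 non-smokers and 28 smokers (14 light / 14 heavy,
split strictly above 2500 cumulative packs), both eyes measured, giving
108 FLIO samples.  Lifetimes are built as

    tau_m = channel baseline + subject offset + smooth spatial field
            + eye noise + dose-scaled effect

so both eyes of a subject share the subject offset ("similar but not
identical") while each eye gets its own spatial field.  The group effect
is dose-dependent: a subject with cumulative packs p carries dose factor
d = min(p / dose_saturation_packs, 1), adding d x effect_ir_ssc_ps inside
the inner-ring annulus of the SSC and d x effect_or_lsc_ps inside the
outer-ring annulus of the LSC.  The annuli are computed here directly in
retinal-mm coordinates (not by reusing the extractor's masks), so a
sectorization bug cannot silently validate itself.  Intensity matrices
are pure noise and carry no group signal.

OCT-A slabs are rasterized stochastic branching vessel trees drawn to a
target foreground density, then blurred and quantized to 8-bit; with the
default ``octa_effect = 0`` they are independent of smoking status,
matching the study's negative OCT-A finding.

All randomness flows through numpy's PCG64 generator with explicit seed
sequences, so identical configurations produce bit-identical cohorts on
any platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .model import (
    CANONICAL_SLABS,
    CHANNELS,
    CohortDataset,
    FlioMeasurement,
    OctaSlabStack,
    SubjectRecord,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_flio",
    "generate_octa",
    "generate_vessel_mask",
    "simulate_to_dir",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Group sizes and the heavy/light split mirror the emulated study; the
    effect magnitudes (in ps) are stand-ins chosen to give heavy smokers
    a sector-level standardized difference of roughly 1.2, since the real
    per-sector differences are not published.  Baselines put typical
    pixels in the 190-350 ps display range.
    """

    n_non_smokers: int = 26
    n_light: int = 14
    n_heavy: int = 14
    tau_baseline_ps: dict[str, float] = field(
        default_factory=lambda: {"SSC": 240.0, "LSC": 280.0}
    )
    tau_between_subject_sd_ps: float = 12.0
    tau_spatial_sd_ps: float = 10.0
    spatial_correlation_px: float = 8.0
    eye_noise_sd_ps: float = 4.0
    effect_ir_ssc_ps: float = 15.0   # max smoker increase, inner ring, SSC
    effect_or_lsc_ps: float = -15.0  # max smoker decrease, outer ring, LSC
    dose_saturation_packs: float = 5000.0
    light_packs_range: tuple[float, float] = (500.0, 2500.0)
    heavy_packs_range: tuple[float, float] = (2500.0, 8000.0)
    intensity_mean_counts: float = 300.0
    intensity_sd_counts: float = 60.0
    fovea_dip_ps: float = 0.0  # optional central tau_m dip (hook; off by default)
    octa_vessel_density: float = 0.12
    octa_effect: float = 0.0  # per-slab density delta at full dose
    octa_slabs: tuple[str, ...] = ("SVC", "DCP")
    octa_exclude_one_light_smoker: bool = True
    image_shape: tuple[int, int] = (256, 256)
    flio_fov_deg: float = 30.0
    mm_per_degree: float = 0.3
    ring_diameters_mm: tuple[float, float, float] = (1.0, 3.0, 6.0)
    octa_shape: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_non_smokers, self.n_light, self.n_heavy) < 0:
            raise ValueError("group sizes must be non-negative")
        for name in (
            "tau_between_subject_sd_ps",
            "tau_spatial_sd_ps",
            "eye_noise_sd_ps",
            "intensity_sd_counts",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.intensity_mean_counts < 0:
            raise ValueError("intensity_mean_counts must be >= 0")
        unknown = set(self.octa_slabs) - set(CANONICAL_SLABS)
        if unknown:
            raise ValueError(f"unknown OCT-A slab names: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator actually injected, for downstream validation."""

    dose_factors: dict[str, float]
    effects_ps: dict[str, float]
    octa_excluded_subjects: list[str]
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def dose_factor(cumulative_packs: float, config: SyntheticConfig) -> float:
    """Linear dose-response with saturation, in [0, 1]."""
    return float(min(max(cumulative_packs, 0.0) / config.dose_saturation_packs, 1.0))


def _subject_rng(config: SyntheticConfig, subject_index: int, *stream: int):
    ss = np.random.SeedSequence([config.seed, subject_index, *stream])
    return np.random.Generator(np.random.PCG64(ss))


def _make_subjects(config: SyntheticConfig) -> list[SubjectRecord]:
    subjects = []
    groups = (
        [("N", "non_smoker")] * config.n_non_smokers
        + [("L", "light_smoker")] * config.n_light
        + [("H", "heavy_smoker")] * config.n_heavy
    )
    counters = {"N": 0, "L": 0, "H": 0}
    for idx, (prefix, status) in enumerate(groups):
        counters[prefix] += 1
        rng = _subject_rng(config, idx, 0)
        age = float(rng.integers(20, 41))
        sex = "M" if rng.random() < 0.5 else "F"
        if status == "non_smoker":
            years, packs = 0.0, 0.0
        else:
            lo, hi = (
                config.light_packs_range
                if status == "light_smoker"
                else config.heavy_packs_range
            )
            packs = float(rng.uniform(lo, hi))
            if packs <= lo:  # keep the half-open (lo, hi] convention exact
                packs = float(np.nextafter(lo, hi))
            years = float(rng.uniform(2.0, 20.0))
        subjects.append(
            SubjectRecord(
                subject_id=f"{prefix}{counters[prefix]:02d}",
                age=age,
                sex=sex,
                years_smoked=years,
                cumulative_packs=packs,
            )
        )
    return subjects


def _radius_mm(shape: tuple[int, int], fov_deg: float, mm_per_degree: float) -> np.ndarray:
    # Independent of the extractor's geometry code on purpose.
    n0, n1 = shape
    pitch = fov_deg * mm_per_degree / n0
    cy, cx = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    rows = np.arange(n0)[:, None] - cy
    cols = np.arange(n1)[None, :] - cx
    return np.hypot(rows, cols) * pitch


def subject_tau_offsets(config: SyntheticConfig, subject_index: int) -> dict[str, float]:
    """Per-channel lifetime offsets shared by both eyes of a subject."""
    rng = _subject_rng(config, subject_index, 1)
    return {
        ch: float(rng.normal(0.0, config.tau_between_subject_sd_ps)) for ch in CHANNELS
    }


def generate_flio(
    subject: SubjectRecord,
    eye: str,
    rng: np.random.Generator,
    config: SyntheticConfig,
    subject_offsets: dict[str, float] | None = None,
) -> FlioMeasurement:
    """Simulate one eye's four FLIO matrices.

    ``rng`` drives everything eye-specific; ``subject_offsets`` (shared
    between eyes) default to zero if not supplied.
    """
    if subject_offsets is None:
        subject_offsets = {ch: 0.0 for ch in CHANNELS}
    shape = tuple(config.image_shape)
    r_mm = _radius_mm(shape, config.flio_fov_deg, config.mm_per_degree)
    r_c, r_ir, r_or = (d / 2.0 for d in config.ring_diameters_mm)
    inner_ring = (r_mm > r_c) & (r_mm <= r_ir)
    outer_ring = (r_mm > r_ir) & (r_mm <= r_or)
    d = dose_factor(subject.cumulative_packs, config)

    tau: dict[str, np.ndarray] = {}
    intensity: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        white = rng.standard_normal(shape)
        smooth = gaussian_filter(white, sigma=config.spatial_correlation_px)
        sd = smooth.std()
        if sd > 0 and config.tau_spatial_sd_ps > 0:
            smooth = smooth * (config.tau_spatial_sd_ps / sd)
        else:
            smooth = np.zeros(shape)
        fld = (
            config.tau_baseline_ps[ch]
            + subject_offsets[ch]
            + smooth
            + rng.normal(0.0, config.eye_noise_sd_ps, shape)
        )
        if ch == "SSC":
            fld = fld + d * config.effect_ir_ssc_ps * inner_ring
        else:
            fld = fld + d * config.effect_or_lsc_ps * outer_ring
        if config.fovea_dip_ps:
            fld = fld - config.fovea_dip_ps * np.exp(-((r_mm / 0.5) ** 2))
        tau[ch] = np.clip(fld, 1.0, 4999.0)
        intensity[ch] = np.clip(
            rng.normal(config.intensity_mean_counts, config.intensity_sd_counts, shape),
            0.0,
            None,
        )
    return FlioMeasurement(subject_id=subject.subject_id, eye=eye, tau_m=tau, intensity=intensity)


def generate_vessel_mask(
    shape: tuple[int, int],
    density: float,
    rng: np.random.Generator,
    widths: tuple[int, int] = (1, 4),
    branch_prob: float = 0.02,
    turn_sd: float = 0.15,
) -> np.ndarray:
    """Rasterize a stochastic branching vessel tree as a binary mask.

    Biased random walks start at random border points heading inward,
    meander, branch, and stamp strokes of width 1-4 px until the target
    foreground fraction is reached (so the achieved density tracks the
    requested one to within one stroke).
    """
    n0, n1 = shape
    mask = np.zeros(shape, dtype=bool)
    target = int(round(max(density, 0.0) * n0 * n1))
    if target <= 0:
        return mask

    # disk stamps per width
    stamps = {}
    for w in range(widths[0], widths[1] + 1):
        r = w / 2.0
        k = int(np.ceil(r))
        yy, xx = np.mgrid[-k : k + 1, -k : k + 1]
        stamps[w] = (yy**2 + xx**2) <= r**2

    count = 0
    guard = 0
    while count < target and guard < 10_000:
        guard += 1
        side = rng.integers(0, 4)
        if side == 0:
            pos = np.array([0.0, rng.uniform(0, n1)])
        elif side == 1:
            pos = np.array([float(n0 - 1), rng.uniform(0, n1)])
        elif side == 2:
            pos = np.array([rng.uniform(0, n0), 0.0])
        else:
            pos = np.array([rng.uniform(0, n0), float(n1 - 1)])
        center = np.array([n0 / 2.0, n1 / 2.0])
        delta = center - pos
        ang = float(np.arctan2(delta[1], delta[0]))  # step is (dy, dx) = (cos, sin)
        stack = [(pos, ang)]
        while stack and count < target:
            pos, ang = stack.pop()
            pos = pos.copy()
            w = int(rng.integers(widths[0], widths[1] + 1))
            stamp = stamps[w]
            k = stamp.shape[0] // 2
            steps = int(rng.integers(40, 160))
            for _ in range(steps):
                ang += float(rng.normal(0.0, turn_sd))
                pos += np.array([np.cos(ang), np.sin(ang)])
                y, x = int(round(pos[0])), int(round(pos[1]))
                if not (0 <= y < n0 and 0 <= x < n1):
                    break
                y0, y1 = max(y - k, 0), min(y + k + 1, n0)
                x0, x1 = max(x - k, 0), min(x + k + 1, n1)
                sub = stamp[y0 - (y - k) : y1 - (y - k), x0 - (x - k) : x1 - (x - k)]
                region = mask[y0:y1, x0:x1]
                count += int(np.count_nonzero(sub & ~region))
                region |= sub
                if count >= target:
                    break
                if rng.random() < branch_prob and len(stack) < 32:
                    turn = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.0))
                    stack.append((pos.copy(), ang + turn))
    return mask


def generate_octa(
    subject: SubjectRecord,
    eye: str,
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> OctaSlabStack:
    """Simulate one eye's OCT-A slab stack at the configured densities."""
    d = dose_factor(subject.cumulative_packs, config)
    slabs = {}
    for slab in config.octa_slabs:
        density = config.octa_vessel_density + config.octa_effect * d
        mask = generate_vessel_mask(tuple(config.octa_shape), density, rng)
        img = gaussian_filter(mask.astype(float), sigma=1.0)
        peak = img.max()
        if peak > 0:
            img = img / peak * 255.0
        slabs[slab] = np.round(img).astype(np.uint8)
    return OctaSlabStack(
        subject_id=subject.subject_id,
        eye=eye,
        slabs=slabs,
        image_shape=tuple(config.octa_shape),
    )


def generate_cohort(config: SyntheticConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a full two-eye cohort with FLIO and (optionally) OCT-A.

    Deterministic given ``config.seed``.  When
    ``octa_exclude_one_light_smoker`` is set (the default) the first light
    smoker contributes no OCT-A data, reproducing the emulated study's
    single excluded angiography dataset.
    """
    subjects = _make_subjects(config)
    flio, octa = [], []
    excluded: list[str] = []
    first_light = next(
        (s.subject_id for s in subjects if s.smoking_status == "light_smoker"), None
    )
    for idx, subject in enumerate(subjects):
        offsets = subject_tau_offsets(config, idx)
        for eye_idx, eye in enumerate(("OD", "OS")):
            eye_rng = _subject_rng(config, idx, 2, eye_idx)
            flio.append(generate_flio(subject, eye, eye_rng, config, offsets))
            if config.octa_slabs:
                skip = (
                    config.octa_exclude_one_light_smoker
                    and subject.subject_id == first_light
                )
                if skip:
                    if subject.subject_id not in excluded:
                        excluded.append(subject.subject_id)
                    continue
                octa_rng = _subject_rng(config, idx, 3, eye_idx)
                octa.append(generate_octa(subject, eye, octa_rng, config))
    cohort = CohortDataset(subjects=subjects, flio=flio, octa=octa)
    truth = GroundTruth(
        dose_factors={s.subject_id: dose_factor(s.cumulative_packs, config) for s in subjects},
        effects_ps={
            "IR_SSC": config.effect_ir_ssc_ps,
            "OR_LSC": config.effect_or_lsc_ps,
        },
        octa_excluded_subjects=excluded,
        seed=config.seed,
    )
    return cohort, truth


def simulate_to_dir(config: SyntheticConfig, out_dir) -> Path:
    """Write a generated cohort as manifest + matrix/slab files.

    The layout round-trips through :func:`fliopipe.io.load_cohort`.
    """
    import pandas as pd

    from .io import (
        MANIFEST_META_COLUMNS,
        flio_path_columns,
        octa_path_column,
        write_matrix,
        write_slab_image,
    )

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(config)
    flio_by_key = {(m.subject_id, m.eye): m for m in cohort.flio}
    octa_by_key = {(m.subject_id, m.eye): m for m in cohort.octa}

    rows = []
    for subject in cohort.subjects:
        for eye in ("OD", "OS"):
            key = (subject.subject_id, eye)
            row: dict[str, object] = {
                "subject_id": subject.subject_id,
                "eye": eye,
                "age": subject.age,
                "sex": subject.sex,
                "years_smoked": subject.years_smoked,
                "cumulative_packs": subject.cumulative_packs,
            }
            if key in flio_by_key:
                m = flio_by_key[key]
                for kind, mats in (("tau", m.tau_m), ("intensity", m.intensity)):
                    for ch in CHANNELS:
                        rel = f"{subject.subject_id}_{eye}_{kind}_{ch.lower()}.tsv"
                        write_matrix(mats[ch], out_dir / rel)
                        row[f"{kind}_{ch.lower()}_path"] = rel
            if key in octa_by_key:
                for slab, img in octa_by_key[key].slabs.items():
                    rel = f"{subject.subject_id}_{eye}_octa_{slab.replace(' ', '_')}.png"
                    write_slab_image(img, out_dir / rel)
                    row[octa_path_column(slab)] = rel
            rows.append(row)

    columns = list(MANIFEST_META_COLUMNS) + flio_path_columns() + [
        octa_path_column(s) for s in config.octa_slabs
    ]
    manifest = pd.DataFrame(rows).reindex(columns=columns)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    return manifest_path
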