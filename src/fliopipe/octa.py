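"""OCT-A feature encodings and cohort embeddings.

An en-face angiography slab (512x512, 8-bit) is summarized either as a
256-bin pixel-value histogram, as mean intensity over a nine-sector
circular grid (the ETDRS layout scaled so the 6 mm outer circle exactly
inscribes the 20-degree field), or through a pluggable external encoder.
Optionally the slab is first converted to a vessel-density map: the local
box-counting fractal dimension of the binarized image inside a sliding
window, a per-pixel roughness measure in [0, 2] that tracks capillary
density.  Encoded cohorts are reduced by PCA to their 15 most variable
dimensions and embedded in 2-D with t-SNE for visual group comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .etdrs import GridGeometry, build_masks, sector_mean, SECTORS
from .model import CohortDataset, FeatureTable, OctaSlabStack

logger = logging.getLogger(__name__)

__all__ = [
    "histogram_encode",
    "sectorize_octa",
    "boxcount_dimension",
    "DensityMap",
    "fractal_density_map",
    "PcaResult",
    "pca_reduce",
    "EmbeddingConfig",
    "Embedding",
    "tsne_embed",
    "encode_cohort",
    "plot_embedding",
]


def histogram_encode(image: np.ndarray) -> np.ndarray:
    """256-bin pixel-value histogram (raw counts) of an 8-bit image."""
    arr = np.asarray(image)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("histogram encoding requires an integer image")
    if arr.size and (arr.min() < 0 or arr.max() > 255):
        raise ValueError("pixel values outside [0, 255]")
    return np.bincount(arr.ravel(), minlength=256)[:256].astype(np.int64)


def octa_geometry(
    image_shape: tuple[int, int] = (512, 512),
    laterality: str = "OD",
    field_of_view_deg: float = 20.0,
    mm_per_degree: float = 0.3,
) -> GridGeometry:
    """Sector-grid geometry for the 20-degree OCT-A field.

    20 deg x 0.3 mm/deg = 6.0 mm extent, so the 6 mm outer circle exactly
    inscribes the image (outer radius = half the image width).
    """
    return GridGeometry(
        image_shape=tuple(image_shape),
        field_of_view_deg=field_of_view_deg,
        mm_per_degree=mm_per_degree,
        laterality=laterality,
    )


def sectorize_octa(
    image: np.ndarray,
    laterality: str = "OD",
    geometry: GridGeometry | None = None,
) -> dict[str, float]:
    """Mean intensity of an OCT-A slab over the nine circular-grid sectors."""
    if geometry is None:
        geometry = octa_geometry(image_shape=image.shape, laterality=laterality)
    masks = build_masks(geometry)
    return sector_mean(np.asarray(image, dtype=float), masks)


# ---------------------------------------------------------------------------
# Local fractal dimension
# ---------------------------------------------------------------------------


def boxcount_dimension(window: np.ndarray, box_sizes: Sequence[int]) -> float:
    """Box-counting dimension of one binary window.

    The window is partitioned into an axis-aligned grid of boxes of side
    ``s`` anchored at its top-left corner (edge boxes may be partial);
    N(s) counts boxes containing at least one foreground pixel.  The
    dimension is the least-squares slope of log N(s) against log(1/s).
    An all-background window has dimension 0 by convention.
    """
    win = np.asarray(window, dtype=bool)
    if not win.any():
        return 0.0
    counts = []
    for s in box_sizes:
        n = 0
        for i in range(0, win.shape[0], s):
            for j in range(0, win.shape[1], s):
                if win[i : i + s, j : j + s].any():
                    n += 1
        counts.append(n)
    x = -np.log(np.asarray(box_sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


@dataclass
class DensityMap:
    """Per-pixel local fractal dimension of a binarized slab, in [0, 2]."""

    values: np.ndarray
    window_size: int
    box_sizes: tuple[int, ...]
    threshold_method: str
    threshold_value: float

    def rescaled_u8(self) -> np.ndarray:
        """Linear rescale of the FD values to an 8-bit image."""
        v = self.values
        span = v.max() - v.min()
        if span == 0:
            return np.zeros(v.shape, dtype=np.uint8)
        return np.round((v - v.min()) / span * 255.0).astype(np.uint8)


def _rect_occupancy(padded: np.ndarray, h: int, w: int) -> np.ndarray:
    """occ[i, j] = any foreground in padded[i:i+h, j:j+w] (valid positions)."""
    ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = padded.astype(np.int64).cumsum(axis=0).cumsum(axis=1)
    s = ii[h:, w:] - ii[:-h, w:] - ii[h:, :-w] + ii[:-h, :-w]
    return s > 0


def fractal_density_map(
    image: np.ndarray,
    window_size: int = 25,
    box_sizes: Sequence[int] = (2, 3, 4, 6, 8, 12),
    threshold: str | float = "otsu",
) -> DensityMap:
    """Sliding-window local fractal dimension of a grayscale slab.

    The slab is binarized globally (Otsu by default, or a fixed numeric
    threshold), reflection-padded, and for every pixel the box-counting
    dimension of its ``window_size`` x ``window_size`` neighbourhood is
    computed as in :func:`boxcount_dimension`.  Windows with no
    foreground get 0; values are clipped to the theoretical [0, 2] range.
    """
    img = np.asarray(image, dtype=float)
    if window_size % 2 == 0:
        raise ValueError("window_size must be odd")
    if window_size > min(img.shape):
        raise ValueError("window_size larger than the image")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold method {threshold!r}")
        thr = float(threshold_otsu(img)) if img.min() != img.max() else float(img.min())
        method = "otsu"
    else:
        thr, method = float(threshold), "fixed"
    fg = img > thr

    half = window_size // 2
    padded = np.pad(fg, half, mode="reflect")
    h_img, w_img = fg.shape

    log_counts = []
    occ_cache: dict[tuple[int, int], np.ndarray] = {}
    for s in box_sizes:
        n_tiles = -(-window_size // s)  # ceil
        total = np.zeros(fg.shape, dtype=np.int64)
        for ky in range(n_tiles):
            hy = min(s, window_size - ky * s)
            for kx in range(n_tiles):
                wx = min(s, window_size - kx * s)
                key = (hy, wx)
                if key not in occ_cache:
                    occ_cache[key] = _rect_occupancy(padded, hy, wx)
                occ = occ_cache[key]
                total += occ[ky * s : ky * s + h_img, kx * s : kx * s + w_img]
        log_counts.append(np.log(np.maximum(total, 1)))

    x = -np.log(np.asarray(box_sizes, dtype=float))
    xc = x - x.mean()
    y = np.stack(log_counts)  # (n_sizes, H, W)
    slope = np.tensordot(xc, y - y.mean(axis=0), axes=1) / (xc @ xc)

    window_occ = _rect_occupancy(padded, window_size, window_size)[:h_img, :w_img]
    values = np.where(window_occ, np.clip(slope, 0.0, 2.0), 0.0)
    return DensityMap(
        values=values,
        window_size=window_size,
        box_sizes=tuple(box_sizes),
        threshold_method=method,
        threshold_value=thr,
    )


# ---------------------------------------------------------------------------
# PCA + t-SNE
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray       # (n, k)
    components: np.ndarray   # (k, d), orthonormal rows
    mean: np.ndarray         # (d,)
    explained_variance: np.ndarray  # (k,)


def pca_reduce(vectors: np.ndarray, n_components: int = 15) -> PcaResult:
    """Mean-centered projection onto the top-variance principal axes.

    Keeps min(n_components, n_samples, n_features) axes.  Component signs
    are fixed by making each component's largest-magnitude loading
    positive, so the projection is fully deterministic.  Components
    beyond the data rank carry (numerically) zero variance; a warning is
    emitted when that happens.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_reduce needs a 2-D array with at least 2 rows")
    k = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if rank < k:
        warnings.warn(
            f"input rank {rank} < requested components {k}; trailing components "
            "carry no variance",
            RuntimeWarning,
            stacklevel=2,
        )
    return PcaResult(
        scores=scores,
        components=comps,
        mean=pca.mean_,
        explained_variance=pca.explained_variance_.copy(),
    )


@dataclass(frozen=True)
class EmbeddingConfig:
    """Dimensionality-reduction settings for cohort embeddings."""

    pca_dims: int = 15
    tsne_dims: int = 2
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tsne_dims != 2:
            raise ValueError("tsne_dims must be 2")


@dataclass
class Embedding:
    """2-D t-SNE coordinates with per-group summary statistics."""

    coords: np.ndarray       # (n, 2)
    labels: list[str]
    group_means: dict[str, tuple[float, float]]
    group_sds: dict[str, tuple[float, float]]


def tsne_embed(
    vectors: np.ndarray,
    labels: Sequence[str],
    config: EmbeddingConfig = EmbeddingConfig(),
) -> Embedding:
    """Embed samples in 2-D with t-SNE and summarize each group.

    Perplexity is auto-reduced below n/3; the layout is PCA-initialized
    and seeded, so a fixed configuration reproduces identical
    coordinates.  Fully degenerate input (all points identical) maps to
    the origin rather than feeding t-SNE a zero-distance matrix.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError(f"t-SNE needs at least 5 samples, got {n}")
    if len(labels) != n:
        raise ValueError("labels length does not match samples")
    if np.ptp(X) == 0:
        coords = np.zeros((n, 2))
    else:
        perplexity = min(config.perplexity, (n - 1) / 3.0 - 1e-9)
        perplexity = max(perplexity, 1.0)
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            init="pca",
            random_state=config.seed,
            learning_rate="auto",
        )
        coords = np.asarray(tsne.fit_transform(X), dtype=float)

    group_means: dict[str, tuple[float, float]] = {}
    group_sds: dict[str, tuple[float, float]] = {}
    for g in dict.fromkeys(labels):  # preserve first-seen order
        pts = coords[[i for i, lab in enumerate(labels) if lab == g]]
        group_means[g] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        sds = pts.std(axis=0, ddof=1) if len(pts) > 1 else np.zeros(2)
        group_sds[g] = (float(sds[0]), float(sds[1]))
    return Embedding(
        coords=coords, labels=list(labels), group_means=group_means, group_sds=group_sds
    )


def plot_embedding(embedding: Embedding, path, title: str = "") -> None:
    """Scatter plot with '+' group means and 1-SD ellipses."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(6, 5))
    groups = list(embedding.group_means)
    cmap = plt.get_cmap("tab10")
    for gi, g in enumerate(groups):
        pts = embedding.coords[[i for i, lab in enumerate(embedding.labels) if lab == g]]
        color = cmap(gi % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=18, alpha=0.6, color=color, label=g)
        mx, my = embedding.group_means[g]
        sx, sy = embedding.group_sds[g]
        ax.plot(mx, my, "+", color=color, markersize=14, markeredgewidth=3)
        ax.add_patch(
            Ellipse((mx, my), 2 * sx, 2 * sy, fill=False, color=color, linewidth=1.5)
        )
    ax.set_xlabel("Dim 1")
    ax.set_ylabel("Dim 2")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def encode_cohort(
    cohort: CohortDataset,
    method: str = "histogram",
    density_map: bool = False,
    slab_name: str = "SVC",
    external_encoder: Callable[[np.ndarray], np.ndarray] | None = None,
    density_kwargs: dict | None = None,
) -> FeatureTable:
    """Encode every OCT-A sample of a cohort into a feature table.

    ``method`` is one of ``histogram``, ``sectorization`` or
    ``external_encoder`` (a caller-supplied image -> vector hook, e.g. a
    pretrained deep feature extractor, which is deliberately not
    bundled).  With ``density_map`` the encoding is applied to the local
    fractal-dimension map instead of the raw slab (rescaled to 8-bit for
    the histogram; raw FD values for sectorization).  Samples missing the
    requested slab are skipped with a logged warning.
    """
    if method not in ("histogram", "sectorization", "external_encoder"):
        raise ValueError(f"unknown encoding method {method!r}")
    if method == "external_encoder" and external_encoder is None:
        raise ValueError("method 'external_encoder' requires an encoder callable")
    status = cohort.status_by_subject
    rows, sids, eyes, labels = [], [], [], []
    for stack in cohort.octa:
        if slab_name not in stack.slabs:
            logger.warning(
                "sample %s/%s has no slab %r; skipped",
                stack.subject_id,
                stack.eye,
                slab_name,
            )
            continue
        img: np.ndarray = stack.slabs[slab_name]
        if density_map:
            dm = fractal_density_map(img, **(density_kwargs or {}))
            img_for_hist = dm.rescaled_u8()
            img_for_sector = dm.values
        else:
            img_for_hist = img
            img_for_sector = img.astype(float)
        if method == "histogram":
            vec = histogram_encode(img_for_hist).astype(float)
            names = [f"hist_{i}" for i in range(256)]
        elif method == "sectorization":
            means = sectorize_octa(img_for_sector, laterality=stack.eye)
            vec = np.array([means[s] for s in SECTORS])
            names = [f"octa_{s}" for s in SECTORS]
        else:
            vec = np.asarray(external_encoder(img), dtype=float).ravel()
            names = [f"enc_{i}" for i in range(vec.size)]
        rows.append(pd.Series(vec, index=names))
        sids.append(stack.subject_id)
        eyes.append(stack.eye)
        labels.append(status[stack.subject_id])
    if not rows:
        logger.warning("no OCT-A samples carried slab %r; empty table", slab_name)
        feats = pd.DataFrame()
        return FeatureTable(subject_ids=[], eyes=[], labels=[], features=feats)
    return FeatureTable(
        subject_ids=sids, eyes=eyes, labels=labels, features=pd.DataFrame(rows)
    )
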