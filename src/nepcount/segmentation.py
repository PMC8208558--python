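"""Single-image foreground segmentation against a colored background.

Four methods behind one call signature, each returning a binary mask plus
diagnostics:

- ``segment_edge``: Laplacian-of-Gaussian zero-crossing edge map, closed
  morphologically and filled from the border.
- ``segment_graphcut``: SLIC superpixels on an L-equalized CIE-Lab image,
  a region-adjacency graph weighted by mean-color similarity, and a
  recursive normalized cut; the partition not anchored to the top image
  rows is labelled foreground.
- ``segment_random_forest``: a 50-tree random forest on per-pixel HSV
  (CLAHE-equalized V) intensity and texture features, trained from a
  foreground box on the animal and the top rows of the image as background.
- ``instance_mask_plugin``: adapter merging instance masks from any
  registered instance-segmentation backend (e.g. a pretrained Mask R-CNN)
  with a binary OR; class labels are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, graph, segmentation as skseg
from skimage.color import rgb2hsv, rgb2lab
from skimage.util import img_as_ubyte
from sklearn.ensemble import RandomForestClassifier

from .imaging import ConfigError, StructuringElement, binary_morphology, clahe, to_gray


@dataclass
class SegmentationResult:
    mask: np.ndarray
    method: str
    diagnostics: dict

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def segment_edge(
    frame: np.ndarray,
    sigma: float = 2.0,
    close_se: StructuringElement = StructuringElement("disk", 5),
    smooth_sigma: float | None = None,
) -> SegmentationResult:
    """Edge-based segmentation: smoothing, LoG zero crossings, closing, fill.

    The grayscale image is Gaussian-smoothed (``smooth_sigma``, default
    1.5 sigma) before the Laplacian-of-Gaussian; zero crossings of the LoG
    response localize object boundaries, morphological closing bridges small
    gaps, interior holes are filled from the border and the closing band is
    opened away again.  A uniform image yields an empty mask.
    """
    if sigma <= 0:
        raise ConfigError("sigma must be > 0")
    if smooth_sigma is None:
        smooth_sigma = 1.5 * sigma
    gray = to_gray(frame, "luminance")
    smoothed = ndimage.gaussian_filter(gray, smooth_sigma)
    log = ndimage.gaussian_laplace(smoothed, sigma=sigma)

    # zero-crossing pixels: sign change towards any 4-neighbor, gated by a
    # slope threshold relative to the mean response so flat sensor noise
    # does not produce speckle edges
    thresh = np.abs(log).mean()
    edges = np.zeros(log.shape, dtype=bool)
    for axis, shift in ((0, 1), (1, 1)):
        a = log
        b = np.roll(log, shift, axis=axis)
        crossing = (a * b < 0) & (np.abs(a - b) > thresh)
        edges |= crossing
        edges |= np.roll(crossing, -shift, axis=axis)
    edges[0, :] = edges[-1, :] = False
    edges[:, 0] = edges[:, -1] = False

    if not edges.any():
        return SegmentationResult(edges, "edge", {"n_edge_pixels": 0})

    closed = binary_morphology(edges, "close", close_se)
    filled = ndimage.binary_fill_holes(closed)
    # the closed edge band inflates the silhouette; erode it back by the
    # closing radius so the boundary sits on the zero crossing
    filled = binary_morphology(filled, "open", close_se)
    return SegmentationResult(
        filled,
        "edge",
        {"n_edge_pixels": int(edges.sum()), "sigma": sigma},
    )


def segment_graphcut(
    frame: np.ndarray,
    n_superpixels: int = 600,
    compactness: float = 1.0,
    ncut_thresh: float = 0.001,
    similarity_sigma: float = 100.0,
    bg_rows: int = 1,
) -> SegmentationResult:
    """Superpixel + normalized-cut segmentation on mean color.

    The frame is converted to CIE-Lab with a histogram-equalized L channel,
    oversegmented by SLIC, summarized as a region-adjacency graph on mean
    color and partitioned by a recursive normalized cut.  Regions whose cut
    partition touches the top ``bg_rows`` image rows are background (the
    background-label convention of the training protocol); the rest is
    foreground.  If every partition touches the top rows, the smallest
    partition by area is taken as foreground; a single-partition outcome is
    degenerate and yields an empty mask.
    """
    if n_superpixels < 2:
        raise ConfigError("need at least 2 superpixels")
    frame = np.asarray(frame, dtype=np.float64)
    lab = rgb2lab(frame)
    l_eq = exposure.equalize_hist(lab[..., 0] / 100.0) * 100.0
    lab_eq = np.dstack([l_eq, lab[..., 1], lab[..., 2]])

    labels = skseg.slic(
        lab_eq,
        n_segments=n_superpixels,
        compactness=compactness,
        convert2lab=False,
        start_label=1,
        channel_axis=-1,
    )
    rag = graph.rag_mean_color(lab_eq, labels, mode="similarity", sigma=similarity_sigma)
    try:
        cut = graph.cut_normalized(labels, rag, thresh=ncut_thresh)
    except np.linalg.LinAlgError:
        return SegmentationResult(
            np.zeros(frame.shape[:2], dtype=bool), "graphcut", {"degenerate": True}
        )

    partitions = np.unique(cut)
    diag = {"n_superpixels": int(labels.max()), "n_partitions": int(len(partitions))}
    if len(partitions) < 2:
        diag["degenerate"] = True
        return SegmentationResult(np.zeros(frame.shape[:2], dtype=bool), "graphcut", diag)

    top = np.unique(cut[:bg_rows, :])
    fg_parts = [p for p in partitions if p not in top]
    if not fg_parts:
        # everything touches the top rows: fall back to the smallest partition
        areas = {p: int((cut == p).sum()) for p in partitions}
        fg_parts = [min(areas, key=areas.get)]
        diag["fallback_smallest"] = True
    mask = np.isin(cut, fg_parts)
    return SegmentationResult(mask, "graphcut", diag)


@dataclass(frozen=True)
class RFLabelSpec:
    """Training-label geometry for the random-forest segmentor.

    ``fg_center`` is the (x, y) center of a ``fg_size`` square of foreground
    training pixels on the animal; the first ``bg_rows`` rows from the top
    are background training pixels.  The two regions must not overlap.
    """

    fg_center: tuple[int, int]
    fg_size: int = 100
    bg_rows: int = 100

    def fg_slice(self, shape: tuple[int, ...]) -> tuple[slice, slice]:
        h, w = shape[:2]
        half = self.fg_size // 2
        x, y = self.fg_center
        y0, y1 = y - half, y - half + self.fg_size
        x0, x1 = x - half, x - half + self.fg_size
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            raise ConfigError(f"foreground box {x0, y0, x1, y1} outside image {h}x{w}")
        if y0 < self.bg_rows:
            raise ConfigError("foreground box overlaps background rows")
        return (slice(y0, y1), slice(x0, x1))


def _pixel_features(frame: np.ndarray, clip_limit: float, tiles: tuple[int, int]) -> np.ndarray:
    """Per-pixel feature stack: H, S, equalized V, local std, local entropy."""
    hsv = rgb2hsv(frame)
    v_eq = clahe(hsv[..., 2], clip_limit=clip_limit, tiles=tiles)
    # texture on the equalized V channel
    mean5 = ndimage.uniform_filter(v_eq, size=5)
    sq5 = ndimage.uniform_filter(v_eq**2, size=5)
    local_std = np.sqrt(np.clip(sq5 - mean5**2, 0.0, None))
    from skimage.filters.rank import entropy as rank_entropy
    from skimage.morphology import footprint_rectangle

    local_entropy = rank_entropy(img_as_ubyte(v_eq), footprint_rectangle((9, 9)))
    local_entropy = local_entropy / 8.0  # bits, max log2(256)
    return np.dstack([hsv[..., 0], hsv[..., 1], v_eq, local_std, local_entropy])


def segment_random_forest(
    frame: np.ndarray,
    labels: RFLabelSpec,
    n_trees: int = 50,
    seed: int = 0,
    max_train_per_class: int = 10_000,
    clahe_clip_limit: float = 0.01,
    clahe_tiles: tuple[int, int] = (8, 8),
) -> SegmentationResult:
    """Random-forest pixel classification into foreground and background.

    Features are HSV intensity (V after CLAHE) plus local texture (5x5
    standard deviation and 9x9 entropy of V).  Training pixels come from the
    label geometry; at most ``max_train_per_class`` pixels per class are
    used, subsampled with the given seed, and the forest itself is seeded,
    so results are deterministic.
    """
    frame = np.asarray(frame, dtype=np.float64)
    feats = _pixel_features(frame, clahe_clip_limit, clahe_tiles)
    h, w, nf = feats.shape

    fg_sl = labels.fg_slice(frame.shape)
    fg_pixels = feats[fg_sl].reshape(-1, nf)
    bg_pixels = feats[: labels.bg_rows, :, :].reshape(-1, nf)

    diag: dict = {"n_trees": n_trees}
    # degenerate training sets: identical constant FG and BG distributions
    if (
        np.allclose(fg_pixels.std(axis=0), 0)
        and np.allclose(bg_pixels.std(axis=0), 0)
        and np.allclose(fg_pixels.mean(axis=0), bg_pixels.mean(axis=0))
    ):
        diag["degenerate"] = True
        diag["low_separability"] = True
        return SegmentationResult(np.zeros((h, w), dtype=bool), "random_forest", diag)

    rng = np.random.default_rng(seed)

    def sample(arr: np.ndarray) -> np.ndarray:
        if len(arr) > max_train_per_class:
            idx = rng.choice(len(arr), size=max_train_per_class, replace=False)
            return arr[idx]
        return arr

    fg_s, bg_s = sample(fg_pixels), sample(bg_pixels)
    X = np.vstack([fg_s, bg_s])
    y = np.concatenate([np.ones(len(fg_s), dtype=int), np.zeros(len(bg_s), dtype=int)])

    sep = np.linalg.norm(fg_s.mean(axis=0) - bg_s.mean(axis=0))
    if sep < 1e-3:
        diag["low_separability"] = True

    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    pred = clf.predict(feats.reshape(-1, nf)).reshape(h, w).astype(bool)
    diag["fg_bg_feature_distance"] = float(sep)
    return SegmentationResult(pred, "random_forest", diag)


class InstanceSegmentor(Protocol):
    """Backend contract: frame in, per-instance masks (+ boxes, scores) out."""

    def predict(self, frame: np.ndarray) -> Sequence[np.ndarray]: ...


class CapabilityError(RuntimeError):
    """No instance-segmentation backend is registered."""


def instance_mask_plugin(frame: np.ndarray, backend: InstanceSegmentor | None) -> SegmentationResult:
    """Merge all instance masks from a backend into one foreground mask.

    Class labels of the backend are ignored — every predicted instance is
    treated as target foreground and the masks are combined by binary OR.
    """
    if backend is None:
        raise CapabilityError(
            "instance segmentation requires a registered backend (e.g. a "
            "pretrained Mask R-CNN adapter); none is bundled"
        )
    frame = np.asarray(frame, dtype=np.float64)
    instances = backend.predict(frame)
    out = np.zeros(frame.shape[:2], dtype=bool)
    for m in instances:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ConfigError(f"instance mask shape {m.shape} != frame {out.shape}")
        out |= m
    return SegmentationResult(out, "instance_plugin", {"n_instances": len(instances)})


SEGMENTORS = {
    "edge": lambda frame, **kw: segment_edge(frame, **kw),
    "graphcut": lambda frame, **kw: segment_graphcut(frame, **kw),
    "random_forest": lambda frame, **kw: segment_random_forest(frame, **kw),
}


def default_rf_labels(frame_shape: tuple[int, ...], fg_size: int = 100, bg_rows: int = 100) -> RFLabelSpec:
    """Label geometry with the foreground box at the image center."""
    h, w = frame_shape[:2]
    return RFLabelSpec(fg_center=(w // 2, h // 2), fg_size=fg_size, bg_rows=bg_rows)
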