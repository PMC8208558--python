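"""Per-frame foreground detection: three filter branches fused by AND.

The detector combines three complementary foreground cues before blob
analysis:

1. an online per-pixel Gaussian-mixture background model (adaptive
   background subtraction for anything that moves),
2. red-minus-gray thresholding (picks up red-reflecting carapace pixels
   regardless of motion), and
3. a mean-intensity-shift + CLAHE filter that suppresses achromatic
   content, restores contrast adaptively and thresholds the red channel.

The three binary masks are multiplied elementwise (a multi-AND), so a pixel
must be moving *and* chromatically red *and* red after contrast restoration
to survive — each branch vetoes a different family of false positives.
Connected components of the fused mask above a minimum area become
detections with bounding box, centroid and area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ConfigError, StructuringElement, binary_morphology, clahe, to_gray

PAPER_SCALE_PIXELS = 1920 * 1440  # reference resolution of the 7500-px area gate


@dataclass(frozen=True)
class Detection:
    """One blob in one frame: bounding box, centroid and pixel area."""

    bbox: tuple[int, int, int, int]  # (x, y, w, h), half-open
    centroid: tuple[float, float]  # (x, y)
    area: int
    frame_index: int


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds and structuring elements of the fused detector.

    ``min_blob_area`` is 7500 px at the reference 1920x1440 resolution; in
    ``area_scaling="resolution-scaled"`` mode it is multiplied by the ratio
    of actual to reference pixel counts so small test frames keep the same
    relative gate.
    """

    red_threshold: float = 0.01
    equalized_red_threshold: float = 0.05
    min_blob_area: int = 7500
    open_se: StructuringElement = StructuringElement("square", 3)
    close_se: StructuringElement = StructuringElement("square", 15)
    area_scaling: str = "fixed"  # or "resolution-scaled"
    clahe_clip_limit: float = 0.01
    clahe_tiles: tuple[int, int] = (8, 8)
    n_gaussians: int = 5
    n_training_frames: int = 140
    min_background_ratio: float = 0.64

    def __post_init__(self) -> None:
        if not (0 < self.red_threshold < 1 and 0 < self.equalized_red_threshold < 1):
            raise ConfigError("thresholds must lie in (0, 1)")
        if self.min_blob_area < 1:
            raise ConfigError("min_blob_area must be >= 1")
        if self.area_scaling not in ("fixed", "resolution-scaled"):
            raise ConfigError(f"unknown area_scaling {self.area_scaling!r}")

    def effective_min_area(self, frame_shape: tuple[int, ...]) -> int:
        if self.area_scaling == "fixed":
            return self.min_blob_area
        h, w = frame_shape[:2]
        return max(1, int(round(self.min_blob_area * (h * w) / PAPER_SCALE_PIXELS)))


def _gmm_update_reference(
    means,
    variances,
    weights,
    pixels,
    alpha,
    match_sigma,
    min_background_ratio,
    init_var,
    init_weight,
):
    """Vectorized one-frame mixture update.

    State layout: ``means`` (N, K, C), ``variances`` and ``weights`` (N, K)
    for N pixels, K components and C color channels; each component carries
    per-channel means and one shared variance, and a component matches when
    the squared color distance is within ``match_sigma**2 * C * variance``.
    This is the plain numpy statement of the update rule; the compiled
    kernel below must agree with it (a cross-check enforced in the test
    suite).  Mutates the state arrays in place, returns the foreground mask.
    """
    n, k, c = means.shape
    diff = pixels[:, None, :] - means  # (N, K, C)
    dist2 = np.sum(diff * diff, axis=2)  # (N, K)
    sigma = np.sqrt(variances)
    matched = dist2 <= (match_sigma * match_sigma * c) * variances

    fitness = weights / sigma
    order = np.argsort(-fitness, axis=1, kind="stable")
    w_sorted = np.take_along_axis(weights, order, axis=1)
    cum = np.cumsum(w_sorted, axis=1)
    # background components: top-ranked until the cumulative weight reaches
    # the ratio (the component crossing the threshold is included)
    bg_sorted = (cum - w_sorted) < min_background_ratio
    is_background = np.zeros_like(bg_sorted)
    np.put_along_axis(is_background, order, bg_sorted, axis=1)

    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.broadcast_to(np.arange(k, dtype=order.dtype), (n, k)), axis=1)
    rank_of_matches = np.where(matched, rank, k)
    best_rank = rank_of_matches.min(axis=1)
    any_match = best_rank < k
    chosen = (rank == best_rank[:, None]) & matched  # one-hot over K

    foreground = ~(any_match & (is_background & chosen).any(axis=1))

    weights *= 1.0 - alpha
    weights[chosen] += alpha
    means[chosen] += alpha * diff[chosen]
    variances[chosen] += alpha * (dist2[chosen] / c - variances[chosen])
    np.clip(variances, 1e-6, None, out=variances)

    if not any_match.all():
        weakest = np.argmin(weights, axis=1)
        replace = (~any_match)[:, None] & (np.arange(k)[None, :] == weakest[:, None])
        means[replace] = pixels[:, None, :].repeat(k, axis=1)[replace]
        variances[replace] = init_var
        weights[replace] = init_weight

    weights /= weights.sum(axis=1, keepdims=True)
    return foreground


try:  # compiled fast path; the numpy reference above is always available
    import numba

    @numba.njit(cache=False, fastmath=False)
    def _gmm_update_kernel(  # pragma: no cover - exercised via apply()
        means, variances, weights, pixels, alpha, match_sigma, min_background_ratio, init_var, init_weight
    ):
        n, k, nc = means.shape
        foreground = np.empty(n, dtype=np.bool_)
        order = np.empty(k, dtype=np.int64)
        fit = np.empty(k, dtype=np.float32)
        dist2 = np.empty(k, dtype=np.float32)
        # all arithmetic in float32 so the kernel agrees bit-for-bit with
        # the numpy reference on float32 state
        nc_f = np.float32(nc)
        one = np.float32(1.0)
        zero = np.float32(0.0)
        thresh_scale = match_sigma * match_sigma * nc_f
        for i in range(n):
            # rank components by weight/sigma, ties to the lower index
            for a in range(k):
                order[a] = a
                fit[a] = weights[i, a] / np.sqrt(variances[i, a])
                d2 = zero
                for ch in range(nc):
                    d = pixels[i, ch] - means[i, a, ch]
                    d2 += d * d
                dist2[a] = d2
            # stable insertion sort, descending fitness (ties keep index order)
            for a in range(1, k):
                key = order[a]
                b = a - 1
                while b >= 0 and fit[order[b]] < fit[key]:
                    order[b + 1] = order[b]
                    b -= 1
                order[b + 1] = key

            # best-ranked matching component and its background membership
            chosen = -1
            chosen_is_bg = False
            cum = zero
            for r in range(k):
                comp = order[r]
                is_bg = cum < min_background_ratio
                cum += weights[i, comp]
                if chosen < 0 and dist2[comp] <= thresh_scale * variances[i, comp]:
                    chosen = comp
                    chosen_is_bg = is_bg
            foreground[i] = not (chosen >= 0 and chosen_is_bg)

            for comp in range(k):
                weights[i, comp] *= one - alpha
            if chosen >= 0:
                weights[i, chosen] += alpha
                for ch in range(nc):
                    means[i, chosen, ch] += alpha * (pixels[i, ch] - means[i, chosen, ch])
                v = variances[i, chosen] + alpha * (dist2[chosen] / nc_f - variances[i, chosen])
                variances[i, chosen] = v if v > np.float32(1e-6) else np.float32(1e-6)
            else:
                weakest = 0
                for comp in range(1, k):
                    if weights[i, comp] < weights[i, weakest]:
                        weakest = comp
                for ch in range(nc):
                    means[i, weakest, ch] = pixels[i, ch]
                variances[i, weakest] = init_var
                weights[i, weakest] = init_weight

            total = zero
            for comp in range(k):
                total += weights[i, comp]
            for comp in range(k):
                weights[i, comp] /= total

        return foreground

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


class GMMBackgroundModel:
    """Online per-pixel mixture-of-Gaussians background model.

    Each pixel's RGB history is modelled by ``n_gaussians`` Gaussian
    components (per-channel means, one shared variance each) with weights
    summing to one.  Components are ranked by weight/sigma; the top-ranked
    components whose cumulative weight reaches ``min_background_ratio``
    constitute the background.  A pixel matching none of those (color
    distance within 2.5 sigma per channel on average) is foreground.  During
    the first ``n_training_frames`` the model learns with rate
    1/frames_seen (a running average) and the returned masks are flagged as
    training output; afterwards the learning rate is a fixed small constant.
    """

    MATCH_SIGMA = 2.5
    INIT_WEIGHT = 0.05
    INIT_VAR = (30.0 / 255.0) ** 2
    POST_TRAINING_RATE = 0.005

    def __init__(
        self,
        n_gaussians: int = 5,
        n_training_frames: int = 140,
        min_background_ratio: float = 0.64,
        use_compiled: bool = True,
    ):
        if not 0 < min_background_ratio < 1:
            raise ConfigError("min_background_ratio must lie in (0, 1)")
        self.n_gaussians = n_gaussians
        self.n_training_frames = n_training_frames
        self.min_background_ratio = min_background_ratio
        self.use_compiled = use_compiled and _HAVE_NUMBA
        self.frames_seen = 0
        self.frame_shape: tuple[int, int] | None = None
        self._means: np.ndarray | None = None  # (N, K, C) float32
        self._vars: np.ndarray | None = None  # (N, K)
        self._weights: np.ndarray | None = None  # (N, K)

    @property
    def training(self) -> bool:
        return self.frames_seen <= self.n_training_frames

    def _init_state(self, pixels: np.ndarray) -> None:
        n, c = pixels.shape
        k = self.n_gaussians
        self._means = np.full((n, k, c), -1000.0, dtype=np.float32)
        # unused slots start far away so they never match before takeover
        self._means[:, 0, :] = pixels
        self._vars = np.full((n, k), self.INIT_VAR, dtype=np.float32)
        self._weights = np.zeros((n, k), dtype=np.float32)
        self._weights[:, 0] = 1.0

    def apply(self, frame: np.ndarray) -> np.ndarray:
        """Update the model with one RGB frame; return the raw foreground mask."""
        frame = np.asarray(frame)
        shape = frame.shape[:2]
        pixels = np.ascontiguousarray(frame.reshape(-1, 3), dtype=np.float32)
        if self._means is None:
            self.frame_shape = shape
            self._init_state(pixels)
            self.frames_seen = 1
            return np.zeros(shape, dtype=bool)
        if shape != self.frame_shape:
            raise ConfigError(
                f"frame size {shape} does not match model size {self.frame_shape}"
            )
        self.frames_seen += 1
        alpha = (
            1.0 / self.frames_seen
            if self.frames_seen <= self.n_training_frames
            else self.POST_TRAINING_RATE
        )
        update = _gmm_update_kernel if self.use_compiled else _gmm_update_reference
        fg = update(
            self._means,
            self._vars,
            self._weights,
            pixels,
            np.float32(alpha),
            np.float32(self.MATCH_SIGMA),
            np.float32(self.min_background_ratio),
            np.float32(self.INIT_VAR),
            np.float32(self.INIT_WEIGHT),
        )
        return fg.reshape(shape)


def gmm_foreground(
    model: GMMBackgroundModel,
    frame: np.ndarray,
    open_se: StructuringElement = StructuringElement("square", 3),
    close_se: StructuringElement = StructuringElement("square", 15),
) -> tuple[np.ndarray, GMMBackgroundModel]:
    """Background-subtraction branch: GMM foreground cleaned by open then close."""
    raw = model.apply(frame)
    if not raw.any():
        return raw, model
    cleaned = binary_morphology(raw, "open", open_se)
    cleaned = binary_morphology(cleaned, "close", close_se)
    return cleaned, model


def red_minus_gray(frame: np.ndarray, threshold: float = 0.01) -> np.ndarray:
    """Red-channel thresholding branch.

    The Rec.601 grayscale frame is subtracted from the red channel (removing
    the achromatic illumination component), negative values are clipped to
    zero and a very low intensity threshold keeps chromatically red pixels.
    """
    if not 0 < threshold < 1:
        raise ConfigError("threshold must lie in (0, 1)")
    frame = np.asarray(frame, dtype=np.float64)
    diff = np.clip(frame[..., 0] - to_gray(frame, "luminance"), 0.0, None)
    return diff >= threshold


def mean_shift_equalized_red(
    frame: np.ndarray,
    threshold: float = 0.05,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Mean-intensity-shift + histogram-equalization branch.

    Subtracting the per-pixel channel mean removes low-saturation content and
    leaves pixels dominated by a single primary; CLAHE restores contrast; a
    low threshold on the resulting red channel removes residual noise.  CLAHE
    acts independently per channel, so only the red channel — the only one
    consumed downstream — is actually equalized.
    """
    if not 0 < threshold < 1:
        raise ConfigError("threshold must lie in (0, 1)")
    frame = np.asarray(frame, dtype=np.float64)
    shifted_red = np.clip(frame[..., 0] - frame.mean(axis=2), 0.0, 1.0)
    if np.ptp(shifted_red) == 0:
        return np.zeros(shifted_red.shape, dtype=bool)
    equalized = clahe(shifted_red, clip_limit=clip_limit, tiles=tiles)
    return equalized >= threshold


def fuse_masks(*masks: np.ndarray) -> np.ndarray:
    """Elementwise AND of the branch masks (the multi-AND fusion)."""
    if not masks:
        raise ConfigError("need at least one mask")
    out = np.asarray(masks[0], dtype=bool)
    for m in masks[1:]:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ConfigError(f"mask size mismatch: {m.shape} vs {out.shape}")
        out = out & m
    return out


def blob_analysis(mask: np.ndarray, min_area: int, frame_index: int = 0) -> list[Detection]:
    """8-connected component labeling with an area gate.

    Components with at least ``min_area`` pixels become detections carrying a
    tight bounding box, the pixel-mean centroid and the pixel count.
    """
    if min_area < 1:
        raise ConfigError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    detections: list[Detection] = []
    if n == 0:
        return detections
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    slices = ndimage.find_objects(labels)
    centroids = ndimage.center_of_mass(mask, labels, index=np.arange(1, n + 1))
    for i in range(n):
        if areas[i] < min_area:
            continue
        sy, sx = slices[i]
        cy, cx = centroids[i]
        detections.append(
            Detection(
                bbox=(sx.start, sy.start, sx.stop - sx.start, sy.stop - sy.start),
                centroid=(float(cx), float(cy)),
                area=int(areas[i]),
                frame_index=frame_index,
            )
        )
    return detections


@dataclass
class DetectorState:
    """Streaming state of the fused detector (the background model)."""

    config: DetectorConfig = field(default_factory=DetectorConfig)
    gmm: GMMBackgroundModel | None = None

    def __post_init__(self) -> None:
        if self.gmm is None:
            self.gmm = GMMBackgroundModel(
                n_gaussians=self.config.n_gaussians,
                n_training_frames=self.config.n_training_frames,
                min_background_ratio=self.config.min_background_ratio,
            )


def detect_frame(
    state: DetectorState, frame: np.ndarray, frame_index: int
) -> tuple[list[Detection], DetectorState]:
    """Run the three branches on one frame, fuse, and extract blobs.

    Returns no detections while the background model is still in its
    training window.
    """
    cfg = state.config
    gmm_mask, _ = gmm_foreground(state.gmm, frame, cfg.open_se, cfg.close_se)
    if state.gmm.training:
        return [], state
    red_mask = red_minus_gray(frame, cfg.red_threshold)
    eq_mask = mean_shift_equalized_red(
        frame, cfg.equalized_red_threshold, cfg.clahe_clip_limit, cfg.clahe_tiles
    )
    fused = fuse_masks(gmm_mask, red_mask, eq_mask)
    return blob_analysis(fused, cfg.effective_min_area(frame.shape), frame_index), state
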