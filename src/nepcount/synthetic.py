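"""Seeded generator of tank-like scenes with exact ground truth.

The generator emulates the experimental observation scene used to develop
the pipeline: a uniformly colored opaque background (tarpaulin presets
green / yellow / orange / white), one or more elongated reddish targets
(Norway lobster reflect red-band light from the astaxanthin pigment in the
carapace) translating across the field of view at near-constant velocity,
plus a smooth illumination gradient and Gaussian pixel noise.  Every frame,
instance mask, bounding box and trajectory is exact by construction, so the
generator plays the role of the human ground-truth annotator for detection,
tracking and counting experiments.

All randomness flows from ``SceneSpec.seed`` through ``numpy`` seed
sequences; two renders of the same spec are bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .imaging import ConfigError

# Tarpaulin color presets (unit-scale RGB), eyeballed from colored PVC sheet.
BACKGROUND_PRESETS: dict[str, tuple[float, float, float]] = {
    "green": (0.10, 0.45, 0.22),
    "yellow": (0.85, 0.78, 0.15),
    "orange": (0.90, 0.45, 0.10),
    "white": (0.92, 0.92, 0.90),
}

# Carotenoid-red body color around which per-target jitter is applied.
TARGET_COLOR = (0.65, 0.25, 0.20)

# Contrast presets blend the target color toward the background color:
# 0 would be no contrast at all, 1 the full preset separation.
CONTRAST_BLEND = {"low": 0.25, "med": 0.55, "high": 1.0}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic observation scene.

    Defaults are a desk-scale stand-in for the experimental footage: 480x640
    frames at 30 fps in front of a green background, one target of body-scale
    100 px entering after the background-model training window and drifting
    with the simulated current at 3 px/frame (about the apparent speed of an
    object passing a 2-knot flow at the paper-scale frame width, scaled to
    the small frame).
    """

    size: tuple[int, int] = (480, 640)
    fps: float = 30.0
    n_frames: int = 300
    background_color: str | tuple[float, float, float] = "green"
    n_targets: int = 1
    target_color: tuple[float, float, float] = TARGET_COLOR
    color_jitter: float = 0.05
    target_scale: float = 100.0
    speed: float = 3.0
    speed_jitter: float = 0.5
    entry_times: tuple[int, ...] | None = None
    illumination_gradient: float = 0.10
    noise_sigma: float = 0.01
    contrast: str = "high"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ConfigError("speed must be > 0")
        if self.contrast not in CONTRAST_BLEND:
            raise ConfigError(f"unknown contrast preset {self.contrast!r}")
        if isinstance(self.background_color, str) and self.background_color not in BACKGROUND_PRESETS:
            raise ConfigError(f"unknown background preset {self.background_color!r}")

    @property
    def background_rgb(self) -> np.ndarray:
        if isinstance(self.background_color, str):
            return np.array(BACKGROUND_PRESETS[self.background_color])
        return np.asarray(self.background_color, dtype=float)

    def target_rgb(self) -> np.ndarray:
        """Target body color after applying the contrast preset blend."""
        bg = self.background_rgb
        fg = np.asarray(self.target_color, dtype=float)
        t = CONTRAST_BLEND[self.contrast]
        return bg + t * (fg - bg)


def easy_spec(seed: int, n_targets: int = 1, **overrides) -> SceneSpec:
    """High-contrast, zero-noise preset used for count-recovery experiments."""
    return SceneSpec(
        seed=seed,
        n_targets=n_targets,
        noise_sigma=0.0,
        illumination_gradient=0.05,
        contrast="high",
        **overrides,
    )


@dataclass
class GroundTruth:
    """Exact per-frame annotation of a rendered scene.

    ``instances[f]`` lists ``(track_id, mask, bbox)`` for every target with at
    least one pixel inside frame ``f``; ``trajectories`` maps track id to the
    list of ``(frame, cx, cy)`` centroids of the visible part.
    """

    instances: list[list[tuple[int, np.ndarray, tuple[int, int, int, int]]]]
    trajectories: dict[int, list[tuple[int, float, float]]]
    total_count: int

    def combined_mask(self, frame_index: int) -> np.ndarray:
        masks = [m for _, m, _ in self.instances[frame_index]]
        if not masks:
            raise ConfigError(f"no instances at frame {frame_index}")
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


def make_target_shape(scale: float, seed: int) -> np.ndarray:
    """Rasterize an elongated body-plus-claws silhouette.

    The template is a cephalothorax-and-tail ellipse with two forward claw
    lobes and a tail fan, overall roughly 4:1 in aspect, with small seeded
    vertex jitter so no two animals are pixel-identical.  The mask is a
    single 8-connected component with area ~0.4 * scale**2.
    """
    if scale < 20:
        raise ConfigError("target scale must be >= 20 px")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EA]))
    s = float(scale)

    # centerline profile: half-width as fraction of s along the body axis u
    u = np.linspace(-0.9, 0.9, 25)
    base = 0.22 * np.exp(-((u + 0.25) ** 2) / 0.35) + 0.10 * np.exp(-((u - 0.55) ** 2) / 0.05)
    base = np.maximum(base, 0.06)
    jitter = rng.normal(0.0, 0.008, size=base.shape)
    half_w = (base + jitter).clip(0.04, 0.30) * s

    cx = 0.95 * s  # canvas center
    cy = 0.45 * s
    xs = cx + u * s
    top = cy - half_w
    bot = cy + half_w
    poly_x = np.concatenate([xs, xs[::-1]])
    poly_y = np.concatenate([top, bot[::-1]])

    canvas = np.zeros((int(0.9 * s) + 2, int(1.9 * s) + 2), dtype=bool)
    rr, cc = draw_polygon(poly_y, poly_x, shape=canvas.shape)
    canvas[rr, cc] = True

    # two claw lobes reaching forward from the head (negative-u end)
    for sign in (-1.0, 1.0):
        ang = rng.normal(0.18, 0.03)
        claw_u = np.linspace(-0.92, -0.35, 8)
        claw_c = cy + sign * (0.16 * s + (claw_u + 0.92) * np.tan(ang) * s * 0.4)
        claw_x = cx + claw_u * s
        cw = np.full_like(claw_u, 0.045 * s)
        px = np.concatenate([claw_x, claw_x[::-1]])
        py = np.concatenate([claw_c - cw, (claw_c + cw)[::-1]])
        rr, cc = draw_polygon(py, px, shape=canvas.shape)
        canvas[rr, cc] = True

    # trim to tight bounding box
    rows = np.flatnonzero(canvas.any(axis=1))
    cols = np.flatnonzero(canvas.any(axis=0))
    return canvas[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return (int(cols[0]), int(rows[0]), int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1))


@dataclass
class _Target:
    track_id: int
    shape: np.ndarray
    color: np.ndarray
    x0: float  # top-left x at entry frame (may be negative: off-frame)
    y0: float
    vx: float
    vy: float
    entry: int


class SceneRenderer:
    """Deterministic renderer for a :class:`SceneSpec`.

    Frames can be streamed repeatedly via :meth:`frames`; the ground truth is
    computed once from the same target parameters, so annotation and pixels
    always agree.
    """

    def __init__(self, spec: SceneSpec):
        self.spec = spec
        h, w = spec.size
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xC0]))
        self.targets: list[_Target] = []

        if spec.entry_times is not None:
            entries = list(spec.entry_times)
            if len(entries) != spec.n_targets:
                raise ConfigError("entry_times length must equal n_targets")
        else:
            # after the background-training window, staggered so targets
            # never overlap in the default single-file presets
            entries = [150 + i * 60 for i in range(spec.n_targets)]

        lane_h = max(1, (h - int(0.6 * spec.target_scale)) // max(1, spec.n_targets))
        for i in range(spec.n_targets):
            shape = make_target_shape(spec.target_scale, seed=int(rng.integers(2**31)))
            sh, sw = shape.shape
            if sh >= h or sw >= w:
                raise ConfigError("target larger than frame")
            color = spec.target_rgb() + rng.uniform(-spec.color_jitter, spec.color_jitter, 3)
            color = np.clip(color, 0.0, 1.0)
            speed = max(0.5, spec.speed + rng.normal(0.0, spec.speed_jitter))
            vy = rng.normal(0.0, 0.1)
            y0 = float(np.clip(i * lane_h + rng.uniform(0, max(1, lane_h - sh)), 0, h - sh - 1))
            self.targets.append(
                _Target(
                    track_id=i + 1,
                    shape=shape,
                    color=color,
                    x0=-float(sw),
                    y0=y0,
                    vx=speed,
                    vy=vy,
                    entry=entries[i],
                )
            )

        # static illumination gradient: brighter toward the light source at top
        yy = np.linspace(1.0, 0.0, h)[:, None]
        xx = np.linspace(-0.5, 0.5, w)[None, :]
        self._illum = 1.0 + spec.illumination_gradient * (yy - 0.5) - 0.2 * spec.illumination_gradient * xx**2
        self._background = np.clip(
            spec.background_rgb[None, None, :] * self._illum[:, :, None], 0.0, 1.0
        )

    def _target_position(self, t: _Target, frame: int) -> tuple[float, float]:
        dt = frame - t.entry
        return (t.x0 + t.vx * dt, t.y0 + t.vy * dt)

    def _paste(self, frame_px: np.ndarray, mask_out: np.ndarray | None, t: _Target, frame: int) -> np.ndarray | None:
        """Composite target into frame; returns the in-frame instance mask or None."""
        h, w = self.spec.size
        sh, sw = t.shape.shape
        x, y = self._target_position(t, frame)
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(0, xi), min(w, xi + sw)
        y0, y1 = max(0, yi), min(h, yi + sh)
        if x0 >= x1 or y0 >= y1:
            return None
        sub = t.shape[y0 - yi : y1 - yi, x0 - xi : x1 - xi]
        if not sub.any():
            return None
        if frame_px is not None:
            region = frame_px[y0:y1, x0:x1]
            region[sub] = t.color * self._illum[y0:y1, x0:x1][sub, None]
        if mask_out is not None:
            mask_out[y0:y1, x0:x1][sub] = True
            return mask_out
        return None

    def frames(self) -> Iterator[np.ndarray]:
        """Stream unit-scale RGB frames; identical across invocations."""
        spec = self.spec
        h, w = spec.size
        for f in range(spec.n_frames):
            px = self._background.copy()
            for t in self.targets:
                if f >= t.entry:
                    self._paste(px, None, t, f)
            if spec.noise_sigma > 0:
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence([int(spec.seed), 0xF0, f])
                )
                px = px + noise_rng.normal(0.0, spec.noise_sigma, px.shape)
            yield np.clip(px, 0.0, 1.0)

    def ground_truth(self) -> GroundTruth:
        spec = self.spec
        h, w = spec.size
        instances: list[list[tuple[int, np.ndarray, tuple[int, int, int, int]]]] = []
        trajectories: dict[int, list[tuple[int, float, float]]] = {}
        for f in range(spec.n_frames):
            per_frame = []
            for t in self.targets:
                if f < t.entry:
                    continue
                mask = np.zeros((h, w), dtype=bool)
                if self._paste(None, mask, t, f) is None:
                    continue
                bbox = _tight_bbox(mask)
                ys, xs = np.nonzero(mask)
                per_frame.append((t.track_id, mask, bbox))
                trajectories.setdefault(t.track_id, []).append(
                    (f, float(xs.mean()), float(ys.mean()))
                )
            instances.append(per_frame)
        return GroundTruth(
            instances=instances,
            trajectories=trajectories,
            total_count=len(trajectories),
        )


def render_video(spec: SceneSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Render all frames into memory together with the exact ground truth."""
    r = SceneRenderer(spec)
    return list(r.frames()), r.ground_truth()


def make_still(spec: SceneSpec, with_target: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Render a single frame with the target centered, plus its exact mask.

    Used for segmentation experiments, emulating still photographs of an
    animal fixed in front of a colored background.
    """
    h, w = spec.size
    r = SceneRenderer(replace(spec, n_targets=1 if with_target else 0, n_frames=1, entry_times=(0,) if with_target else None))
    if with_target:
        t = r.targets[0]
        sh, sw = t.shape.shape
        t.x0 = (w - sw) / 2.0
        t.y0 = (h - sh) / 2.0
        t.vx = 0.0
        t.vy = 0.0
    frame = next(r.frames())
    mask = np.zeros((h, w), dtype=bool)
    if with_target:
        r._paste(None, mask, r.targets[0], 0)
    return frame, mask


def copy_paste_augment(
    fg_img: np.ndarray,
    fg_mask: np.ndarray,
    bg_img: np.ndarray,
    bg_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Composite the foreground of one image onto another, no geometric transform.

    The output pixel is the foreground image wherever its mask is set and the
    background image elsewhere; the output ground-truth mask is the binary OR
    of the two input masks.
    """
    fg_img = np.asarray(fg_img, dtype=float)
    bg_img = np.asarray(bg_img, dtype=float)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not (fg_img.shape == bg_img.shape and fg_mask.shape == bg_mask.shape == fg_img.shape[:2]):
        raise ConfigError("copy-paste inputs must share one raster size")
    out = np.where(fg_mask[..., None], fg_img, bg_img)
    return out, fg_mask | bg_mask
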