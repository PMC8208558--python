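"""End-to-end detect → track → count over a frame stream."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .detection import DetectorConfig, DetectorState, detect_frame
from .tracking import CountReport, TrackerConfig, TrackerState, finalize_count, step

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: CountReport
    tracker: TrackerState
    config: TrackerConfig
    detections_per_frame: list[int] = field(default_factory=list)


def count_stream(
    frames: Iterable[np.ndarray],
    detector_config: DetectorConfig | None = None,
    tracker_config: TrackerConfig | None = None,
) -> PipelineResult:
    """Run the fused detector and the tracker over frames, then tally tracks.

    Frames are consumed one at a time; memory use is constant in the length
    of the video.
    """
    det_cfg = detector_config or DetectorConfig()
    trk_cfg = tracker_config or TrackerConfig()
    det_state = DetectorState(config=det_cfg)
    trk_state = TrackerState()
    n_dets: list[int] = []
    for i, frame in enumerate(frames):
        detections, det_state = detect_frame(det_state, frame, i)
        trk_state = step(trk_state, detections, i, trk_cfg)
        n_dets.append(len(detections))
        if detections:
            log.info("frame %d: %d detection(s)", i, len(detections))
    report = finalize_count(trk_state, trk_cfg)
    return PipelineResult(
        report=report,
        tracker=trk_state,
        config=trk_cfg,
        detections_per_frame=n_dets,
    )


def tracks_to_mot_rows(result: PipelineResult) -> list[tuple]:
    """MOT-style rows (frame, id, x, y, w, h, conf) for counted tracks."""
    from .tracking import counted_tracks

    rows = []
    for t in counted_tracks(result.tracker, result.config):
        for f, x, y in t.history:
            bbox = t.bboxes.get(f)
            if bbox is not None:
                bx, by, bw, bh = bbox
            else:  # coasted frame: synthesize a box around the predicted centroid
                bw = bh = 0
                bx, by = int(round(x)), int(round(y))
            rows.append((f, t.id, bx, by, bw, bh, 1.0))
    rows.sort(key=lambda r: (r[0], r[1]))
    return rows
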