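"""BOLD head-motion quality control.

A session's realignment parameters (3 translations in mm, 3 rotations in
radians per frame) are summarized as framewise displacement (FD) in the
Power convention: the sum of absolute backward differences of the six
parameters, with rotations converted to arc length on a sphere of
``head_radius_mm``. A scan fails QC if any frame's FD exceeds ``max_fd``
(default 3 mm) or the mean FD exceeds ``max_mean_fd`` (default 1 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "QCReport",
    "framewise_displacement",
    "qc_bold",
    "read_motion_trace",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_MAX_FD_MM = 3.0
DEFAULT_MAX_MEAN_FD_MM = 1.0

#: Visual checks the automated gate cannot perform; carried on every report.
MANUAL_CHECKLIST = (
    "image artifacts",
    "long-lasting intensity changes in carpet plot",
    "full head coverage on T1",
    "incidental findings on T1",
)


@dataclass
class MotionTrace:
    """Per-frame rigid-motion parameters: columns tx, ty, tz (mm), rx, ry, rz (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be an (n_frames, 6) array")
        if not np.isfinite(self.params).all():
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class QCReport:
    passed: bool
    reasons: list[str]
    fd_max: float
    fd_mean: float
    manual_checklist: tuple[str, ...] = field(default=MANUAL_CHECKLIST)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "pass": self.passed,
            "reasons": self.reasons,
            "fd_max": self.fd_max,
            "fd_mean": self.fd_mean,
            "manual_checklist": list(self.manual_checklist),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def framewise_displacement(
    trace: MotionTrace, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-frame FD; the first frame has FD 0 by convention.

    FD_t = sum |Delta translation| + head_radius * sum |Delta rotation|.
    """
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames to compute FD")
    diffs = np.abs(np.diff(trace.params, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def qc_bold(
    fd: np.ndarray,
    max_fd: float = DEFAULT_MAX_FD_MM,
    max_mean_fd: float = DEFAULT_MAX_MEAN_FD_MM,
) -> QCReport:
    """Apply the motion gate; reasons list every rule violated.

    The mean includes the zero-valued first frame.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    reasons = []
    fd_max = float(fd.max())
    fd_mean = float(fd.mean())
    if fd_max > max_fd:
        reasons.append(f"max FD exceeded: {fd_max:.3f} mm > {max_fd:g} mm")
    if fd_mean > max_mean_fd:
        reasons.append(f"mean FD exceeded: {fd_mean:.3f} mm > {max_mean_fd:g} mm")
    return QCReport(passed=not reasons, reasons=reasons, fd_max=fd_max, fd_mean=fd_mean)


def read_motion_trace(path: str | Path) -> MotionTrace:
    """Read a 6-column whitespace- or tab-delimited motion-parameter file."""
    table = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if table.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {table.shape[1]}")
    return MotionTrace(table.to_numpy(dtype=float))
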