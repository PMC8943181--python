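"""Operation design: randomized factors and instrument-protocol windows.

Each operation carries three two-level factors — smoke-evacuation-system use
(randomized 1:1 in blocks), surgical approach (open vs minimally invasive,
decided before randomization) and measurement location (inlet at surgeon
level vs in room air) — plus the instrument protocol bracketing the
operation: a pre-operation blank, a standard-gas calibration window and a
post-operation blank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError

__all__ = ["APPROACHES", "SES_LEVELS", "LOCATIONS", "OperationDesign"]

APPROACHES = ("open", "minimally_invasive")
SES_LEVELS = ("with_ses", "without_ses")
LOCATIONS = ("surgeon_level", "room_air")

Window = tuple[float, float]


def _check_window(name: str, w: Window) -> None:
    if not (w[0] >= 0 and w[1] >= w[0]):
        raise ValidationError(f"{name} window {w} is not a valid [start, end) interval")


def _overlap(a: Window, b: Window) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class OperationDesign:
    """Factor labels and protocol windows for one operation.

    ``duration`` is the length of the operation segment in seconds; the
    blank/calibration windows are ``[start, end)`` intervals in seconds from
    record start and must not overlap the operation segment, which runs from
    ``operation_start`` to ``operation_start + duration``.
    """

    op_id: str
    approach: str
    ses: str
    location: str
    duration: float
    blank_pre_window: Window = (0.0, 60.0)
    calib_window: Window = (60.0, 120.0)
    blank_post_window: Window | None = None
    operation_start: float = 120.0

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValidationError(f"approach must be one of {APPROACHES}, got {self.approach!r}")
        if self.ses not in SES_LEVELS:
            raise ValidationError(f"ses must be one of {SES_LEVELS}, got {self.ses!r}")
        if self.location not in LOCATIONS:
            raise ValidationError(f"location must be one of {LOCATIONS}, got {self.location!r}")
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        _check_window("blank_pre", self.blank_pre_window)
        _check_window("calib", self.calib_window)
        if self.blank_post_window is None:
            object.__setattr__(
                self,
                "blank_post_window",
                (self.operation_end, self.operation_end + 90.0),
            )
        _check_window("blank_post", self.blank_post_window)
        op = (self.operation_start, self.operation_end)
        windows = {
            "blank_pre": self.blank_pre_window,
            "calib": self.calib_window,
            "blank_post": self.blank_post_window,
            "operation": op,
        }
        labels = list(windows)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if _overlap(windows[a], windows[b]):
                    raise ValidationError(f"windows {a} and {b} overlap: {windows[a]} / {windows[b]}")
        if self.blank_pre_window[1] > self.operation_start:
            raise ValidationError("pre-operation blank must precede the operation segment")
        if self.blank_post_window[0] < self.operation_end:
            raise ValidationError("post-operation blank must follow the operation segment")

    @property
    def operation_end(self) -> float:
        return self.operation_start + self.duration

    @property
    def record_end(self) -> float:
        """End of the full record (last protocol window)."""
        return max(self.blank_post_window[1], self.operation_end)

    def segments(self) -> dict[str, Window]:
        """Segment windows keyed by the labels the signal stage expects."""
        return {
            "blank_pre": self.blank_pre_window,
            "calib": self.calib_window,
            "operation": (self.operation_start, self.operation_end),
            "blank_post": self.blank_post_window,
        }

    def to_dict(self) -> dict:
        return {
            "op_id": self.op_id,
            "approach": self.approach,
            "ses": self.ses,
            "location": self.location,
            "duration": float(self.duration),
            "blank_pre_window": [float(x) for x in self.blank_pre_window],
            "calib_window": [float(x) for x in self.calib_window],
            "blank_post_window": [float(x) for x in self.blank_post_window],
            "operation_start": float(self.operation_start),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "OperationDesign":
        def win(key):
            v = d.get(key)
            if v is None:
                return None
            if isinstance(v, str):
                v = [float(x) for x in v.strip("[]() ").split(",")]
            return (float(v[0]), float(v[1]))

        return cls(
            op_id=str(d["op_id"]),
            approach=str(d["approach"]),
            ses=str(d["ses"]),
            location=str(d["location"]),
            duration=float(d["duration"]),
            blank_pre_window=win("blank_pre_window") or (0.0, 60.0),
            calib_window=win("calib_window") or (60.0, 120.0),
            blank_post_window=win("blank_post_window"),
            operation_start=float(d.get("operation_start", 120.0)),
        )
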