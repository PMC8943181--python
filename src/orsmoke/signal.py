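"""Per-operation VOC time-series processing.

An :class:`IonTimeSeries` holds one operation's concentration matrix (ppb by
volume, one column per ion/compound, nominally on a 1 s grid) together with
labelled segments: a pre-operation instrument blank, a standard-gas
calibration window, the operation itself, and a post-operation blank.

Processing follows the instrument protocol of the measurement campaign the
simulator emulates: the channel-wise mean over the pre-operation blank is
subtracted from every sample, a single sensitivity factor per channel is
derived from the calibration segment, and per-operation summaries (mean,
maximum and time-of-maximum over the operation segment only) feed the
exposure and statistics stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import OperationDesign
from .errors import CalibrationError, FormatError, ProcessingError, ValidationError

__all__ = [
    "IonTimeSeries",
    "OperationSummary",
    "subtract_blank",
    "calibrate",
    "total_voc",
    "summarize_operation",
    "read_series",
    "write_series",
    "summaries_to_frames",
    "frames_to_summaries",
    "write_summaries",
    "read_summaries",
]

SEGMENT_NAMES = ("blank_pre", "calib", "operation", "blank_post")


@dataclass
class IonTimeSeries:
    """One operation's multichannel concentration record.

    Parameters
    ----------
    op_id:
        Operation identifier.
    data:
        DataFrame indexed by time (seconds from record start, strictly
        increasing) with one column per channel, values in ppb by volume.
        Negative values are permitted (they arise after blank subtraction).
    segments:
        Mapping of segment label to half-open ``[start, end)`` interval in
        seconds.  ``operation`` must be present and non-empty.
    uncalibrated_channels:
        Channels that :func:`calibrate` left untouched for lack of a
        standard-gas concentration.
    """

    op_id: str
    data: pd.DataFrame
    segments: dict[str, tuple[float, float]]
    uncalibrated_channels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.data.shape[1] < 1:
            raise ValidationError(f"{self.op_id}: at least one channel required")
        t = self.data.index.to_numpy(dtype=float)
        if not np.all(np.isfinite(t)) or np.any(np.diff(t) <= 0):
            raise ValidationError(f"{self.op_id}: time axis must be finite, strictly increasing")
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValidationError(f"{self.op_id}: concentrations must be finite")
        if "operation" not in self.segments:
            raise ValidationError(f"{self.op_id}: missing operation segment")
        if len(self.segment("operation")) == 0:
            raise ValidationError(f"{self.op_id}: empty operation segment")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def time(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    def segment(self, name: str) -> pd.DataFrame:
        """Samples falling in a labelled half-open window."""
        if name not in self.segments:
            raise KeyError(name)
        start, end = self.segments[name]
        t = self.data.index.to_numpy(dtype=float)
        return self.data.loc[(t >= start) & (t < end)]


def subtract_blank(series: IonTimeSeries) -> IonTimeSeries:
    """Subtract the pre-operation instrument blank from every sample.

    The channel-wise mean over the ``blank_pre`` segment is removed from the
    whole record; segment labels are preserved.  Negative results are kept —
    clipping would bias downstream means and totals upward.
    """
    if "blank_pre" not in series.segments or len(series.segment("blank_pre")) == 0:
        raise ProcessingError(f"{series.op_id}: no pre-operation blank segment to subtract")
    blank_mean = series.segment("blank_pre").mean(axis=0)
    return replace(series, data=series.data - blank_mean)


def calibrate(series: IonTimeSeries, standard_ppb: Mapping[str, float]) -> IonTimeSeries:
    """Apply single-point standard-gas calibration per channel.

    For each channel with a known standard concentration, the sensitivity
    factor ``standard_ppb / mean(calibration segment)`` multiplies every
    sample.  Channels without a standard are left unchanged and flagged in
    ``uncalibrated_channels``.
    """
    if "calib" not in series.segments or len(series.segment("calib")) == 0:
        raise ProcessingError(f"{series.op_id}: no calibration segment")
    calib_mean = series.segment("calib").mean(axis=0)
    factors = pd.Series(1.0, index=series.data.columns)
    flagged = []
    for channel in series.data.columns:
        if channel not in standard_ppb:
            flagged.append(channel)
            continue
        std = standard_ppb[channel]
        if std <= 0:
            raise CalibrationError(f"{series.op_id}/{channel}: standard concentration must be > 0")
        if calib_mean[channel] <= 0:
            raise CalibrationError(
                f"{series.op_id}/{channel}: calibration-segment mean is not positive"
            )
        factors[channel] = std / calib_mean[channel]
    return replace(
        series,
        data=series.data * factors,
        uncalibrated_channels=frozenset(flagged),
    )


def total_voc(series: IonTimeSeries, channel_subset: Sequence[str] | str = "all",
              name: str = "total_voc") -> IonTimeSeries:
    """Pointwise sum over a channel subset as a single-channel series.

    With the harmful-panel names as the subset this yields the "harmful
    total" trace; ``"all"`` sums every channel (the total-VOC trace).
    """
    if isinstance(channel_subset, str):
        if channel_subset != "all":
            raise KeyError(channel_subset)
        subset = series.channels
    else:
        unknown = [c for c in channel_subset if c not in series.data.columns]
        if unknown:
            raise KeyError(f"unknown channels {unknown}")
        subset = list(channel_subset)
    total = series.data[subset].sum(axis=1).to_frame(name=name)
    return replace(series, data=total)


@dataclass
class OperationSummary:
    """Per-operation summary statistics over the operation segment.

    ``channel_stats`` is indexed by channel with columns ``mean_ppb``,
    ``max_ppb`` and ``argmax_time_fraction`` (time of the first maximum,
    as a fraction of the operation-segment length).
    """

    op_id: str
    channel_stats: pd.DataFrame
    total_voc_mean_ppb: float
    total_voc_max_ppb: float
    harmful_total_mean_ppb: float
    harmful_total_max_ppb: float
    design: OperationDesign

    def __post_init__(self) -> None:
        cs = self.channel_stats
        if (cs["mean_ppb"] > cs["max_ppb"] + 1e-9).any():
            raise ValidationError(f"{self.op_id}: channel mean exceeds channel max")
        frac = cs["argmax_time_fraction"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValidationError(f"{self.op_id}: argmax time fraction outside [0, 1]")

    def response(self, name: str) -> float:
        """Scalar response by name, for the statistics stage.

        Totals are addressed directly (e.g. ``"harmful_total_mean_ppb"``);
        per-channel statistics as ``"mean:<channel>"``, ``"max:<channel>"``
        or ``"argmax:<channel>"``.
        """
        if ":" in name:
            stat, _, channel = name.partition(":")
            column = {"mean": "mean_ppb", "max": "max_ppb", "argmax": "argmax_time_fraction"}[stat]
            return float(self.channel_stats.loc[channel, column])
        return float(getattr(self, name))


def _segment_summary(frame: pd.DataFrame, start: float, length: float) -> pd.DataFrame:
    means = frame.mean(axis=0)
    maxima = frame.max(axis=0)
    # idxmax returns the first time at which the maximum occurs (earliest tie)
    argmax_frac = (frame.idxmax(axis=0).astype(float) - start) / length
    return pd.DataFrame(
        {"mean_ppb": means, "max_ppb": maxima, "argmax_time_fraction": argmax_frac}
    )


def summarize_operation(
    series: IonTimeSeries,
    design: OperationDesign,
    registry=None,
) -> OperationSummary:
    """Summarize one operation: per-channel and total statistics.

    Statistics are computed over the operation segment only — blanks and
    calibration windows describe the instrument, not the exposure.  The
    harmful totals sum the channels named in ``registry`` (all channels when
    no registry is given).
    """
    op = series.segment("operation")
    if len(op) == 0:
        raise ProcessingError(f"{series.op_id}: empty operation segment")
    start, end = series.segments["operation"]
    stats = _segment_summary(op, start, end - start)

    total = op.sum(axis=1)
    if registry is not None:
        panel = [c for c in series.channels if c in registry]
    else:
        panel = series.channels
    harmful = op[panel].sum(axis=1) if panel else pd.Series(0.0, index=op.index)

    return OperationSummary(
        op_id=series.op_id,
        channel_stats=stats,
        total_voc_mean_ppb=float(total.mean()),
        total_voc_max_ppb=float(total.max()),
        harmful_total_mean_ppb=float(harmful.mean()),
        harmful_total_max_ppb=float(harmful.max()),
        design=design,
    )


# ---------------------------------------------------------------------------
# File formats: delimited series + structured sidecar, and summary tables.


def write_series(series: IonTimeSeries, csv_path: str | Path,
                 meta_path: str | Path | None = None,
                 design: OperationDesign | None = None,
                 extra_meta: Mapping | None = None) -> None:
    """Write a series as ``time_s,<channel>,...`` CSV plus a YAML sidecar."""
    csv_path = Path(csv_path)
    out = series.data.copy()
    out.insert(0, "time_s", series.time)
    out.to_csv(csv_path, index=False)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.yaml")
    meta: dict = {
        "op_id": series.op_id,
        "segments": {k: [float(a), float(b)] for k, (a, b) in series.segments.items()},
        "uncalibrated_channels": sorted(series.uncalibrated_channels),
    }
    if design is not None:
        meta["design"] = design.to_dict()
    if extra_meta:
        meta.update(dict(extra_meta))
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))


def read_series(csv_path: str | Path,
                meta_path: str | Path | None = None) -> tuple[IonTimeSeries, OperationDesign | None]:
    """Read a series written by :func:`write_series`."""
    csv_path = Path(csv_path)
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.yaml")
    frame = pd.read_csv(csv_path)
    if "time_s" not in frame.columns:
        raise FormatError(f"{csv_path}: missing time_s column")
    meta = yaml.safe_load(meta_path.read_text())
    series = IonTimeSeries(
        op_id=str(meta["op_id"]),
        data=frame.set_index("time_s"),
        segments={k: (float(v[0]), float(v[1])) for k, v in meta["segments"].items()},
        uncalibrated_channels=frozenset(meta.get("uncalibrated_channels", [])),
    )
    design = OperationDesign.from_dict(meta["design"]) if "design" in meta else None
    return series, design


def summaries_to_frames(summaries: Iterable[OperationSummary]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries as (per-operation totals table, long-format channel table)."""
    totals_rows, channel_rows = [], []
    for s in summaries:
        totals_rows.append(
            {
                "op_id": s.op_id,
                **s.design.to_dict(),
                "total_voc_mean_ppb": s.total_voc_mean_ppb,
                "total_voc_max_ppb": s.total_voc_max_ppb,
                "harmful_total_mean_ppb": s.harmful_total_mean_ppb,
                "harmful_total_max_ppb": s.harmful_total_max_ppb,
            }
        )
        cs = s.channel_stats.reset_index(names="channel")
        cs.insert(0, "op_id", s.op_id)
        channel_rows.append(cs)
    totals = pd.DataFrame(totals_rows)
    channels = pd.concat(channel_rows, ignore_index=True) if channel_rows else pd.DataFrame(
        columns=["op_id", "channel", "mean_ppb", "max_ppb", "argmax_time_fraction"]
    )
    return totals, channels


def frames_to_summaries(totals: pd.DataFrame, channels: pd.DataFrame) -> list[OperationSummary]:
    """Inverse of :func:`summaries_to_frames`."""
    out = []
    grouped = dict(tuple(channels.groupby("op_id", sort=False))) if len(channels) else {}
    for row in totals.itertuples(index=False):
        d = row._asdict()
        cs = grouped.get(d["op_id"])
        if cs is None:
            cs = pd.DataFrame(columns=["channel", "mean_ppb", "max_ppb", "argmax_time_fraction"])
        cs = cs.set_index("channel")[["mean_ppb", "max_ppb", "argmax_time_fraction"]]
        out.append(
            OperationSummary(
                op_id=d["op_id"],
                channel_stats=cs,
                total_voc_mean_ppb=d["total_voc_mean_ppb"],
                total_voc_max_ppb=d["total_voc_max_ppb"],
                harmful_total_mean_ppb=d["harmful_total_mean_ppb"],
                harmful_total_max_ppb=d["harmful_total_max_ppb"],
                design=OperationDesign.from_dict(d),
            )
        )
    return out


def write_summaries(summaries: Iterable[OperationSummary],
                    totals_path: str | Path, channels_path: str | Path) -> None:
    totals, channels = summaries_to_frames(summaries)
    totals.to_csv(totals_path, index=False)
    channels.to_csv(channels_path, index=False)


def read_summaries(totals_path: str | Path, channels_path: str | Path) -> list[OperationSummary]:
    return frames_to_summaries(pd.read_csv(totals_path), pd.read_csv(channels_path))
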