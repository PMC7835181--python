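"""Frame schedules, time-activity curves and regional extraction.

Conventions
-----------
* Internal time unit is the second; user-facing protocol descriptions use
  minutes.  Frames are half-open intervals ``[start, end)`` and every numeric
  routine evaluates a curve at the frame midpoint.
* Brain TACs are decay-corrected to injection time (kBq/mL); whole-body
  dosimetry TACs are *not* decay-corrected and are expressed as fraction of
  injected activity.
* Cumulative integrals treat the TAC as piecewise linear through ``(0, 0)``
  and the frame midpoints (bolus injection at t = 0, no pre-injection
  activity); after the last midpoint the curve is held constant.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ScheduleError, StateError, ValidationError

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.771

_TOKEN_RE = re.compile(r"^\s*(\d+)\s*x\s*(\d+(?:\.\d+)?)\s*s\s*$")


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame boundaries in seconds.

    Frames must be strictly increasing and non-overlapping; gaps between
    frames are permitted (coffee-break acquisitions).
    """

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape:
            raise ScheduleError("frame_start and frame_end must be 1-D and congruent")
        if start.size:
            if np.any(end <= start):
                raise ScheduleError("all frame durations must be positive")
            if np.any(np.diff(start) <= 0):
                raise ScheduleError("frame starts must be strictly increasing")
            if np.any(start[1:] < end[:-1] - 1e-9):
                raise ScheduleError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    def __len__(self) -> int:
        return self.n_frames

    @property
    def duration(self) -> float:
        """End of the last frame, seconds."""
        return float(self.end[-1]) if self.n_frames else 0.0

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoints, seconds."""
        return (self.start + self.end) / 2.0

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, mask: np.ndarray) -> "FrameSchedule":
        mask = np.asarray(mask, dtype=bool)
        return FrameSchedule(self.start[mask], self.end[mask])


def parse_frame_schedule(spec: str) -> FrameSchedule:
    """Parse a compact frame specification such as ``"6x15s,3x30s"``.

    Each comma-separated token is ``<count>x<duration>s``.  Frames are
    contiguous and start at t = 0.  The printed 31-frame/120-min protocol is
    ``"6x15s,3x30s,3x60s,2x90s,2x180s,9x300s,6x600s"``.
    """
    durations: list[float] = []
    for token in spec.split(","):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ScheduleError(f"malformed frame token {token.strip()!r}")
        count, dur = int(m.group(1)), float(m.group(2))
        if count < 1 or dur <= 0:
            raise ScheduleError(f"malformed frame token {token.strip()!r}")
        durations.extend([dur] * count)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    return FrameSchedule(edges[:-1], edges[1:])


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint of each frame, seconds."""
    return schedule.midpoints


@dataclass
class TimeActivityCurve:
    """Activity concentration per frame.

    ``activity`` is kBq/mL for imaging TACs or fraction of injected activity
    for whole-body organ TACs (``units="fraction_injected"``).  Negative
    values are tolerated (reconstruction noise) but flagged.
    """

    schedule: FrameSchedule
    activity: np.ndarray
    decay_corrected: bool = True
    reference_time: float = 0.0
    label: str = ""
    units: str = "kBq/mL"

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValidationError(
                f"activity length {self.activity.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.activity)):
            raise ValidationError("activity values must be finite")

    @property
    def has_negative_values(self) -> bool:
        return bool(np.any(self.activity < 0))

    @property
    def midpoints(self) -> np.ndarray:
        return self.schedule.midpoints


def decay_correct(
    tac: TimeActivityCurve,
    half_life_min: float = F18_HALF_LIFE_MIN,
    to_reference: bool = True,
) -> TimeActivityCurve:
    """Apply (or remove) physical decay correction at frame midpoints.

    With ``to_reference=True`` the measured activity is multiplied by
    ``2**(t_mid / half_life)`` referring it back to injection time; with
    ``to_reference=False`` the correction is undone.  The two directions are
    exact inverses.  Applying a correction twice raises :class:`StateError`.
    """
    if half_life_min <= 0:
        raise ValidationError("half_life must be positive")
    if to_reference and tac.decay_corrected:
        raise StateError(f"TAC {tac.label!r} is already decay-corrected")
    if not to_reference and not tac.decay_corrected:
        raise StateError(f"TAC {tac.label!r} is not decay-corrected")
    factor = np.exp2((tac.midpoints - tac.reference_time) / (half_life_min * 60.0))
    activity = tac.activity * factor if to_reference else tac.activity / factor
    return replace(tac, activity=activity, decay_corrected=to_reference)


def cumulative_integral(tac: TimeActivityCurve, t) -> np.ndarray | float:
    """Integral of the TAC from 0 to ``t`` (seconds), trapezoid rule.

    The curve is anchored at ``(0, 0)``, linear between frame midpoints and
    constant after the last midpoint.  Works across schedule gaps (the
    trapezoid between the midpoints flanking a gap bridges it linearly).
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValidationError("integration time must be non-negative")
    if tac.schedule.n_frames and np.any(t_arr > tac.schedule.duration + 1e-9):
        raise ValidationError("integration time beyond last frame end")
    nodes = np.concatenate([[0.0], tac.midpoints])
    vals = np.concatenate([[0.0], tac.activity])
    seg = np.diff(nodes)
    cum = np.concatenate([[0.0], np.cumsum((vals[:-1] + vals[1:]) / 2.0 * seg)])
    idx = np.clip(np.searchsorted(nodes, t_arr, side="right") - 1, 0, nodes.size - 1)
    out = np.empty_like(t_arr)
    inner = idx < nodes.size - 1
    if np.any(inner):
        i = idx[inner]
        dt = t_arr[inner] - nodes[i]
        frac = dt / seg[i]
        v_t = vals[i] + frac * (vals[i + 1] - vals[i])
        out[inner] = cum[i] + (vals[i] + v_t) / 2.0 * dt
    tail = ~inner
    if np.any(tail):
        out[tail] = cum[-1] + vals[-1] * (t_arr[tail] - nodes[-1])
    return out if np.ndim(t) else float(out[0])


@dataclass
class DynamicVolume:
    """4-D dynamic image: voxel grid ``(x, y, z, frame)`` in kBq/mL."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("dynamic volume must be 4-D (x, y, z, frame)")
        if self.data.shape[-1] != self.schedule.n_frames:
            raise ValidationError("frame axis length must equal schedule length")


def extract_regional_tacs(
    volume: DynamicVolume,
    labels: np.ndarray,
    region_map: dict[int, str],
) -> tuple[dict[str, TimeActivityCurve], dict[str, int]]:
    """Mean TAC per labelled region.

    ``labels`` is an integer volume congruent with the dynamic grid;
    ``region_map`` maps label value to region name.  Labels present in the
    volume but absent from the map are skipped with a warning.  Returns
    ``(tacs, voxel_counts)``.
    """
    labels = np.asarray(labels)
    if labels.shape != volume.data.shape[:3]:
        raise ValidationError("label volume must be congruent with the dynamic grid")
    tacs: dict[str, TimeActivityCurve] = {}
    counts: dict[str, int] = {}
    present = np.unique(labels)
    unmapped = [int(v) for v in present if int(v) not in region_map and v != 0]
    if unmapped:
        warnings.warn(f"labels without region name skipped: {unmapped}", stacklevel=2)
    for value, name in region_map.items():
        mask = labels == value
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"region {name!r} (label {value}) has no voxels", stacklevel=2)
            continue
        mean_tac = volume.data[mask].mean(axis=0)
        tacs[name] = TimeActivityCurve(volume.schedule, mean_tac, label=name)
        counts[name] = n
    return tacs, counts


def write_tac_table(tacs: dict[str, TimeActivityCurve], path, sep: str = ",") -> None:
    """Write regional TACs as delimited text.

    Columns are ``frame_start_s, frame_end_s, <region>...``; all TACs must
    share one schedule.
    """
    items = list(tacs.items())
    if not items:
        raise ValidationError("no TACs to write")
    schedule = items[0][1].schedule
    for name, tac in items:
        if not np.array_equal(tac.schedule.start, schedule.start):
            raise ValidationError(f"TAC {name!r} has a different schedule")
    frame = {"frame_start_s": schedule.start, "frame_end_s": schedule.end}
    frame.update({name: tac.activity for name, tac in items})
    pd.DataFrame(frame).to_csv(path, sep=sep, index=False)


def read_tac_table(
    path,
    decay_corrected: bool = True,
    units: str = "kBq/mL",
) -> dict[str, TimeActivityCurve]:
    """Read a regional TAC table written by :func:`write_tac_table`.

    Comma- or tab-delimited text with a header row; a gap in the frame
    boundaries (coffee-break acquisition) is preserved in the schedule.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        # round_trip parsing keeps write->read exact to the last ulp
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows
        raise FormatError(f"cannot parse TAC table {path}: {exc}") from None
    for col in ("frame_start_s", "frame_end_s"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    start = df["frame_start_s"].to_numpy(dtype=float)
    if np.any(np.diff(start) <= 0):
        bad = int(np.argmax(np.diff(start) <= 0)) + 3  # header + 1-based + offset
        raise FormatError("frame_start_s not strictly increasing", line=bad)
    schedule = FrameSchedule(start, df["frame_end_s"].to_numpy(dtype=float))
    regions = [c for c in df.columns if c not in ("frame_start_s", "frame_end_s")]
    return {
        name: TimeActivityCurve(
            schedule,
            df[name].to_numpy(dtype=float),
            decay_corrected=decay_corrected,
            label=name,
            units=units,
        )
        for name in regions
    }


def read_dynamic_nifti(path, schedule: FrameSchedule) -> DynamicVolume:
    """Load a 4-D NIfTI dynamic series with a caller-supplied frame schedule."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return DynamicVolume(data, schedule, tuple(float(z) for z in zooms))


def read_label_nifti(path) -> np.ndarray:
    """Load a 3-D integer label volume from NIfTI."""
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj).astype(int)


def write_nifti(data: np.ndarray, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Write an array as NIfTI-1 with a diagonal affine from the voxel size."""
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    data = np.asarray(data)
    if data.dtype.kind in "iu":  # NIfTI-1 has no 64-bit integer type
        data = data.astype(np.int32)
    nib.save(nib.Nifti1Image(data, affine), str(path))
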