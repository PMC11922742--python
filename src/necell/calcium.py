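"""Calcium-trace activity calling for fluorescence time-lapse recordings.

Pipeline (the only supported order, recorded in output metadata):
complete-track filtering -> per-frame background subtraction -> per-cell
median normalization -> topographic-prominence peak calling at cutoff 0.1.
A cell is *active* iff it has at least one peak with prominence >= the
cutoff; per field of view the active fraction n_active / n_cells is the
summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "TraceMatrix",
    "Peak",
    "PeakCallResult",
    "PIPELINE_ORDER",
    "filter_complete",
    "subtract_background",
    "normalize_median",
    "call_peaks",
    "active_fraction",
    "analyze_fov",
]

PIPELINE_ORDER = ("filter_complete", "subtract_background",
                  "normalize_median", "call_peaks")


@dataclass
class TraceMatrix:
    """Per-cell fluorescence time series for one field of view.

    ``traces`` is cells x frames in arbitrary fluorescence units;
    ``background`` is the per-frame scalar background of the field of view
    (one background per field, not per-cell annuli).
    """

    fov_id: str
    traces: np.ndarray                    # (n_cells, n_frames)
    background: np.ndarray                # (n_frames,)
    complete_mask: np.ndarray             # (n_cells,) bool
    frame_interval: float = 2.0           # s (0.5 Hz)
    cell_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.background = np.asarray(self.background, dtype=float)
        self.complete_mask = np.asarray(self.complete_mask, dtype=bool)
        if self.background.shape != (self.traces.shape[1],):
            raise ValueError("background length must equal the frame count")
        if self.complete_mask.shape != (self.traces.shape[0],):
            raise ValueError("complete_mask length must equal the cell count")
        if not self.cell_ids:
            self.cell_ids = tuple(f"cell{i}" for i in range(self.traces.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class Peak:
    frame: int
    amplitude: float     # normalized units
    prominence: float


@dataclass(frozen=True)
class PeakCallResult:
    """Peak calls and the per-field activity summary."""

    fov_id: str
    peaks: dict[str, tuple[Peak, ...]]    # cell_id -> peaks
    active: dict[str, bool]
    n_cells: int
    n_active: int
    excluded_cells: tuple[str, ...]       # non-positive-median exclusions
    prominence_cutoff: float
    pipeline: tuple[str, ...] = PIPELINE_ORDER

    @property
    def active_fraction(self) -> float:
        if self.n_cells == 0:
            raise ValueError("active fraction undefined for an empty FOV")
        return self.n_active / self.n_cells


def filter_complete(tm: TraceMatrix) -> TraceMatrix:
    """Keep only cells segmented and tracked at every frame."""
    keep = tm.complete_mask
    return TraceMatrix(
        fov_id=tm.fov_id,
        traces=tm.traces[keep].reshape(int(keep.sum()), tm.n_frames),
        background=tm.background,
        complete_mask=np.ones(int(keep.sum()), dtype=bool),
        frame_interval=tm.frame_interval,
        cell_ids=tuple(c for c, k in zip(tm.cell_ids, keep) if k),
    )


def subtract_background(tm: TraceMatrix) -> TraceMatrix:
    """Subtract the per-frame field background from every cell trace.

    Values may go negative and are retained (not clipped)."""
    out = TraceMatrix(
        fov_id=tm.fov_id,
        traces=tm.traces - tm.background[None, :],
        background=np.zeros_like(tm.background),
        complete_mask=tm.complete_mask.copy(),
        frame_interval=tm.frame_interval,
        cell_ids=tm.cell_ids,
    )
    return out


def normalize_median(trace: np.ndarray) -> np.ndarray:
    """Normalize a single trace to its own median; the output has median 1.

    Raises for a non-positive median (callers exclude such cells with a
    logged reason rather than crashing a whole field of view)."""
    trace = np.asarray(trace, dtype=float)
    med = np.median(trace)
    if med <= 0:
        raise ValueError(f"non-positive median ({med}); cell excluded")
    return trace / med


def call_peaks(trace: np.ndarray, prominence_cutoff: float = 0.1,
               min_distance: int | None = None,
               min_width: float | None = None) -> tuple[Peak, ...]:
    """Local maxima with topographic prominence >= the cutoff.

    Prominence of a peak is its height above the higher of the two lowest
    valleys separating it from the nearest higher terrain (or trace edge).
    Plateau maxima take the plateau midpoint index (left-biased on even
    plateaus); first/last samples are not callable.  No minimum distance or
    width constraint is applied unless requested.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3:
        return ()
    kwargs: dict = {"prominence": prominence_cutoff}
    if min_distance is not None:
        kwargs["distance"] = min_distance
    if min_width is not None:
        kwargs["width"] = min_width
    idx, props = find_peaks(trace, **kwargs)
    return tuple(
        Peak(frame=int(i), amplitude=float(trace[i]), prominence=float(p))
        for i, p in zip(idx, props["prominences"])
    )


def active_fraction(result: PeakCallResult) -> float:
    """Fraction of complete-track cells with >= 1 supra-cutoff peak."""
    return result.active_fraction


def analyze_fov(tm: TraceMatrix, prominence_cutoff: float = 0.1,
                normalized_units: bool = True) -> PeakCallResult:
    """Run the full pipeline on one field of view.

    ``normalized_units=False`` applies the prominence cutoff on
    background-subtracted raw traces instead of median-normalized ones.
    """
    complete = filter_complete(tm)
    sub = subtract_background(complete)
    peaks: dict[str, tuple[Peak, ...]] = {}
    active: dict[str, bool] = {}
    excluded: list[str] = []
    for cid, trace in zip(sub.cell_ids, sub.traces):
        if normalized_units:
            try:
                trace = normalize_median(trace)
            except ValueError:
                excluded.append(cid)
                continue
        p = call_peaks(trace, prominence_cutoff)
        peaks[cid] = p
        active[cid] = len(p) > 0
    n_cells = len(active)
    return PeakCallResult(
        fov_id=tm.fov_id, peaks=peaks, active=active,
        n_cells=n_cells, n_active=sum(active.values()),
        excluded_cells=tuple(excluded),
        prominence_cutoff=prominence_cutoff,
    )
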