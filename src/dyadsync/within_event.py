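"""Within-event and within-movie-clip trajectory similarity.

Given an event segmentation (typically fitted to default-mode-network
activity pooled over all couples) or a table of movie-clip intervals, ISTS
is recomputed inside each window: trajectory matrices are built from the
window's TRs only, correlated between the dyad members, and the per-window
values are averaged (unweighted by default) into a single within-event ISTS
per dyad per ROI. Windows shorter than 3 TRs cannot support a trajectory
correlation and are skipped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Dataset, RoiTimeSeries, ValidationError, validate_clip_table
from .events import EventSegmenter
from .trajectory import IstsTable, build_trajectory_matrix, compute_ists

logger = logging.getLogger(__name__)

#: shortest usable window: 2 TRs give a single off-diagonal entry, from
#: which no correlation across dyad members' matrices can be formed
MIN_WINDOW_LENGTH = 3


@dataclass
class EventWindows:
    """Ordered, non-overlapping half-open TR intervals defining events.

    ``source`` records whether the windows came from an HMM segmentation
    (``"hmm"``) or from the movie-clip table (``"clips"``);
    ``n_skipped`` counts windows dropped for being shorter than
    :data:`MIN_WINDOW_LENGTH`.
    """

    source: str
    windows: list[tuple[int, int]]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.windows:
            if end - start < MIN_WINDOW_LENGTH:
                raise ValidationError(f"window [{start}, {end}) shorter than minimum")
            if start < prev_end:
                raise ValidationError("windows overlap or are unordered")
            prev_end = end


def build_event_windows(
    source: EventSegmenter | np.ndarray | pd.DataFrame,
    min_length: int = MIN_WINDOW_LENGTH,
) -> EventWindows:
    """Turn a fitted segmentation (or per-TR assignment, or clip table) into windows.

    HMM windows are the maximal runs of constant state assignment; clip
    windows are the table's ``[start_tr, end_tr)`` intervals. Windows
    shorter than ``min_length`` are filtered out and counted.
    """
    if isinstance(source, pd.DataFrame):
        clips = validate_clip_table(source)
        raw = list(zip(clips["start_tr"].astype(int), clips["end_tr"].astype(int)))
        kind = "clips"
    else:
        if isinstance(source, EventSegmenter):
            assignment = source.assignment_
        else:
            assignment = np.asarray(source, dtype=int)
        if np.any(np.diff(assignment) < 0):
            raise ValidationError("assignment violates the no-return constraint")
        change = np.flatnonzero(np.diff(assignment) != 0) + 1
        edges = [0, *change.tolist(), assignment.size]
        raw = list(zip(edges[:-1], edges[1:]))
        kind = "hmm"
    kept = [(s, e) for s, e in raw if e - s >= min_length]
    n_skipped = len(raw) - len(kept)
    if n_skipped:
        logger.warning("%d window(s) shorter than %d TRs skipped", n_skipped, min_length)
    if not kept:
        raise ValidationError("no usable windows after length filtering")
    return EventWindows(source=kind, windows=kept, n_skipped=n_skipped)


def within_window_ists(
    a_ts: RoiTimeSeries,
    b_ts: RoiTimeSeries,
    windows: EventWindows,
    length_weighted: bool = False,
) -> tuple[float, list[float]]:
    """Mean within-window ISTS for one dyad in one ROI.

    Builds a trajectory matrix per window per subject (from that window's
    TRs only), correlates them, and averages across windows. Windows where
    ISTS is undefined are skipped and excluded from the average; if none
    remain the result is NaN with a warning. A single window covering the
    whole run reduces exactly to full-run ISTS.
    """
    if a_ts.n_trs != b_ts.n_trs:
        raise ValidationError("dyad members have different run lengths")
    per_window: list[float] = []
    for start, end in windows.windows:
        tr_idx = np.arange(start, end)
        ma = build_trajectory_matrix(a_ts, tr_idx)
        mb = build_trajectory_matrix(b_ts, tr_idx)
        per_window.append(compute_ists(ma, mb))
    vals = np.asarray(per_window, dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        logger.warning(
            "within-window ISTS undefined in every window for %s/%s roi %d",
            a_ts.subject_id,
            b_ts.subject_id,
            a_ts.roi_id,
        )
        return float("nan"), per_window
    if length_weighted:
        lengths = np.array([e - s for s, e in windows.windows], dtype=float)
        mean = float(np.average(vals[ok], weights=lengths[ok]))
    else:
        mean = float(vals[ok].mean())
    return mean, per_window


def within_event_table(
    dataset: Dataset,
    windows: EventWindows,
    dyads: pd.DataFrame | None = None,
    length_weighted: bool = False,
) -> IstsTable:
    """Within-event (or within-clip) ISTS for every dyad and ROI.

    The same window set — e.g. events from the DMN segmentation fitted on
    all couples pooled — is applied to every ROI.
    """
    if dyads is None:
        dyads = dataset.dyads
    roi_ids = dataset.roi_ids
    out = np.empty((len(dyads), len(roi_ids)))
    for i, row in enumerate(dyads.itertuples(index=False)):
        for j, rid in enumerate(roi_ids):
            out[i, j], _ = within_window_ists(
                dataset.get(row.male_id, rid),
                dataset.get(row.female_id, rid),
                windows,
                length_weighted=length_weighted,
            )
    values = pd.DataFrame(
        out, index=pd.Index(dyads["dyad_id"], name="dyad_id"), columns=roi_ids
    )
    scope = "within_event" if windows.source == "hmm" else "within_clip"
    return IstsTable(
        values=values,
        dyads=dyads.reset_index(drop=True),
        scope=scope,
        extra={"n_windows": len(windows.windows), "n_skipped": windows.n_skipped},
    )
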