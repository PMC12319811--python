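"""Core data model shared by every stage of the pipeline.

The pipeline consumes pre-extracted regional voxel x TR matrices (one per
subject per ROI), a parcellation table assigning each ROI to one of seven
large-scale networks, a dyad table (married couples with a satisfaction
score, plus random male-female pairings used as the null class), and
optional run metadata (per-TR condition labels and movie-clip boundaries).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven canonical large-scale networks of the default 200-ROI scheme:
#: visual, somatomotor, dorsal attention, ventral attention, limbic,
#: central executive (frontoparietal) and default mode.
NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "CEN", "DMN")

#: Dyad classes: couples split by the satisfaction threshold, plus
#: non-couple random pairings (derangements of spouses).
DYAD_CLASSES = ("couple_high", "couple_low", "random")

#: Satisfaction score above which a couple counts as highly satisfied.
SATISFACTION_THRESHOLD = 60.0


class ValidationError(ValueError):
    """Raised when an input table or matrix violates the data model."""


@dataclass
class RoiTimeSeries:
    """Voxel x TR BOLD matrix for one subject in one region of interest.

    Parameters
    ----------
    subject_id : str
    roi_id : int
        1-based ROI index into the parcellation scheme.
    data : ndarray of shape (n_voxels, n_trs)
        BOLD signal, arbitrary units. Requires at least 3 voxels (a Pearson
        correlation across fewer voxels is degenerate) and at least 3 TRs
        (a trajectory matrix needs at least 3 time points).
    """

    subject_id: str
    roi_id: int
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(
                f"RoiTimeSeries {self.subject_id}/roi {self.roi_id}: "
                f"data must be 2-D (voxels x TRs), got ndim={self.data.ndim}"
            )
        v, t = self.data.shape
        if v < 3 or t < 3:
            raise ValidationError(
                f"RoiTimeSeries {self.subject_id}/roi {self.roi_id}: "
                f"needs >=3 voxels and >=3 TRs, got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError(
                f"RoiTimeSeries {self.subject_id}/roi {self.roi_id}: "
                "non-finite values present"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    def zero_variance_trs(self) -> np.ndarray:
        """TR indices whose multi-voxel pattern is constant across voxels."""
        return np.flatnonzero(self.data.std(axis=0) == 0)


@dataclass
class RunMetadata:
    """Optional per-run annotations.

    condition_mask maps each labelled TR to a condition (e.g. ``marital`` /
    ``non_marital``); unlabelled TRs carry no condition. clip_table lists
    movie-clip intervals as half-open, 0-based ``[start_tr, end_tr)``.
    """

    condition_mask: pd.DataFrame | None = None  # columns: tr, label
    clip_table: pd.DataFrame | None = None  # columns: clip_id, start_tr, end_tr, theme

    def condition_trs(self, label: str) -> np.ndarray:
        """Sorted TR indices carrying a given condition label."""
        if self.condition_mask is None:
            raise ValidationError("no condition mask available")
        m = self.condition_mask
        return np.sort(m.loc[m["label"] == label, "tr"].to_numpy(dtype=int))


def validate_parcellation(parcellation: pd.DataFrame) -> pd.DataFrame:
    """Validate a parcellation table (columns roi_id, roi_name, network)."""
    required = {"roi_id", "roi_name", "network"}
    missing = required - set(parcellation.columns)
    if missing:
        raise ValidationError(f"parcellation table missing columns {sorted(missing)}")
    if parcellation["roi_id"].duplicated().any():
        dupes = parcellation.loc[parcellation["roi_id"].duplicated(), "roi_id"]
        raise ValidationError(f"duplicate roi_id in parcellation: {list(dupes)}")
    bad = set(parcellation["network"]) - set(NETWORKS)
    if bad:
        raise ValidationError(f"unknown networks in parcellation: {sorted(bad)}")
    return parcellation.reset_index(drop=True)


def validate_dyads(dyads: pd.DataFrame) -> pd.DataFrame:
    """Validate a dyad table.

    Columns: dyad_id, male_id, female_id, dyad_class, cmqi_score,
    marriage_duration. Couples must be classed consistently with the
    satisfaction threshold; random pairs carry no score and must not pair a
    male with his own spouse (checked against the couple rows present).
    """
    required = {"dyad_id", "male_id", "female_id", "dyad_class"}
    missing = required - set(dyads.columns)
    if missing:
        raise ValidationError(f"dyad table missing columns {sorted(missing)}")
    for col in ("cmqi_score", "marriage_duration"):
        if col not in dyads.columns:
            dyads = dyads.assign(**{col: np.nan})
    bad = set(dyads["dyad_class"]) - set(DYAD_CLASSES)
    if bad:
        raise ValidationError(f"unknown dyad classes: {sorted(bad)}")
    if (dyads["male_id"] == dyads["female_id"]).any():
        row = dyads.loc[dyads["male_id"] == dyads["female_id"]].iloc[0]
        raise ValidationError(
            f"invalid dyad {row['dyad_id']}: pairs subject {row['male_id']} with itself"
        )
    couples = dyads[dyads["dyad_class"].str.startswith("couple")]
    scores = couples["cmqi_score"].to_numpy(dtype=float)
    if np.isnan(scores).any():
        raise ValidationError("couple rows must carry a cmqi_score")
    is_high = couples["dyad_class"] == "couple_high"
    wrong = (is_high & (scores <= SATISFACTION_THRESHOLD)) | (
        ~is_high & (scores > SATISFACTION_THRESHOLD)
    )
    if wrong.any():
        row = couples.loc[wrong].iloc[0]
        raise ValidationError(
            f"dyad {row['dyad_id']}: class {row['dyad_class']} inconsistent with "
            f"cmqi_score {row['cmqi_score']} (threshold {SATISFACTION_THRESHOLD})"
        )
    spouse_of = dict(zip(couples["male_id"], couples["female_id"]))
    rnd = dyads[dyads["dyad_class"] == "random"]
    own = rnd["female_id"].to_numpy() == rnd["male_id"].map(spouse_of).to_numpy()
    if own.any():
        row = rnd.loc[own].iloc[0]
        raise ValidationError(
            f"random dyad {row['dyad_id']} pairs {row['male_id']} with his own spouse"
        )
    if dyads["dyad_id"].duplicated().any():
        raise ValidationError("duplicate dyad_id")
    return dyads.reset_index(drop=True)


def validate_clip_table(clips: pd.DataFrame, n_trs: int | None = None) -> pd.DataFrame:
    """Validate a movie-clip table of half-open, non-overlapping intervals."""
    required = {"clip_id", "start_tr", "end_tr"}
    missing = required - set(clips.columns)
    if missing:
        raise ValidationError(f"clip table missing columns {sorted(missing)}")
    clips = clips.sort_values("start_tr").reset_index(drop=True)
    starts = clips["start_tr"].to_numpy(dtype=int)
    ends = clips["end_tr"].to_numpy(dtype=int)
    if (ends <= starts).any():
        raise ValidationError("clip with end_tr <= start_tr")
    if (starts[1:] < ends[:-1]).any():
        raise ValidationError("overlapping clip intervals")
    if starts.size and starts[0] < 0:
        raise ValidationError("clip starting before TR 0")
    if n_trs is not None and ends.size and ends[-1] > n_trs:
        raise ValidationError(f"clip extending past run length {n_trs}")
    return clips


@dataclass
class Dataset:
    """A fully validated analysis dataset.

    ``timeseries`` maps ``(subject_id, roi_id)`` to :class:`RoiTimeSeries`;
    all runs share the same TR count.
    """

    timeseries: dict[tuple[str, int], RoiTimeSeries]
    parcellation: pd.DataFrame
    dyads: pd.DataFrame
    metadata: RunMetadata = field(default_factory=RunMetadata)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.parcellation = validate_parcellation(self.parcellation)
        self.dyads = validate_dyads(self.dyads)
        known_rois = set(self.parcellation["roi_id"])
        t_seen = set()
        for (sid, rid), ts in self.timeseries.items():
            if (sid, rid) != (ts.subject_id, ts.roi_id):
                raise ValidationError(f"timeseries key {(sid, rid)} mismatches entry")
            if rid not in known_rois:
                raise ValidationError(f"timeseries references unknown roi_id {rid}")
            t_seen.add(ts.n_trs)
        if len(t_seen) > 1:
            raise ValidationError(f"inconsistent TR counts across runs: {sorted(t_seen)}")
        subj_seen = {sid for sid, _ in self.timeseries}
        for _, row in self.dyads.iterrows():
            for col in ("male_id", "female_id"):
                if row[col] not in subj_seen:
                    raise ValidationError(
                        f"dyad {row['dyad_id']} references unknown subject {row[col]}"
                    )
        if self.metadata.clip_table is not None:
            self.metadata.clip_table = validate_clip_table(
                self.metadata.clip_table, self.n_trs
            )

    @property
    def subjects(self) -> list[str]:
        return sorted({sid for sid, _ in self.timeseries})

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.parcellation["roi_id"])

    @property
    def n_trs(self) -> int:
        return next(iter(self.timeseries.values())).n_trs

    def get(self, subject_id: str, roi_id: int) -> RoiTimeSeries:
        try:
            return self.timeseries[(subject_id, roi_id)]
        except KeyError:
            raise KeyError(f"no time series for subject {subject_id} roi {roi_id}")

    def network_rois(self, network: str) -> list[int]:
        """ROI ids belonging to one of the seven networks."""
        if network not in NETWORKS:
            raise ValidationError(f"unknown network {network!r}")
        p = self.parcellation
        return sorted(p.loc[p["network"] == network, "roi_id"])

    def summary(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "n_rois": len(self.roi_ids),
            "n_trs": self.n_trs,
            "n_dyads": int(len(self.dyads)),
            "dyad_classes": self.dyads["dyad_class"].value_counts().to_dict(),
        }


def as_dict(obj) -> dict:
    """dataclass -> plain dict (for JSON summaries)."""
    return dataclasses.asdict(obj)
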