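"""Pattern-trajectory matrices and inter-subject trajectory similarity (ISTS).

For one subject and one ROI, the multi-voxel pattern (MVP) at TR *t* is the
vector of voxel activities at that time point. The *pattern trajectory
matrix* is the TR x TR matrix of Pearson correlations between MVPs at every
pair of time points: entries near the diagonal compare patterns close in
time, entries far from it compare temporally distant patterns. ISTS for a
dyad is the Pearson correlation between the two members' vectorized
trajectory matrices (strict upper triangle, diagonal excluded), computed
independently per ROI. Dyad-level similarity is put on a common scale by
z-scoring ISTS per ROI across all dyad classes pooled (ISTS-Z), and a
whole-brain score is the mean ISTS across ROIs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import Dataset, RoiTimeSeries, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PatternTrajectoryMatrix:
    """TR x TR Pearson correlation matrix between a subject's MVPs.

    Symmetric, unit diagonal, entries in [-1, 1]. Rows/columns of TRs whose
    MVP had zero variance across voxels are NaN. ``tr_mask_used`` records
    which TRs of the original run were retained (None = all).
    """

    subject_id: str
    roi_id: int
    matrix: np.ndarray
    tr_mask_used: np.ndarray | None = None

    @property
    def n_trs(self) -> int:
        return self.matrix.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Vectorized strict upper triangle (row-major), NaN where missing."""
        iu = np.triu_indices(self.n_trs, k=1)
        return self.matrix[iu]


def build_trajectory_matrix(
    ts: RoiTimeSeries, tr_mask: np.ndarray | None = None
) -> PatternTrajectoryMatrix:
    """Correlate a subject's MVPs at every pair of (optionally masked) TRs.

    Parameters
    ----------
    ts : RoiTimeSeries
        Voxel x TR matrix for one subject in one ROI.
    tr_mask : array of TR indices or boolean mask, optional
        TR subset to retain *before* building the matrix, so that only
        within-condition temporal structure is compared.

    Returns
    -------
    PatternTrajectoryMatrix
        T' x T' matrix where T' is the masked run length. A TR whose MVP is
        constant across voxels gets a NaN row/column (warning logged).
    """
    data = ts.data
    if tr_mask is not None:
        tr_mask = np.asarray(tr_mask)
        if tr_mask.dtype == bool:
            if tr_mask.size != ts.n_trs:
                raise ValidationError(
                    f"boolean tr_mask length {tr_mask.size} != T {ts.n_trs}"
                )
            tr_idx = np.flatnonzero(tr_mask)
        else:
            tr_idx = np.asarray(tr_mask, dtype=int)
            if tr_idx.size and (tr_idx.min() < 0 or tr_idx.max() >= ts.n_trs):
                raise ValidationError("tr_mask index out of range")
        # advanced indexing yields an F-ordered copy; normalize layout so a
        # full-run mask reproduces the unmasked result bit for bit
        data = np.ascontiguousarray(data[:, tr_idx])
    else:
        tr_idx = None

    tp = data.shape[1]
    if tp < 3:
        raise ValidationError(
            f"subject {ts.subject_id} roi {ts.roi_id}: fewer than 3 TRs after masking"
        )
    degenerate = np.flatnonzero(data.std(axis=0) == 0)
    usable = tp - degenerate.size
    if usable < 3:
        raise ValidationError(
            f"subject {ts.subject_id} roi {ts.roi_id}: fewer than 3 usable TRs "
            "(zero-variance patterns)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = np.corrcoef(data.T)
    np.fill_diagonal(mat, 1.0)
    mat = np.clip(mat, -1.0, 1.0)
    if degenerate.size:
        logger.warning(
            "subject %s roi %d: %d zero-variance MVP(s) at TR(s) %s set to missing",
            ts.subject_id,
            ts.roi_id,
            degenerate.size,
            degenerate.tolist(),
        )
        mat[degenerate, :] = np.nan
        mat[:, degenerate] = np.nan
    return PatternTrajectoryMatrix(ts.subject_id, ts.roi_id, mat, tr_idx)


def compute_ists(a: PatternTrajectoryMatrix, b: PatternTrajectoryMatrix) -> float:
    """Pearson correlation between two vectorized trajectory matrices.

    Both matrices must have the same size and the same missing-TR set; the
    diagonal is excluded and missing entries are dropped pairwise-complete.
    Returns NaN (with a warning) if fewer than 3 valid entries remain.
    """
    if a.matrix.shape != b.matrix.shape:
        raise ValidationError(
            f"trajectory matrix shape mismatch: {a.matrix.shape} vs {b.matrix.shape}"
        )
    va, vb = a.upper_triangle(), b.upper_triangle()
    if not np.array_equal(np.isnan(va), np.isnan(vb)):
        raise ValidationError("mismatched missing-TR sets between trajectory matrices")
    ok = ~np.isnan(va)
    va, vb = va[ok], vb[ok]
    if va.size < 3 or va.std() == 0 or vb.std() == 0:
        logger.warning(
            "ISTS undefined for %s/%s roi %d (too few or constant entries)",
            a.subject_id,
            b.subject_id,
            a.roi_id,
        )
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def make_random_pairs(
    dyads: pd.DataFrame, seed: int, n_draws: int = 1
) -> pd.DataFrame:
    """Re-pair husbands with non-spouse wives (a derangement of couples).

    Permutations of the wives are rejection-sampled until none is matched
    with her own husband; each male is paired with exactly one female and no
    female is reused. ``n_draws`` independent derangements can be drawn (the
    default is a single one); rows are tagged ``rand{draw}_{male_id}``.

    Raises on a single couple, for which no derangement exists.
    """
    couples = dyads[dyads["dyad_class"].str.startswith("couple")].reset_index(drop=True)
    n = len(couples)
    if n < 2:
        raise ValidationError("need >=2 couples to form random pairs")
    rng = np.random.default_rng(seed)
    rows = []
    for draw in range(n_draws):
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
        for i in range(n):
            rows.append(
                {
                    "dyad_id": f"rand{draw}_{couples.at[i, 'male_id']}",
                    "male_id": couples.at[i, "male_id"],
                    "female_id": couples.at[int(perm[i]), "female_id"],
                    "dyad_class": "random",
                    "cmqi_score": np.nan,
                    "marriage_duration": np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class IstsTable:
    """Dyad x ROI ISTS values with optional z-scores and whole-brain means.

    ``values`` and ``zvalues`` are DataFrames indexed by dyad_id with ROI id
    columns; ``dyads`` carries the matching metadata rows.
    """

    values: pd.DataFrame
    dyads: pd.DataFrame
    zvalues: pd.DataFrame | None = None
    whole_brain: pd.Series | None = None
    scope: str = "full_run"
    extra: dict = field(default_factory=dict)

    def classes(self) -> pd.Series:
        return self.dyads.set_index("dyad_id")["dyad_class"].loc[self.values.index]

    def to_long(self) -> pd.DataFrame:
        """Long-format table: dyad_id, roi_id, ists, ists_z, scope."""
        long = (
            self.values.rename_axis("dyad_id")
            .reset_index()
            .melt(id_vars="dyad_id", var_name="roi_id", value_name="ists")
        )
        if self.zvalues is not None:
            zl = (
                self.zvalues.rename_axis("dyad_id")
                .reset_index()
                .melt(id_vars="dyad_id", var_name="roi_id", value_name="ists_z")
            )
            long = long.merge(zl, on=["dyad_id", "roi_id"], how="left")
        else:
            long["ists_z"] = np.nan
        long["scope"] = self.scope
        return long.sort_values(["dyad_id", "roi_id"]).reset_index(drop=True)


def compute_ists_table(
    dataset: Dataset,
    dyads: pd.DataFrame | None = None,
    tr_mask: np.ndarray | None = None,
    scope: str = "full_run",
) -> IstsTable:
    """ISTS for every dyad and every ROI of a dataset.

    Trajectory matrices are built per subject per ROI (optionally TR-masked)
    and correlated within each dyad. Matrices are cached per subject so each
    is built once.
    """
    if dyads is None:
        dyads = dataset.dyads
    roi_ids = dataset.roi_ids
    cache: dict[tuple[str, int], PatternTrajectoryMatrix] = {}

    def traj(sid: str, rid: int) -> PatternTrajectoryMatrix:
        key = (sid, rid)
        if key not in cache:
            cache[key] = build_trajectory_matrix(dataset.get(sid, rid), tr_mask)
        return cache[key]

    out = np.empty((len(dyads), len(roi_ids)))
    for i, row in enumerate(dyads.itertuples(index=False)):
        for j, rid in enumerate(roi_ids):
            out[i, j] = compute_ists(traj(row.male_id, rid), traj(row.female_id, rid))
    values = pd.DataFrame(out, index=pd.Index(dyads["dyad_id"], name="dyad_id"),
                          columns=roi_ids)
    return IstsTable(values=values, dyads=dyads.reset_index(drop=True), scope=scope)


def zscore_across_dyads(
    table: IstsTable, classes_included: set[str] | None = None
) -> IstsTable:
    """Fill ``zvalues``: per-ROI z-scores over the pooled included dyads.

    All three dyad classes (couple_high, couple_low, random) are pooled by
    default, so ISTS-Z expresses each dyad's similarity relative to the full
    spread of couple and non-couple pairings. Sample SD (ddof=1) is used.
    ROIs with zero SD get NaN z-values with a warning.
    """
    cls = table.classes()
    if classes_included is None:
        included = pd.Series(True, index=table.values.index)
    else:
        included = cls.isin(classes_included)
    if int(included.sum()) < 3:
        raise ValidationError("need >=3 dyads in the included classes to z-score")
    sub = table.values.loc[included]
    mean = sub.mean(axis=0, skipna=True)
    sd = sub.std(axis=0, ddof=1, skipna=True)
    degenerate = sd[(sd == 0) | sd.isna()].index
    if len(degenerate):
        logger.warning(
            "zero-SD ISTS in ROI(s) %s: z-values set to missing", list(degenerate)
        )
        sd = sd.replace(0, np.nan)
    z = (table.values - mean) / sd
    z.loc[~included] = np.nan
    return IstsTable(
        values=table.values,
        dyads=table.dyads,
        zvalues=z,
        whole_brain=table.whole_brain,
        scope=table.scope,
        extra=table.extra,
    )


def whole_brain_average(
    table: IstsTable, scope: list[int] | None = None, use_z: bool = False
) -> pd.DataFrame:
    """Mean ISTS (or ISTS-Z) per dyad over a set of ROIs.

    Missing entries are skipped; the count of contributing ROIs is reported
    alongside the mean. ``scope=None`` averages over all ROIs (the
    whole-brain score); pass a network's ROI list to restrict.
    """
    source = table.zvalues if use_z else table.values
    if source is None:
        raise ValidationError("z-values requested but not computed")
    sub = source if scope is None else source[scope]
    if sub.isna().all(axis=1).any():
        raise ValidationError("dyad with no valid ISTS in requested scope")
    return pd.DataFrame(
        {"mean_ists": sub.mean(axis=1, skipna=True), "n_rois": sub.notna().sum(axis=1)}
    )
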