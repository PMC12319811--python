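"""Synthetic dyadic fMRI generator with known ground truth.

Emulates the statistical structure the downstream stages assume: each ROI's
signal is a piecewise-stable sequence of event mean patterns (shared by all
subjects, as a common stimulus would impose) plus temporally smooth
fluctuations, of which a tunable fraction ``c`` (the coupling) is shared
within a couple, plus white measurement noise:

    x_spouse(t) = mu[event(t)] + sqrt(c) * s(t) + sqrt(1 - c) * e(t) + n(t)

where ``s`` is the couple-shared fluctuation, ``e`` the spouse's
idiosyncratic one (both unit-variance Gaussian processes smoothed with a
3-TR moving average to mimic BOLD autocorrelation) and ``n`` white Gaussian
noise. Satisfaction scores are generated monotonically from coupling, so
the full pipeline has a known positive coupling-satisfaction effect to
recover. Random (non-couple) pairings for null comparisons use the same
derangement operation as the real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .datatypes import (
    Dataset,
    NETWORKS,
    RoiTimeSeries,
    RunMetadata,
    SATISFACTION_THRESHOLD,
    ValidationError,
)

#: moving-average window (TRs) applied to fluctuation processes
SMOOTH_WINDOW = 3


@dataclass
class SyntheticConfig:
    """Generator settings.

    coupling may be a scalar (same ``c`` for every couple), a (low, high)
    pair (couples drawn uniformly in that range, giving the between-couple
    variation the satisfaction analyses need), or a length-``n_couples``
    sequence of explicit values. ``event_contrast`` scales the separation
    of event mean patterns relative to the unit-variance fluctuations;
    ``noise_sd`` is the white-noise SD on the same scale.
    """

    n_couples: int = 30
    n_rois: int = 20
    voxels_per_roi: int = 50
    n_trs: int = 100
    n_events: int = 5
    coupling: float | tuple[float, float] | list[float] = (0.2, 0.8)
    event_contrast: float = 1.0
    noise_sd: float = 1.0
    satisfaction_slope: float = 40.0
    satisfaction_noise_sd: float = 5.0
    n_clips: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_events <= self.n_trs):
            raise ValidationError(
                f"n_events must lie in [1, n_trs]: {self.n_events} vs {self.n_trs}"
            )
        if self.noise_sd <= 0 or self.satisfaction_noise_sd < 0:
            raise ValidationError("noise SDs must be positive")
        if self.n_couples < 2:
            raise ValidationError("need at least 2 couples")
        vals = np.atleast_1d(np.asarray(self.coupling, dtype=float))
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("coupling values must lie in [0, 1]")

    def coupling_values(self, rng: np.random.Generator) -> np.ndarray:
        c = self.coupling
        if np.isscalar(c):
            vals = np.full(self.n_couples, float(c))
        elif len(c) == 2 and self.n_couples != 2:
            lo, hi = c
            vals = rng.uniform(lo, hi, size=self.n_couples)
        else:
            vals = np.asarray(c, dtype=float)
            if vals.size != self.n_couples:
                raise ValidationError(
                    f"coupling sequence length {vals.size} != n_couples {self.n_couples}"
                )
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("coupling values must lie in [0, 1]")
        return vals


def generate_event_sequence(
    k_true: int, n_trs: int, seed: int | np.random.Generator
) -> list[int]:
    """Random interior event boundaries (0-based TRs, strictly increasing).

    Partitions ``[0, n_trs)`` into ``k_true`` contiguous events, each at
    least ``max(3, n_trs // (3 * k_true))`` TRs long so that within-event
    trajectory matrices stay well defined. Returns the ``k_true - 1``
    boundary TRs (the first TR of each event after the first).
    """
    if k_true < 1:
        raise ValidationError("k_true must be >= 1")
    if k_true == 1:
        return []
    min_len = max(3, n_trs // (3 * k_true))
    if k_true * min_len > n_trs:
        raise ValidationError(
            f"cannot fit {k_true} events of length >= {min_len} into {n_trs} TRs"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slack = n_trs - k_true * min_len
    extra = rng.multinomial(slack, np.full(k_true, 1.0 / k_true))
    lengths = min_len + extra
    return np.cumsum(lengths)[:-1].tolist()


def assignment_from_boundaries(boundaries: list[int], n_trs: int) -> np.ndarray:
    """Per-TR event index implied by a boundary list."""
    assign = np.zeros(n_trs, dtype=int)
    for b in boundaries:
        assign[b:] += 1
    return assign


def generate_satisfaction(
    c_values: np.ndarray,
    slope: float,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Satisfaction scores tied monotonically to coupling.

    score = threshold + slope * (c - mean(c)) + N(0, noise_sd); classes are
    assigned by the 60-point threshold (``couple_high`` strictly above).
    With slope 0 the scores are independent of coupling; with zero noise
    their rank order equals the rank order of ``c``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.asarray(c_values, dtype=float)
    scores = SATISFACTION_THRESHOLD + slope * (c - c.mean())
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=c.size)
    classes = np.where(scores > SATISFACTION_THRESHOLD, "couple_high", "couple_low")
    return pd.DataFrame({"cmqi_score": scores, "dyad_class": classes})


def _smooth_unit_process(rng: np.random.Generator, shape: tuple) -> np.ndarray:
    """White Gaussian noise smoothed over the time axis, rescaled to ~unit SD.

    The last axis is time. A length-3 uniform moving average shrinks the
    variance by the window size, so the output is multiplied back by
    sqrt(window) to keep the generative variance budget interpretable.
    """
    raw = rng.standard_normal(shape)
    sm = uniform_filter1d(raw, size=SMOOTH_WINDOW, axis=-1, mode="nearest")
    return sm * np.sqrt(SMOOTH_WINDOW)


def _build_parcellation(n_rois: int) -> pd.DataFrame:
    networks = [NETWORKS[(i * len(NETWORKS)) // n_rois] for i in range(n_rois)]
    return pd.DataFrame(
        {
            "roi_id": np.arange(1, n_rois + 1),
            "roi_name": [f"ROI{r:03d}" for r in range(1, n_rois + 1)],
            "network": networks,
        }
    )


def _build_clips(n_clips: int, n_trs: int) -> pd.DataFrame:
    edges = np.linspace(0, n_trs, n_clips + 1).astype(int)
    themes = ["marital" if i % 2 == 0 else "non_marital" for i in range(n_clips)]
    return pd.DataFrame(
        {
            "clip_id": [f"clip{i + 1:02d}" for i in range(n_clips)],
            "start_tr": edges[:-1],
            "end_tr": edges[1:],
            "theme": themes,
        }
    )


def generate_dyad_timeseries(config: SyntheticConfig) -> Dataset:
    """Generate a full synthetic dataset plus ground truth.

    Returns a validated :class:`Dataset` whose ``ground_truth`` dict holds
    the true event boundaries, per-couple coupling values and the seed. All
    randomness flows from ``config.seed``, so the dataset is reproducible
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n, r, v, t = (
        config.n_couples,
        config.n_rois,
        config.voxels_per_roi,
        config.n_trs,
    )
    boundaries = generate_event_sequence(config.n_events, t, rng)
    assign = assignment_from_boundaries(boundaries, t)
    c_vals = config.coupling_values(rng)
    sat = generate_satisfaction(
        c_vals, config.satisfaction_slope, config.satisfaction_noise_sd, rng
    )

    subjects = [(f"m{i + 1:03d}", f"f{i + 1:03d}") for i in range(n)]
    timeseries: dict[tuple[str, int], RoiTimeSeries] = {}
    for j in range(r):
        roi_id = j + 1
        # event mean patterns: one V-vector per event, separation set by contrast
        means = rng.normal(0.0, config.event_contrast, size=(config.n_events, v))
        base = means[assign].T  # V x T
        for i, (male, female) in enumerate(subjects):
            c = c_vals[i]
            shared = _smooth_unit_process(rng, (v, t))
            for sid in (male, female):
                idio = _smooth_unit_process(rng, (v, t))
                fluct = np.sqrt(c) * shared + np.sqrt(1.0 - c) * idio
                noise = rng.normal(0.0, config.noise_sd, size=(v, t))
                timeseries[(sid, roi_id)] = RoiTimeSeries(
                    subject_id=sid, roi_id=roi_id, data=base + fluct + noise
                )

    dyads = pd.DataFrame(
        {
            "dyad_id": [f"d{i + 1:03d}" for i in range(n)],
            "male_id": [m for m, _ in subjects],
            "female_id": [f for _, f in subjects],
            "dyad_class": sat["dyad_class"],
            "cmqi_score": sat["cmqi_score"],
            "marriage_duration": np.round(rng.uniform(1.0, 20.0, size=n), 1),
        }
    )
    metadata = RunMetadata()
    if config.n_clips > 0:
        clips = _build_clips(config.n_clips, t)
        metadata.clip_table = clips
        mask_rows = []
        for clip in clips.itertuples(index=False):
            for tr in range(clip.start_tr, clip.end_tr):
                mask_rows.append({"tr": tr, "label": clip.theme})
        metadata.condition_mask = pd.DataFrame(mask_rows)

    ground_truth = {
        "boundaries": list(map(int, boundaries)),
        "coupling": c_vals.tolist(),
        "dyad_ids": dyads["dyad_id"].tolist(),
        "n_events": config.n_events,
        "seed": config.seed,
    }
    return Dataset(
        timeseries=timeseries,
        parcellation=_build_parcellation(r),
        dyads=dyads,
        metadata=metadata,
        ground_truth=ground_truth,
    )
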