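"""Ordered-state HMM event segmentation of network activity.

During naturalistic viewing, cortical activity moves through a sequence of
discrete, temporally stable multivariate patterns ("events") punctuated by
rapid transitions ("event boundaries"). The model is a hidden Markov model
whose K states are ordered: from state k the chain either stays at k or
advances to k+1, never returning to an earlier state, so each state is one
contiguous event. Emissions are isotropic Gaussians around a per-state mean
pattern with a single shared variance, fitted by EM on per-TR z-scored
features; the transition structure is fixed (advance probability K/T,
giving K expected events in T TRs) rather than learned.

The number of events is selected by nested cross-validation: an outer loop
holds out one test subject, the remaining subjects are split into training
and validation sets whose data are averaged, and the inner loop scores each
candidate K by the forward log-likelihood of the validation average under
the model fitted to the training average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .datatypes import Dataset, ValidationError

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-12


def _zscore_per_tr(X: np.ndarray) -> np.ndarray:
    """Z-score each TR's feature vector (pattern normalization).

    Removes per-TR amplitude and offset so the model segments on pattern
    shape, not global signal level. Constant rows are left at zero.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


class EventSegmenter(BaseEstimator):
    """Left-to-right Gaussian HMM for event segmentation.

    Parameters
    ----------
    n_events : int
        Number of ordered states K. Must not exceed the number of TRs.
    advance_prob : float, optional
        Probability of advancing to the next state at each step. Defaults
        to ``K / T`` at fit time (K expected events in a run of length T).
    normalize : {"tr", "feature", None}
        Feature normalization applied before fitting and scoring. ``"tr"``
        (default) z-scores each time point's pattern across features;
        ``"feature"`` z-scores each feature's time course.
    tol : float
        EM stops when the relative log-likelihood improvement falls below
        this value.
    max_iter : int
        EM iteration cap.
    split_merge : bool
        Optional post-EM refinement for uneven event lengths: repeatedly
        propose merging the two most similar adjacent states while
        splitting the segment with the largest residual variance, re-run
        EM, and keep the proposal only if the log-likelihood improves.
    n_refine : int
        Maximum number of accepted split/merge refinement rounds.

    Attributes
    ----------
    state_means_ : ndarray of shape (n_events, n_features)
    emission_sd_ : float
        Shared isotropic emission SD.
    posterior_ : ndarray of shape (n_trs, n_events)
        Per-TR marginal state posterior (rows sum to 1).
    assignment_ : ndarray of shape (n_trs,)
        Monotone per-TR state index (argmax posterior, made non-decreasing).
    boundaries_ : list of int
        TRs at which the assigned state increments.
    log_likelihood_ : float
    ll_history_ : list of float
        Training log-likelihood at each EM iteration (non-decreasing).
    """

    def __init__(
        self,
        n_events: int = 5,
        advance_prob: float | None = None,
        normalize: str | None = "tr",
        tol: float = 1e-6,
        max_iter: int = 200,
        split_merge: bool = False,
        n_refine: int = 5,
    ):
        self.n_events = n_events
        self.advance_prob = advance_prob
        self.normalize = normalize
        self.tol = tol
        self.max_iter = max_iter
        self.split_merge = split_merge
        self.n_refine = n_refine

    # ------------------------------------------------------------------ utils

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError(f"expected T x D feature matrix, got ndim={X.ndim}")
        if not np.isfinite(X).all():
            raise ValidationError("non-finite values in feature matrix")
        if self.normalize == "tr":
            return _zscore_per_tr(X)
        if self.normalize == "feature":
            return _zscore_per_tr(X.T).T
        if self.normalize is None:
            return X
        raise ValidationError(f"unknown normalize option {self.normalize!r}")

    def _log_transition(self, n_trs: int) -> tuple[np.ndarray, np.ndarray]:
        """(log stay, log advance) per state for a run of length n_trs."""
        k = self.n_events
        p = self.advance_prob if self.advance_prob is not None else k / n_trs
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"advance probability {p} outside [0, 1]")
        with np.errstate(divide="ignore"):
            log_stay = np.full(k, np.log1p(-p) if p < 1 else -np.inf)
            log_adv = np.full(k, np.log(p) if p > 0 else -np.inf)
        log_stay[-1] = 0.0  # last state is absorbing
        log_adv[-1] = -np.inf
        return log_stay, log_adv

    def _log_emission(self, X: np.ndarray, means: np.ndarray, var: float) -> np.ndarray:
        d = X.shape[1]
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ means.T
            + (means**2).sum(axis=1)[None, :]
        )
        return -0.5 * (d * (_LOG2PI + np.log(var)) + sq / var)

    def _forward(self, log_e, log_stay, log_adv):
        t_len, k = log_e.shape
        lal = np.full((t_len, k), -np.inf)
        lal[0, 0] = log_e[0, 0]  # chain starts in the first state
        for t in range(1, t_len):
            stay = lal[t - 1] + log_stay
            adv = np.full(k, -np.inf)
            adv[1:] = lal[t - 1, :-1] + log_adv[:-1]
            lal[t] = log_e[t] + np.logaddexp(stay, adv)
        return lal

    def _backward(self, log_e, log_stay, log_adv):
        t_len, k = log_e.shape
        lbe = np.zeros((t_len, k))
        for t in range(t_len - 2, -1, -1):
            stay = log_stay + log_e[t + 1] + lbe[t + 1]
            adv = np.full(k, -np.inf)
            adv[:-1] = log_adv[:-1] + log_e[t + 1, 1:] + lbe[t + 1, 1:]
            lbe[t] = np.logaddexp(stay, adv)
        return lbe

    def _loglik_posterior(self, X, means, var):
        log_e = self._log_emission(X, means, var)
        log_stay, log_adv = self._log_transition(X.shape[0])
        lal = self._forward(log_e, log_stay, log_adv)
        lbe = self._backward(log_e, log_stay, log_adv)
        ll = float(logsumexp(lal[-1]))
        gamma = np.exp(lal + lbe - ll)
        gamma /= gamma.sum(axis=1, keepdims=True)
        return ll, gamma

    def _m_step(self, X, gamma, means_prev):
        weights = gamma.sum(axis=0)
        means = means_prev.copy()
        active = weights > 1e-10
        means[active] = (gamma.T[active] @ X) / weights[active, None]
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ means.T
            + (means**2).sum(axis=1)[None, :]
        )
        var = float((gamma * sq).sum() / (X.shape[0] * X.shape[1]))
        return means, max(var, _VAR_FLOOR)

    def _block_init(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """Deterministic init: K equal contiguous blocks of the run."""
        t_len = X.shape[0]
        edges = np.linspace(0, t_len, self.n_events + 1).astype(int)
        means = np.vstack(
            [X[edges[k] : max(edges[k + 1], edges[k] + 1)].mean(axis=0)
             for k in range(self.n_events)]
        )
        assign = np.searchsorted(edges[1:], np.arange(t_len), side="right")
        resid = X - means[assign]
        return means, max(float((resid**2).mean()), _VAR_FLOOR)

    def _run_em(self, X, means, var):
        history = []
        ll_prev = -np.inf
        gamma = None
        for _ in range(self.max_iter):
            ll, gamma = self._loglik_posterior(X, means, var)
            history.append(ll)
            if np.isfinite(ll_prev) and ll - ll_prev < self.tol * abs(ll_prev):
                break
            ll_prev = ll
            means, var = self._m_step(X, gamma, means)
        else:
            # iteration cap hit after an M-step: sync posterior with params
            ll, gamma = self._loglik_posterior(X, means, var)
            history.append(ll)
        return means, var, gamma, history

    # ------------------------------------------------------------------- API

    def fit(self, X: np.ndarray, y=None) -> "EventSegmenter":
        """Fit the segmentation to a T x D feature series."""
        X = self._prepare(X)
        t_len = X.shape[0]
        if self.n_events < 1:
            raise ValidationError("n_events must be >= 1")
        if self.n_events > t_len:
            raise ValidationError(
                f"n_events={self.n_events} exceeds run length T={t_len}"
            )
        means, var = self._block_init(X)
        means, var, gamma, history = self._run_em(X, means, var)
        if self.split_merge and self.n_events >= 2:
            means, var, gamma, history = self._refine(X, means, var, gamma, history)
        self.n_features_in_ = X.shape[1]
        self.state_means_ = means
        self.emission_var_ = var
        self.emission_sd_ = float(np.sqrt(var))
        self.posterior_ = gamma
        self.ll_history_ = history
        self.log_likelihood_ = history[-1]
        self.assignment_ = self._monotone_argmax(gamma)
        self.boundaries_ = extract_boundaries(self.assignment_)
        return self

    def _refine(self, X, means, var, gamma, history):
        """Split/merge proposals accepted only on log-likelihood improvement."""
        for _ in range(self.n_refine):
            assign = self._monotone_argmax(gamma)
            visited = np.unique(assign)
            if visited.size < 2:
                break
            gaps = np.linalg.norm(np.diff(means, axis=0), axis=1)
            merge_k = int(np.argmin(gaps))  # merge states merge_k, merge_k+1
            seg_var = np.array(
                [
                    ((X[assign == k] - means[k]) ** 2).sum() if (assign == k).any()
                    else -np.inf
                    for k in range(self.n_events)
                ]
            )
            split_k = int(np.argmax(seg_var))
            if split_k in (merge_k, merge_k + 1):
                break
            prop = means.copy()
            merged = 0.5 * (means[merge_k] + means[merge_k + 1])
            seg = np.flatnonzero(assign == split_k)
            half = seg.size // 2
            if half < 1:
                break
            first, second = X[seg[:half]].mean(axis=0), X[seg[half:]].mean(axis=0)
            # rebuild the ordered mean sequence with the merge and the split
            new_rows = []
            for k in range(self.n_events):
                if k == merge_k:
                    new_rows.append(merged)
                elif k == merge_k + 1:
                    continue
                elif k == split_k:
                    new_rows.extend([first, second])
                else:
                    new_rows.append(prop[k])
            cand_means, cand_var, cand_gamma, cand_hist = self._run_em(
                X, np.vstack(new_rows), var
            )
            if cand_hist[-1] > history[-1]:
                means, var, gamma = cand_means, cand_var, cand_gamma
                history = history + cand_hist
            else:
                break
        return means, var, gamma, history

    @staticmethod
    def _monotone_argmax(gamma: np.ndarray) -> np.ndarray:
        """Per-TR argmax posterior, forced non-decreasing (no-return rule)."""
        return np.maximum.accumulate(np.argmax(gamma, axis=1))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Monotone state assignment of new data under the fitted states."""
        self._check_fitted(X)
        _, gamma = self._loglik_posterior(
            self._prepare(X), self.state_means_, self.emission_var_
        )
        return self._monotone_argmax(gamma)

    def score(self, X: np.ndarray, y=None) -> float:
        """Forward-algorithm log-likelihood under the frozen fitted model."""
        self._check_fitted(X)
        X = self._prepare(X)
        log_e = self._log_emission(X, self.state_means_, self.emission_var_)
        log_stay, log_adv = self._log_transition(X.shape[0])
        lal = self._forward(log_e, log_stay, log_adv)
        return float(logsumexp(lal[-1]))

    def _check_fitted(self, X):
        if not hasattr(self, "state_means_"):
            raise ValidationError("EventSegmenter is not fitted")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.state_means_.shape[1]:
            raise ValidationError(
                f"feature dimension {X.shape} incompatible with fitted model "
                f"(D={self.state_means_.shape[1]})"
            )


def fit_event_hmm(data: np.ndarray, n_events: int, **kwargs) -> EventSegmenter:
    """Convenience wrapper: fit an :class:`EventSegmenter` to a T x D series."""
    return EventSegmenter(n_events=n_events, **kwargs).fit(data)


def held_out_loglik(model: EventSegmenter, data: np.ndarray) -> float:
    """Log-likelihood of held-out data under a frozen fitted model."""
    return model.score(data)


def extract_boundaries(assignment: np.ndarray) -> list[int]:
    """TRs at which the per-TR state index increments."""
    assignment = np.asarray(assignment)
    if np.any(np.diff(assignment) < 0):
        raise ValidationError("assignment violates the no-return constraint")
    return (np.flatnonzero(np.diff(assignment) > 0) + 1).tolist()


@dataclass
class CvScheme:
    """Nested cross-validation layout for selecting the number of events.

    The inner split sizes must sum to the inner-loop subject count (all
    subjects minus the held-out test subject). ``n_outer_folds=None`` runs
    a full leave-one-subject-out outer loop; a smaller number subsamples
    test subjects (a cost-control option for simulation studies).
    The study-scale layout (36 subjects -> 27 train / 8 validation, K from
    1 to 100) is expressible directly; defaults are desk-scale.
    """

    train_size: int = 8
    validation_size: int = 3
    k_range: tuple[int, int] = (1, 10)
    n_outer_folds: int | None = None

    def __post_init__(self) -> None:
        if self.train_size < 1 or self.validation_size < 1:
            raise ValidationError("train and validation sizes must be >= 1")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValidationError(f"invalid k_range {self.k_range}")

    def ks(self, n_trs: int) -> list[int]:
        lo, hi = self.k_range
        if hi > n_trs:
            logger.warning("k_range truncated at run length T=%d", n_trs)
            hi = n_trs
        return list(range(lo, hi + 1))


@dataclass
class StateSelection:
    """Outcome of nested-CV selection of the number of events."""

    k_star: int
    fold_k_star: list[int]
    per_fold: pd.DataFrame  # columns: fold, test_subject, k, val_loglik
    test_models: list[EventSegmenter] = field(default_factory=list)


def select_num_states(
    group_data: np.ndarray,
    scheme: CvScheme,
    seed: int,
    fit_kwargs: dict | None = None,
) -> StateSelection:
    """Nested-CV choice of the number of events for one group/network.

    Parameters
    ----------
    group_data : ndarray of shape (n_subjects, n_trs, n_features)
        One feature series per subject (e.g. per-ROI mean signals of one
        network).
    scheme : CvScheme
    seed : int
        Controls the train/validation shuffles and (if used) the outer-fold
        subsample; fixed seed gives identical splits and selection.

    Notes
    -----
    Each outer fold holds out one test subject; the remaining subjects are
    shuffled and split into train/validation sets, each averaged across
    subjects. Every candidate K is fitted on the train average and scored
    on the validation average; the fold's K* maximizes validation
    log-likelihood, and a final model at K* is fitted to the held-out test
    subject. The overall K* is the mode of fold-level choices (ties break
    toward fewer events).
    """
    data = np.asarray(group_data, dtype=float)
    if data.ndim != 3:
        raise ValidationError("group data must be subjects x TRs x features")
    n_subj, n_trs, _ = data.shape
    if scheme.train_size + scheme.validation_size != n_subj - 1:
        raise ValidationError(
            f"train+validation ({scheme.train_size}+{scheme.validation_size}) "
            f"must equal inner-loop subject count {n_subj - 1}"
        )
    fit_kwargs = fit_kwargs or {}
    ks = scheme.ks(n_trs)
    rng = np.random.default_rng(seed)
    test_subjects = np.arange(n_subj)
    if scheme.n_outer_folds is not None and scheme.n_outer_folds < n_subj:
        test_subjects = np.sort(
            rng.choice(n_subj, size=scheme.n_outer_folds, replace=False)
        )

    records, fold_k_star, test_models = [], [], []
    for fold, test_idx in enumerate(test_subjects):
        rest = np.delete(np.arange(n_subj), test_idx)
        rest = rng.permutation(rest)
        train_avg = data[rest[: scheme.train_size]].mean(axis=0)
        val_avg = data[rest[scheme.train_size :]].mean(axis=0)
        lls = []
        for k in ks:
            model = EventSegmenter(n_events=k, **fit_kwargs).fit(train_avg)
            ll = model.score(val_avg)
            lls.append(ll)
            records.append(
                {"fold": fold, "test_subject": int(test_idx), "k": k, "val_loglik": ll}
            )
        k_best = ks[int(np.argmax(lls))]
        fold_k_star.append(k_best)
        test_models.append(
            EventSegmenter(n_events=k_best, **fit_kwargs).fit(data[test_idx])
        )
    counts = pd.Series(fold_k_star).value_counts()
    top = counts[counts == counts.max()].index.min()
    return StateSelection(
        k_star=int(top),
        fold_k_star=fold_k_star,
        per_fold=pd.DataFrame.from_records(records),
        test_models=test_models,
    )


def compare_group_segmentations(
    group_a: dict[str, np.ndarray] | np.ndarray,
    group_b: dict[str, np.ndarray] | np.ndarray,
    scheme: CvScheme,
    seed: int,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Select K independently per group (per network) and compare.

    Accepts either a single subjects x TRs x features array per group or a
    ``{network: array}`` mapping; returns one row per network with each
    group's K* and the boundaries of a group-level model fitted at K* on
    the subject-average data.
    """
    if not isinstance(group_a, dict):
        group_a, group_b = {"all": group_a}, {"all": group_b}
    if set(group_a) != set(group_b):
        raise ValidationError("groups must cover the same networks")
    fit_kwargs = fit_kwargs or {}
    rows = []
    for net in group_a:
        out = {}
        for label, dat in (("a", group_a[net]), ("b", group_b[net])):
            sel = select_num_states(dat, scheme, seed, fit_kwargs)
            pooled = np.asarray(dat, dtype=float).mean(axis=0)
            model = EventSegmenter(n_events=sel.k_star, **fit_kwargs).fit(pooled)
            out[f"k_star_{label}"] = sel.k_star
            out[f"boundaries_{label}"] = model.boundaries_
        rows.append({"network": net, **out})
    return pd.DataFrame(rows)


def network_features(
    dataset: Dataset,
    network: str | None = None,
    subjects: list[str] | None = None,
    level: str = "roi_mean",
) -> np.ndarray:
    """Assemble subjects x TRs x features series for HMM fitting.

    ``level="roi_mean"`` (default) uses each ROI's voxel-mean time course
    as one feature; ``level="voxels"`` concatenates all voxels of the
    network's ROIs.
    """
    rois = dataset.network_rois(network) if network else dataset.roi_ids
    if not rois:
        raise ValidationError(f"network {network!r} has no ROIs in this parcellation")
    subjects = subjects if subjects is not None else dataset.subjects
    out = []
    for sid in subjects:
        cols = []
        for rid in rois:
            ts = dataset.get(sid, rid)
            if level == "roi_mean":
                cols.append(ts.data.mean(axis=0))
            elif level == "voxels":
                cols.extend(ts.data)
            else:
                raise ValidationError(f"unknown feature level {level!r}")
        out.append(np.column_stack(cols) if level == "roi_mean" else np.vstack(cols).T)
    return np.stack(out)
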