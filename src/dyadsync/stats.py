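"""Dyad-level statistics: group tests and PLS-1 inference.

The region-wise link between trajectory similarity and satisfaction is
modelled with the first partial-least-squares component (PLS-1): the unit
weight vector ``w`` over ROIs maximizing the covariance between the
projected similarity profile ``X w`` and the satisfaction scores ``y``.
For a single component this has the closed form ``w ∝ Xcᵀ yc`` (centered
data), which the estimator uses directly. Significance of the component is
assessed by permuting ``y`` across dyads (add-one permutation p-value on
the explained covariance); the reliability of each ROI's weight is
assessed by bootstrap resampling of dyads with sign alignment, giving a z
value per ROI that is converted to a two-tailed normal p and controlled
with Benjamini-Hochberg FDR.

Group contrasts use Welch two-sample t tests with Cohen's d (pooled-SD),
two-way ANOVA for the fMRI-state x marital-status design, and
Pearson/Spearman correlations for the satisfaction and marriage-duration
analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- PLS-1


class PLS1Regression(BaseEstimator, RegressorMixin):
    """First partial-least-squares component of X (dyad x ROI) against y.

    Attributes
    ----------
    weights_ : ndarray of shape (n_rois,)
        Unit-norm loading vector; sign fixed so the component score
        correlates non-negatively with ``y``.
    scores_ : ndarray of shape (n_dyads,)
        Component scores ``Xc @ weights_``.
    covariance_explained_ : float
        Squared sample covariance between the scores and ``y`` — the
        statistic permuted under the null.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLS1Regression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValidationError(f"incompatible shapes X{X.shape}, y{y.shape}")
        if X.shape[0] < 3:
            raise ValidationError("PLS-1 needs at least 3 dyads")
        if np.std(y) == 0:
            raise ValidationError("satisfaction scores have zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        xc = X - self.x_mean_
        yc = y - self.y_mean_
        w = xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValidationError("zero cross-covariance: PLS-1 undefined")
        w = w / norm
        t = xc @ w
        if np.dot(t, yc) < 0:  # deterministic sign convention
            w, t = -w, -t
        self.weights_ = w
        self.scores_ = t
        cov = float(np.dot(t, yc) / (len(y) - 1))
        self.covariance_explained_ = cov**2
        # least-squares slope of y on the single component, for predict()
        denom = float(np.dot(t, t))
        self.coef_ = cov * (len(y) - 1) / denom if denom > 0 else 0.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean_) @ self.weights_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.y_mean_ + self.coef_ * self.transform(X)


def pls1_fit(X: np.ndarray, y: np.ndarray) -> PLS1Regression:
    """Fit PLS-1 (thin wrapper over :class:`PLS1Regression`)."""
    return PLS1Regression().fit(X, y)


def _batched_cov_explained(xc: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Squared covariance of the PLS-1 score with each column of ``ys``.

    For centered X and centered y the statistic reduces to
    ``(‖Xcᵀ yc‖ / (n − 1))²``, which vectorizes over permutations.
    """
    n = xc.shape[0]
    w_raw = xc.T @ ys  # (R, P)
    return (w_raw**2).sum(axis=0) / (n - 1) ** 2


def pls_permutation_test(
    X: np.ndarray, y: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the covariance explained by PLS-1.

    ``y`` is shuffled across dyads ``n_perm`` times; the add-one estimate
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)`` avoids zero p-values.
    Returns (p, null distribution).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    model = pls1_fit(X, y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    perms = perms - perms.mean(axis=0)
    null = _batched_cov_explained(xc, perms)
    p = (1.0 + np.sum(null >= model.covariance_explained_)) / (1.0 + n_perm)
    return float(p), null


def pls_bootstrap_z(
    X: np.ndarray,
    y: np.ndarray,
    n_boot: int = 500,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Bootstrap reliability of each ROI's PLS-1 weight.

    Dyads are resampled with replacement and PLS-1 refitted; each bootstrap
    weight vector is sign-aligned to the original (flipped when the dot
    product is negative — PLS components are sign-indeterminate, so without
    alignment the SEs would be meaningless). Per ROI,
    ``z = w / SE_boot(w)`` with a normal-theory CI. Degenerate resamples
    (zero-variance y) are redrawn and counted.
    """
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    model = pls1_fit(X, y)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    boot_w = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.std(y[idx]) > 0:
                break
            n_redrawn += 1
        wb = pls1_fit(X[idx], y[idx]).weights_
        if np.dot(wb, model.weights_) < 0:
            wb = -wb
        boot_w[b] = wb
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
    se = boot_w.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, model.weights_ / se, np.inf * np.sign(model.weights_))
    zq = sps.norm.ppf(0.5 + ci_level / 2.0)
    return pd.DataFrame(
        {
            "weight": model.weights_,
            "se": se,
            "z": z,
            "ci_low": model.weights_ - zq * se,
            "ci_high": model.weights_ + zq * se,
        }
    )


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    mask, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return mask, p_adj


@dataclass
class PlsResult:
    """Full PLS-1 inference for one ISTS table."""

    weights: np.ndarray
    covariance_explained: float
    p_permutation: float
    roi_table: pd.DataFrame  # weight, se, z, ci_low, ci_high, p, fdr_significant
    n_perm: int
    n_boot: int
    q: float = 0.05


def pls_inference(
    X: np.ndarray,
    y: np.ndarray,
    roi_ids=None,
    n_perm: int = 5000,
    n_boot: int = 500,
    q: float = 0.05,
    seed: int = 0,
) -> PlsResult:
    """PLS-1 fit + permutation test + bootstrap z + FDR, in one call."""
    model = pls1_fit(X, y)
    p_perm, _ = pls_permutation_test(X, y, n_perm=n_perm, seed=seed)
    table = pls_bootstrap_z(X, y, n_boot=n_boot, seed=seed + 1)
    table["p"] = 2.0 * sps.norm.sf(np.abs(table["z"]))
    mask, p_adj = fdr_correct(table["p"].to_numpy(), q=q)
    table["p_fdr"] = p_adj
    table["fdr_significant"] = mask
    if roi_ids is not None:
        table.insert(0, "roi_id", list(roi_ids))
    return PlsResult(
        weights=model.weights_,
        covariance_explained=model.covariance_explained_,
        p_permutation=p_perm,
        roi_table=table,
        n_perm=n_perm,
        n_boot=n_boot,
        q=q,
    )


# -------------------------------------------------------------- group tests


@dataclass
class GroupTestResult:
    """A single t/F/correlation result with effect size."""

    test: str
    statistic: float
    p: float
    df: float | tuple
    cohens_d: float | None = None
    extra: dict = field(default_factory=dict)


def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d; sign follows mean(a) - mean(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0 if a.mean() == b.mean() else float(np.sign(a.mean() - b.mean()) * np.inf)
    return float((a.mean() - b.mean()) / pooled)


def welch_t(a, b) -> GroupTestResult:
    """Welch two-sample t test (two-tailed) with Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs >=2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupTestResult(
        test="welch_t",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
        cohens_d=cohens_d(a, b),
    )


def two_way_anova(
    df: pd.DataFrame, dv: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way ANOVA (type II) with interaction on a long-format table.

    Covers the fMRI-state x marital-status design on per-dyad whole-brain
    ISTS; marital status may carry two or three levels (couples only, or
    couples plus random pairs).
    """
    for col in (dv, factor_a, factor_b):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} missing")
    counts = df.groupby([factor_a, factor_b], observed=True)[dv].count()
    if (counts < 2).any():
        raise ValidationError("every design cell needs >=2 observations")
    model = ols(f"{dv} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = anova_lm(model, typ=2)
    return table


def correlation(x, y, method: str = "pearson") -> GroupTestResult:
    """Pearson or Spearman correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return GroupTestResult(
        test=method, statistic=float(r), p=float(p), df=float(x.size - 2)
    )


def group_compare(
    values_by_group: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Welch t tests between named groups of per-dyad values."""
    names = list(values_by_group)
    for name, vals in values_by_group.items():
        if len(vals) == 0:
            raise ValidationError(f"group {name!r} is empty")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        res = welch_t(values_by_group[a], values_by_group[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "cohens_d": res.cohens_d,
            }
        )
    return pd.DataFrame(rows)
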