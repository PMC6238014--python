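"""Group-comparison statistics for DAT-imaging method evaluation.

Effect sizes use Glass's delta (standardized by the control-group SD only,
appropriate when disease inflates variance); method agreement uses the
two-way mixed-effects consistency ICC (single rater, ICC(3,1)); diagnostic
accuracy uses the ROC area via the rank (Mann-Whitney) identity with
half-credit for ties; group location differences use the exact two-sided
Mann-Whitney U test.  Lateralization helpers implement left/right averaging
and selection of the hemisphere contralateral to the clinically most
affected body side (the lower-binding hemisphere when symptoms are
symmetric).
"""

from __future__ import annotations

from math import comb
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "glass_delta",
    "glass_delta_from_summary",
    "icc_consistency",
    "roc_auc",
    "mann_whitney_exact",
    "correlations",
    "lr_average",
    "contralateral_select",
    "laterality_concordance",
    "residualize",
]


def glass_delta(hc_values, ps_values) -> float:
    """Glass's delta = (mean_HC - mean_PS) / SD_HC (sample SD, n-1)."""
    hc = np.asarray(hc_values, dtype=float)
    ps = np.asarray(ps_values, dtype=float)
    if hc.size < 2:
        raise ValueError("need at least 2 control values")
    sd = hc.std(ddof=1)
    if sd == 0:
        raise ValueError("control-group SD is zero; Glass's delta undefined")
    return float((hc.mean() - ps.mean()) / sd)


def glass_delta_from_summary(mean_hc: float, mean_ps: float, sd_hc: float) -> float:
    """Glass's delta from published group means and control SD."""
    if sd_hc <= 0:
        raise ValueError("control-group SD must be positive")
    return (mean_hc - mean_ps) / sd_hc


def icc_consistency(x_method1, x_method2) -> float:
    """Single-rater two-way mixed consistency ICC between two paired methods.

    ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1)*MS_error)
    with k = 2 methods and MS terms from the two-way ANOVA decomposition
    without a subject-by-method interaction.
    """
    x = np.asarray(x_method1, dtype=float)
    y = np.asarray(x_method2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("methods must give paired equal-length 1-D data")
    n = x.size
    if n < 3:
        raise ValueError("consistency ICC needs at least 3 subjects")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    meth_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_meth = n * np.sum((meth_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_meth
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    return float((ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err))


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the rank identity with half-credit for ties."""
    scores = np.concatenate([pos, neg])
    ranks = sps.rankdata(scores)
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(
    labels,
    scores,
    direction: str = "higher",
    ci: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """ROC area for binary labels, with a seeded bootstrap 95% CI.

    direction="lower" means a lower score indicates the positive class
    (disease), as for DAT availability; scores are then negated internally.
    Returns (auc, (lo, hi)) or (auc, None) when ci=False.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if direction == "lower":
        scores = -scores
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    pos = scores[labels == classes[1]]
    neg = scores[labels == classes[0]]
    auc = _auc_rank(pos, neg)
    if not ci:
        return auc, None
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, pos.size, pos.size)]
        q = neg[rng.integers(0, neg.size, neg.size)]
        boots[b] = _auc_rank(p, q)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (pairwise x > y count, ties half)."""
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def mann_whitney_exact(
    x,
    y,
    max_enumeration: int = 200_000,
    n_mc: int = 20_000,
    seed: int = 0,
) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of the permutation
    distribution of U (tie-adjusted automatically by mid-ranks).

    When the number of group assignments exceeds max_enumeration, a seeded
    Monte-Carlo permutation approximation with n_mc draws is used instead.
    p = min(1, 2*min(P(U <= u_obs), P(U >= u_obs))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    u_obs = _u_statistic(x, y)
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    if comb(n, n1) <= max_enumeration:
        us = np.fromiter(
            (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)),
            dtype=float,
            count=comb(n, n1),
        )
    else:
        rng = np.random.default_rng(seed)
        us = np.empty(n_mc)
        for b in range(n_mc):
            perm = rng.permutation(n)[:n1]
            us[b] = ranks[perm].sum() - offset
    tol = 1e-9
    p_le = np.mean(us <= u_obs + tol)
    p_ge = np.mean(us >= u_obs - tol)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def correlations(a, b, method: str = "pearson") -> tuple[float, float]:
    """Pearson's r or Spearman's rho with the two-tailed p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired data with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(a, b)
    elif method == "spearman":
        r, p = sps.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


def lr_average(left: float, right: float) -> float:
    """Arithmetic mean of the left- and right-hemisphere values."""
    if left is None or right is None or not (
        np.isfinite(left) and np.isfinite(right)
    ):
        raise ValueError("both hemisphere values are required")
    return (left + right) / 2.0


def contralateral_select(left: float, right: float, clinical_side: str) -> float:
    """Value in the hemisphere contralateral to the affected body side.

    Left-sided symptoms select the right hemisphere and vice versa; with
    symmetric symptoms the lower-binding hemisphere is selected.
    """
    if clinical_side == "left":
        return right
    if clinical_side == "right":
        return left
    if clinical_side == "symmetric":
        return min(left, right)
    raise ValueError("clinical_side must be 'left', 'right' or 'symmetric'")


def laterality_concordance(left_values, right_values, clinical_sides) -> float:
    """Percent of lateralized patients whose lower-binding hemisphere is
    contralateral to the clinical side."""
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    sides = np.asarray(clinical_sides)
    lateralized = (sides == "left") | (sides == "right")
    if not lateralized.any():
        raise ValueError("no lateralized patients")
    expect_left_lower = sides[lateralized] == "right"
    lower_is_left = left[lateralized] < right[lateralized]
    concordant = lower_is_left == expect_left_lower
    return float(concordant.mean() * 100.0)


def residualize(values, covariate) -> np.ndarray:
    """Residuals of a simple linear regression of values on a covariate.

    Used for covariate (age) adjustment before ROC analysis.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    slope, intercept = np.polyfit(covariate, values, 1)
    return values - (slope * covariate + intercept)
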