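"""Core statistics: the CNV weight statistic, its permutation null, and BH-FDR.

The weight statistic for a gene with an altered copy state in some samples is

    w = (m_alt - m_norm) / (sd_alt + sd_norm)

where the means/SDs are taken over the altered-state and normal-state sample
groups (sample SD, n-1 denominator; a singleton group has SD 0).  A large
positive weight for a gain means the gained samples express the gene higher
than the normal ones, with tight within-group spread.  Significance comes from
a permutation null that reassigns the altered/normal labels uniformly at
random while preserving group sizes.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "weight_from_values",
    "permutation_pvalue",
    "perm_index_masks",
    "perm_weights",
]

# tolerance when counting permuted weights >= observed (guards the identity
# permutation against float round-off; exact ties still count)
_TIE_EPS = 1e-12


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    Raises ValueError for p-values outside (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def weight_from_values(altered, normal, direction: str = "gain") -> float:
    """Weight statistic from raw per-sample expression values.

    ``direction='gain'`` returns (m_alt - m_norm)/(sd_alt + sd_norm);
    ``direction='loss'`` flips the numerator to (m_norm - m_alt) so that a
    positive weight always means the expected expression shift (gain -> high,
    loss -> low).  A zero denominator with nonzero numerator returns a signed
    infinity sentinel (ranked most extreme); 0/0 returns 0.
    """
    m1, s1 = _group_mean_sd(altered)
    m0, s0 = _group_mean_sd(normal)
    num = (m1 - m0) if direction == "gain" else (m0 - m1)
    den = s1 + s0
    if den == 0.0:
        if num == 0.0:
            return 0.0
        return float(np.sign(num) * np.inf)
    return num / den


def perm_index_masks(
    n: int,
    k: int,
    n_perm: int,
    seed,
    exhaustive_if_possible: bool = True,
) -> tuple[np.ndarray, bool]:
    """Boolean (P, n) matrix of altered-group assignments.

    When the number of distinct assignments C(n, k) is at most ``n_perm`` and
    exhaustive mode is enabled, every assignment is enumerated exactly once
    (exact null); otherwise ``n_perm`` assignments are drawn uniformly with
    replacement.  Returns (masks, exact_flag).
    """
    if not (0 < k < n):
        raise ValueError("need 0 < k < n for a two-group permutation null")
    n_assign = comb(n, k)
    if exhaustive_if_possible and n_assign <= n_perm:
        masks = np.zeros((n_assign, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), k)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=k, replace=False)] = True
    return masks, False


def perm_weights(values: np.ndarray, masks: np.ndarray, direction: str = "gain") -> np.ndarray:
    """Vectorised weight statistic for every row-mask of ``masks``."""
    x = np.asarray(values, dtype=float)
    n = x.size
    k = int(masks[0].sum())
    m = n - k
    s1 = masks @ x
    ss1 = masks @ (x * x)
    s0 = x.sum() - s1
    ss0 = (x * x).sum() - ss1
    m1 = s1 / k
    m0 = s0 / m
    sd1 = np.sqrt(np.maximum(ss1 - s1 * s1 / k, 0.0) / (k - 1)) if k > 1 else np.zeros_like(s1)
    sd0 = np.sqrt(np.maximum(ss0 - s0 * s0 / m, 0.0) / (m - 1)) if m > 1 else np.zeros_like(s0)
    num = (m1 - m0) if direction == "gain" else (m0 - m1)
    den = sd1 + sd0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = num / den
    zero_den = den == 0.0
    if np.any(zero_den):
        w[zero_den & (num > 0)] = np.inf
        w[zero_den & (num < 0)] = -np.inf
        w[zero_den & (num == 0.0)] = 0.0
    return w


def permutation_pvalue(
    values,
    altered_mask,
    direction: str = "gain",
    n_perm: int = 10000,
    seed=0,
    exhaustive_if_possible: bool = True,
    alternative: str = "greater",
    masks: np.ndarray | None = None,
    exact: bool | None = None,
) -> tuple[float, bool]:
    """One-sided permutation p-value for the observed weight.

    Monte-Carlo mode uses the add-one plug p = (1 + #{w_perm >= w_obs}) /
    (1 + n_perm) so p is never zero; exhaustive enumeration drops the plug
    and returns #{w_perm >= w_obs} / #assignments.  ``alternative='two-sided'``
    compares absolute weights instead.  A precomputed mask matrix (with its
    exact flag) may be supplied to share the null across genes with the same
    group sizes.  Returns (p, exact_flag).
    """
    x = np.asarray(values, dtype=float)
    altered = np.asarray(altered_mask, dtype=bool)
    if x.shape != altered.shape:
        raise ValueError("values and altered_mask must share shape")
    k = int(altered.sum())
    n = x.size
    if k == 0 or k == n:
        raise ValueError("both altered and normal groups must be nonempty")
    if masks is None:
        masks, exact = perm_index_masks(n, k, n_perm, seed, exhaustive_if_possible)
    elif exact is None:
        raise ValueError("exact flag required with precomputed masks")
    w_obs = weight_from_values(x[altered], x[~altered], direction=direction)
    w_perm = perm_weights(x, masks, direction=direction)
    if alternative == "two-sided":
        w_obs_cmp, w_perm_cmp = abs(w_obs), np.abs(w_perm)
    else:
        w_obs_cmp, w_perm_cmp = w_obs, w_perm
    thresh = w_obs_cmp - _TIE_EPS * max(1.0, abs(w_obs_cmp) if np.isfinite(w_obs_cmp) else 1.0)
    count = int(np.sum(w_perm_cmp >= thresh))
    if exact:
        return count / masks.shape[0], True
    return (1 + count) / (1 + masks.shape[0]), False
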