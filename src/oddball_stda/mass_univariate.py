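"""Point-wise paired permutation t-tests over channels x time, FDR control,
window-of-maximum-significance extraction, and paired effect sizes.

The permutation scheme is within-subject sign flipping of the paired
differences: under the null hypothesis of no condition difference, each
subject's difference wave is symmetric around zero, so all 2^S sign
assignments are equally likely.  When the requested permutation count
reaches 2^S the full enumeration is used and p-values are exact.
p-values always include the observed statistic in numerator and
denominator, so p >= 1/(n_perm + 1) and never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatMap",
    "SignificanceMask",
    "perm_paired_ttest",
    "fdr_mask",
    "max_significance_window",
    "cohens_d_paired",
    "sign_flip_matrix",
    "paired_t",
]

_TIE_EPS = 1e-12


@dataclass
class StatMap:
    """t-scores and permutation p-values per (channel, sample)."""

    t: np.ndarray
    p: np.ndarray
    n_subjects: int
    n_permutations: int  # rows actually used (2^S if enumerated)
    exhaustive: bool
    degenerate: np.ndarray  # bool map: zero-variance differences


@dataclass
class SignificanceMask:
    """Boolean discovery map from a Benjamini-Hochberg step-up at level q."""

    mask: np.ndarray
    q_level: float


def sign_flip_matrix(n_subjects: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Sign matrix (rows x subjects) for the paired permutation null.

    If 2^n_subjects <= n_perm the full enumeration is returned (exact test);
    otherwise the observed assignment (all +1) plus n_perm random rows.
    Returns (signs, exhaustive).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    n_all = 2 ** n_subjects if n_subjects < 63 else np.inf
    if n_all <= n_perm:
        bits = np.arange(int(n_all))[:, None] >> np.arange(n_subjects)[None, :]
        return np.where(bits & 1, -1.0, 1.0), True
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm + 1, n_subjects))
    signs[0] = 1.0
    return signs, False


def paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t statistic over axis 0 (subjects); 0 where variance is 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0,
                     np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return t


def signflip_t(diffs2d: np.ndarray, signs: np.ndarray,
               sumsq: np.ndarray | None = None) -> np.ndarray:
    """t statistics of sign-flipped differences, one row per sign pattern.

    Uses the flip-invariance of squared differences so only the flipped sums
    need a matrix product.  The observed statistic must be computed through
    this same formula (an all-ones row) so that the identity and global-flip
    patterns reproduce |t_obs| bit-for-bit in the permutation counts.
    """
    n = diffs2d.shape[0]
    if sumsq is None:
        sumsq = np.sum(diffs2d ** 2, axis=0)
    mean = (signs @ diffs2d) / n
    var = np.maximum(sumsq - n * mean ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        t = np.where(var == 0,
                     np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return t


def _perm_t_counts(diffs2d: np.ndarray, signs: np.ndarray,
                   abs_t_obs: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Count sign-flip rows with |t*| >= |t_obs| per point (chunked GEMM)."""
    sumsq = np.sum(diffs2d ** 2, axis=0)
    counts = np.zeros(diffs2d.shape[1])
    for lo in range(0, signs.shape[0], chunk):
        t = signflip_t(diffs2d, signs[lo:lo + chunk], sumsq)
        counts += np.sum(np.abs(t) >= abs_t_obs[None, :] - _TIE_EPS, axis=0)
    return counts


def perm_paired_ttest(condA: np.ndarray, condB: np.ndarray,
                      n_perm: int = 5000, seed=0) -> StatMap:
    """Point-wise paired sign-flip permutation t-test.

    condA/condB: subjects x channels x samples (or subjects x anything).
    Returns the observed t map and two-tailed permutation p-values.
    Zero-variance (degenerate) points get t = 0, p = 1 when all differences
    vanish.
    """
    condA, condB = np.asarray(condA, float), np.asarray(condB, float)
    if condA.shape != condB.shape:
        raise ValueError("condition arrays must have matching shapes")
    if condA.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    diffs = condA - condB
    shape = diffs.shape[1:]
    d2 = diffs.reshape(diffs.shape[0], -1)

    t_obs = signflip_t(d2, np.ones((1, d2.shape[0])))[0]
    degenerate = np.std(d2, axis=0, ddof=1) == 0
    all_zero = degenerate & (d2.sum(axis=0) == 0)

    signs, exhaustive = sign_flip_matrix(condA.shape[0], n_perm, seed)
    counts = _perm_t_counts(d2, signs, np.abs(t_obs))
    p = counts / signs.shape[0]
    p[all_zero] = 1.0
    t_out = np.where(all_zero, 0.0, t_obs)
    return StatMap(t_out.reshape(shape), p.reshape(shape), condA.shape[0],
                   signs.shape[0], exhaustive, degenerate.reshape(shape))


def fdr_mask(stat: StatMap, q: float = 0.05) -> SignificanceMask:
    """Benjamini-Hochberg step-up jointly over all channel x sample p-values."""
    p = np.asarray(stat.p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return SignificanceMask(reject.reshape(p.shape), q)


def max_significance_window(mask: SignificanceMask, times_ms: np.ndarray,
                            channel_labels) -> dict | None:
    """Longest run of samples whose significant-electrode count stays >= 90%
    of the global maximum; plus the electrodes significant anywhere in it.

    Returns None for an empty mask.  Ties between equally long runs break to
    the earliest.
    """
    m = np.asarray(mask.mask, bool)
    counts = m.sum(axis=0)
    gmax = counts.max() if counts.size else 0
    if gmax == 0:
        return None
    ok = counts >= 0.9 * gmax
    best_lo, best_len = None, 0
    lo = None
    for i, v in enumerate(np.append(ok, False)):
        if v and lo is None:
            lo = i
        elif not v and lo is not None:
            if i - lo > best_len:
                best_lo, best_len = lo, i - lo
            lo = None
    sl = slice(best_lo, best_lo + best_len)
    electrodes = [channel_labels[c] for c in np.flatnonzero(m[:, sl].any(axis=1))]
    return {
        "t_start_ms": float(times_ms[sl][0]),
        "t_end_ms": float(times_ms[sl][-1]),
        "sample_slice": (best_lo, best_lo + best_len),
        "electrodes": electrodes,
        "peak_count": int(gmax),
    }


def cohens_d_paired(condA: np.ndarray, condB: np.ndarray) -> np.ndarray:
    """Paired Cohen's d per point: mean(diff)/sd(diff); NaN where sd = 0."""
    condA, condB = np.asarray(condA, float), np.asarray(condB, float)
    if condA.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    diffs = condA - condB
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diffs.mean(axis=0) / sd
    return np.where(sd == 0, np.nan, d)
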