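"""Monte-Carlo calibration experiments for the inference machinery.

These utilities verify, on synthetic null or known-effect data, that the
statistical procedures deliver their nominal guarantees: per-cell type-I
error of the point-wise permutation test, family-wise error of the
cluster-mass and SnPM max-statistic tests, false-discovery proportion of
the BH mask, and sLORETA's zero localization error for noiseless point
sources.  They are used by the acceptance/validation scripts and tests.
"""

from __future__ import annotations

import numpy as np

from .cluster_perm import ClusterTestConfig, build_adjacency, cluster_mass_test
from .forward_model import Montage, build_source_grid, compute_leadfield, \
    standard_montage_1010
from .mass_univariate import fdr_mask, perm_paired_ttest
from .sloreta import InverseConfig, compute_inverse_operator, localize
from .snpm import snpm_paired_test

__all__ = [
    "pointwise_type1_experiment",
    "cluster_fwer_experiment",
    "snpm_fwer_experiment",
    "fdr_fdp_experiment",
    "zero_localization_experiment",
]

_CAL_CHANNELS = ("F3", "Fz", "F4", "FC1", "FCz", "FC2", "C1", "Cz")


def _null_shape(n_subjects, n_channels, n_samples):
    return (n_subjects, n_channels, n_samples)


def pointwise_type1_experiment(n_sims: int = 500, n_subjects: int = 12,
                               n_channels: int = 8, n_samples: int = 50,
                               alpha: float = 0.05, n_perm: int = 5000,
                               seed: int = 0) -> float:
    """Mean fraction of (channel, sample) cells with p <= alpha under the
    global null (white-noise differences); should approximate alpha."""
    rates = np.empty(n_sims)
    for i in range(n_sims):
        rng = np.random.default_rng([seed, 50, i])
        a = rng.standard_normal(_null_shape(n_subjects, n_channels, n_samples))
        b = rng.standard_normal(_null_shape(n_subjects, n_channels, n_samples))
        stat = perm_paired_ttest(a, b, n_perm=n_perm, seed=[seed, 51, i])
        rates[i] = np.mean(stat.p <= alpha)
    return float(rates.mean())


def _calibration_adjacency(montage: Montage | None = None):
    montage = montage or standard_montage_1010()
    return build_adjacency(montage, channels=list(_CAL_CHANNELS))


def cluster_fwer_experiment(n_sims: int = 200, n_subjects: int = 12,
                            n_samples: int = 50, family_alpha: float = 0.05,
                            n_perm: int = 500, seed: int = 0) -> float:
    """Fraction of null simulations in which any cluster reaches
    p <= family_alpha (family-wise error of the cluster-mass test)."""
    adjacency = _calibration_adjacency()
    n_ch = len(adjacency.labels)
    hits = 0
    for i in range(n_sims):
        rng = np.random.default_rng([seed, 52, i])
        diffs = rng.standard_normal(_null_shape(n_subjects, n_ch, n_samples))
        res = cluster_mass_test(
            diffs, ClusterTestConfig(n_perm=n_perm, seed=[seed, 53, i]),
            adjacency)
        hits += any(c.p_value <= family_alpha for c in res.clusters)
    return hits / n_sims


def snpm_fwer_experiment(n_sims: int = 200, n_subjects: int = 12,
                         n_voxels: int = 50, alpha: float = 0.05,
                         n_perm: int = 5000, seed: int = 0) -> float:
    """Fraction of null simulations with any voxel above t_crit(alpha)."""
    hits = 0
    for i in range(n_sims):
        rng = np.random.default_rng([seed, 54, i])
        a = rng.standard_normal((n_subjects, n_voxels))
        b = rng.standard_normal((n_subjects, n_voxels))
        res = snpm_paired_test(a, b, n_perm=n_perm, alphas=(alpha,),
                               seed=[seed, 55, i])
        hits += bool(res.suprathreshold(alpha).any())
    return hits / n_sims


def fdr_fdp_experiment(n_sims: int = 200, n_subjects: int = 12,
                       n_channels: int = 8, n_samples: int = 50,
                       effect_fraction: float = 0.1, effect_d: float = 1.5,
                       q: float = 0.05, n_perm: int = 5000,
                       seed: int = 0) -> float:
    """Mean false-discovery proportion of the BH mask with sparse true
    effects of standardized size `effect_d` (should stay near or below q)."""
    fdps = np.empty(n_sims)
    m = n_channels * n_samples
    k_true = int(round(effect_fraction * m))
    for i in range(n_sims):
        rng = np.random.default_rng([seed, 56, i])
        diffs = rng.standard_normal((n_subjects, m))
        true_cells = rng.choice(m, size=k_true, replace=False)
        diffs[:, true_cells] += effect_d  # unit-sd differences: d = effect_d
        stat = perm_paired_ttest(
            diffs.reshape(n_subjects, n_channels, n_samples),
            np.zeros((n_subjects, n_channels, n_samples)),
            n_perm=n_perm, seed=[seed, 57, i])
        mask = fdr_mask(stat, q).mask.ravel()
        n_disc = mask.sum()
        truth = np.zeros(m, bool)
        truth[true_cells] = True
        fdps[i] = (mask & ~truth).sum() / n_disc if n_disc else 0.0
    return float(fdps.mean())


def zero_localization_experiment(seed: int = 0, head_radius_cm: float = 9.2,
                                 inner_radius_cm: float = 7.8,
                                 spacing_mm: float = 10.0,
                                 alpha: float = 1e-3) -> dict:
    """sLORETA zero-localization-error scan over every grid voxel.

    Each voxel in turn is a noiseless source with a random moment; the
    standardized image must peak at the true voxel.  Returns the fraction
    of exactly localized voxels and the voxel count.
    """
    montage = standard_montage_1010(head_radius_cm)
    grid = build_source_grid(inner_radius_cm, spacing_mm)
    lf = compute_leadfield(montage, grid, reference="CAR",
                           channels=montage.scalp_labels)
    op = compute_inverse_operator(lf, InverseConfig(alpha=alpha))
    rng = np.random.default_rng(seed)
    correct = 0
    for v in range(grid.n_voxels):
        topo = lf.gain[:, v, :] @ rng.standard_normal(3)
        correct += localize(topo, op).peak_voxel == v
    return {"fraction_correct": correct / grid.n_voxels,
            "n_voxels": grid.n_voxels}
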