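"""Spherical head model: montage geometry, source lattice, analytic lead field."""

import numpy as np
import pytest
from scipy.special import eval_legendre, lpmv

from oddball_stda.forward_model import (
    MONTAGE_64_LABELS,
    EmptyGridError,
    SingularGeometryError,
    _sphere_dipole_gain,
    build_source_grid,
    compute_leadfield,
    read_montage_sfp,
    standard_montage_1010,
    write_montage_sfp,
)

R = 9.2


def series_potential(e_cm, d_cm, q_nAm, R_cm, sigma=0.33, n_terms=400):
    """Independent oracle: truncated Legendre-series surface potential."""
    R_ = R_cm / 100
    e = np.asarray(e_cm) / 100
    d = np.asarray(d_cm) / 100
    q = np.asarray(q_nAm) * 1e-9
    b = np.linalg.norm(d)
    bh = d / b if b > 1e-12 else np.array([0.0, 0.0, 1.0])
    eh = e / np.linalg.norm(e)
    x = float(np.clip(eh @ bh, -1, 1))
    f = b / R_
    qr = q @ bh
    t = eh - x * bh
    st = np.linalg.norm(t)
    qt = q @ t / st if st > 1e-12 else 0.0
    tot = 0.0
    for n in range(1, n_terms + 1):
        Pn = eval_legendre(n, x)
        Pn1 = -lpmv(1, n, x)  # without Condon-Shortley phase
        tot += (2 * n + 1) / n * f ** (n - 1) * (n * qr * Pn + qt * Pn1)
    return tot / (4 * np.pi * sigma * R_**2) * 1e6


class TestMontage:
    def test_has_the_64_study_channels(self, montage):
        assert len(montage.labels) == 64
        assert montage.labels == tuple(MONTAGE_64_LABELS)
        assert len(montage.scalp_labels) == 62
        assert "M1" not in montage.scalp_labels

    def test_cz_at_apex_and_all_on_sphere(self, montage):
        np.testing.assert_allclose(montage.position("Cz"), [0, 0, R], atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(montage.positions, axis=1), R,
                                   atol=1e-9)

    def test_sagittal_mirror_symmetry(self, montage):
        """Left/right homologue electrodes are exact sagittal mirrors."""
        flip = np.array([-1.0, 1.0, 1.0])
        for label in montage.labels:
            digits = "".join(c for c in label if c.isdigit())
            if not digits or int(digits) % 2 != 0:
                continue
            left = label[: len(label) - len(digits)] + str(int(digits) - 1)
            np.testing.assert_allclose(
                montage.position(left), montage.position(label) * flip,
                atol=1e-12, err_msg=f"{left} vs {label}")

    def test_midline_channels_on_sagittal_plane(self, montage):
        for label in ("Fpz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"):
            assert abs(montage.position(label)[0]) < 1e-12

    def test_agrees_angularly_with_mne_template(self, montage):
        """Sanity cross-check against mne's realistic 10/05 positions.

        A realistic head is not a sphere (temporal sites sit lower), so only
        coarse angular agreement is expected: every probe stays within 30
        degrees and well-separated sites remain well separated.
        """
        mne = pytest.importorskip("mne")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = mne.channels.make_standard_montage("standard_1005")
        pos = std.get_positions()["ch_pos"]
        # mne's template is in an MRI frame: recentre on the best-fit sphere
        pts = np.array([pos[l] for l in montage.labels])
        A = np.column_stack([2 * pts, np.ones(len(pts))])
        b = (pts**2).sum(axis=1)
        center = np.linalg.lstsq(A, b, rcond=None)[0][:3]
        for label in ("Fz", "Cz", "Pz", "Oz", "T7", "T8", "C3", "C4", "F3",
                      "P4", "FCz", "PO3"):
            v_mne = np.asarray(pos[label]) - center
            v_mne = v_mne / np.linalg.norm(v_mne)
            v = montage.position(label) / R
            ang = np.degrees(np.arccos(np.clip(v @ v_mne, -1, 1)))
            assert ang < 30.0, f"{label}: {ang:.1f} deg"

    def test_sfp_round_trip(self, montage, tmp_path):
        path = tmp_path / "montage.sfp"
        write_montage_sfp(montage, path)
        back = read_montage_sfp(path)
        assert back.labels == montage.labels
        np.testing.assert_allclose(back.positions, montage.positions, atol=1e-5)

    def test_positive_radius_required(self):
        with pytest.raises(ValueError):
            standard_montage_1010(-1.0)


class TestSourceGrid:
    @pytest.mark.parametrize("radius_cm,spacing_mm", [(1.0, 5.0), (2.5, 7.5),
                                                      (7.8, 10.0)])
    def test_count_matches_bruteforce_lattice(self, radius_cm, spacing_mm):
        grid = build_source_grid(radius_cm, spacing_mm)
        h = spacing_mm / 10.0
        n = int(np.floor(radius_cm / h))
        count = 0
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                for k in range(-n, n + 1):
                    if (i * i + j * j + k * k) * h * h < radius_cm**2:
                        count += 1
        assert grid.n_voxels == count

    def test_all_voxels_strictly_inside(self, grid):
        assert np.all(np.linalg.norm(grid.positions, axis=1)
                      < grid.inner_radius_cm)

    def test_halving_spacing_scales_count_by_about_eight(self):
        c1 = build_source_grid(5.0, 10.0).n_voxels
        c2 = build_source_grid(5.0, 5.0).n_voxels
        assert 0.8 * 8 < c2 / c1 < 1.2 * 8

    def test_empty_grid_raises(self):
        with pytest.raises(EmptyGridError):
            build_source_grid(0.4, 10.0)  # spacing exceeds the radius


class TestLeadField:
    def test_linearity_in_moment(self, montage, grid):
        lf = compute_leadfield(montage, grid)
        q = np.array([3.0, -1.0, 2.0])
        v1 = lf.gain[:, 10, :] @ q
        v2 = lf.gain[:, 10, :] @ (2 * q)
        np.testing.assert_allclose(v2, 2 * v1, rtol=1e-12)

    def test_car_columns_sum_to_zero(self, leadfield_car):
        sums = leadfield_car.gain2d.sum(axis=0)
        assert np.abs(sums).max() < 1e-10

    def test_matches_independent_series_oracle(self, montage, rng):
        """Closed-form potentials equal a second, independently coded
        Legendre-series evaluation at 5 electrodes."""
        electrodes = montage.positions[:5]
        for _ in range(4):
            d = rng.uniform(-4, 4, 3)
            q = rng.uniform(-20, 20, 3)
            gain = _sphere_dipole_gain(electrodes, d[None, :], R)
            v = gain[:, 0, :] @ q
            oracle = [series_potential(e, d, q, R) for e in electrodes]
            np.testing.assert_allclose(v, oracle, atol=1e-10)

    def test_mirror_symmetry_of_potentials(self, montage):
        """A dipole mirrored across the sagittal plane maps left/right
        electrode potentials onto each other."""
        d = np.array([3.0, 1.5, 2.0])
        q = np.array([1.0, 2.0, -1.5])
        d_m = d * [-1, 1, 1]
        q_m = q * [-1, 1, 1]
        v = _sphere_dipole_gain(montage.positions, d[None], R)[:, 0, :] @ q
        v_m = _sphere_dipole_gain(montage.positions, d_m[None], R)[:, 0, :] @ q_m
        for label in ("C4", "F4", "P4", "T8", "M2", "O2", "Fp2"):
            digits = "".join(c for c in label if c.isdigit())
            left = label[: len(label) - len(digits)] + str(int(digits) - 1)
            i, j = montage.index(left), montage.index(label)
            assert abs(v[j] - v_m[i]) < 1e-8

    def test_deeper_dipole_has_weaker_scalp_maximum(self, montage):
        q = np.array([0.0, 0.0, 10.0])
        prev = np.inf
        for r in (7.0, 5.5, 4.0, 2.5, 1.0):
            d = np.array([r / np.sqrt(2), 0.0, r / np.sqrt(2)])
            v = _sphere_dipole_gain(montage.positions, d[None], R)[:, 0, :] @ q
            peak = np.abs(v).max()
            assert peak < prev
            prev = peak

    def test_dipole_on_surface_raises(self, montage, grid):
        with pytest.raises(SingularGeometryError):
            _sphere_dipole_gain(montage.positions, np.array([[0.0, 0.0, R]]), R)

    def test_channel_subset_and_reference(self, montage, grid):
        lf = compute_leadfield(montage, grid, reference="linked-mastoid")
        i1, i2 = lf.labels.index("M1"), lf.labels.index("M2")
        mast_mean = 0.5 * (lf.gain2d[i1] + lf.gain2d[i2])
        assert np.abs(mast_mean).max() < 1e-12
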