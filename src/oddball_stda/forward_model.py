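"""Spherical head model: 10/10 montage, gridded source space, analytic lead field.

The head is modelled as a homogeneous conducting sphere (default radius
9.2 cm, conductivity 0.33 S/m).  Electrode positions are idealized 10/10
coordinates on that sphere; sources live on a regular cubic lattice strictly
inside an inner "brain" radius.  The lead field is the closed-form surface
potential of a current dipole inside a bounded homogeneous sphere, obtained
by summing the Legendre expansion analytically.

Coordinates are head-centred Cartesian in cm: +x right, +y anterior,
+z superior.  Gain units are microvolts per nA*m of dipole moment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "SourceGrid",
    "LeadField",
    "standard_montage_1010",
    "build_source_grid",
    "compute_leadfield",
    "read_montage_sfp",
    "write_montage_sfp",
    "MONTAGE_64_LABELS",
    "MASTOID_LABELS",
]

#: The 64 recording sites of the study montage, in acquisition order.
MONTAGE_64_LABELS = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "M1", "M2",
]

MASTOID_LABELS = ("M1", "M2")

DEFAULT_HEAD_RADIUS_CM = 9.2
DEFAULT_CONDUCTIVITY_S_PER_M = 0.33


class SingularGeometryError(ValueError):
    """Raised when a dipole sits on or outside the electrode sphere."""


class EmptyGridError(ValueError):
    """Raised when grid parameters yield no voxels."""


@dataclass(frozen=True)
class Montage:
    """Labelled 3D electrode positions on a spherical head surface."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), cm
    head_radius_cm: float

    def __post_init__(self):
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions shape must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_labels(self) -> tuple[str, ...]:
        """All labels except the mastoids M1/M2 (the 62-channel statistics set)."""
        return tuple(l for l in self.labels if l not in MASTOID_LABELS)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx].copy(), self.head_radius_cm)


@dataclass(frozen=True)
class SourceGrid:
    """Regular cubic lattice of source voxels inside the inner head radius."""

    positions: np.ndarray  # (n_voxels, 3), cm
    spacing_mm: float
    inner_radius_cm: float

    @property
    def n_voxels(self) -> int:
        return self.positions.shape[0]

    @property
    def spacing_cm(self) -> float:
        return self.spacing_mm / 10.0

    def nearest_voxel(self, point_cm) -> int:
        d = np.linalg.norm(self.positions - np.asarray(point_cm, float), axis=1)
        return int(np.argmin(d))


@dataclass
class LeadField:
    """Linear forward operator: channels x voxels x 3 orientations, uV per nA*m."""

    gain: np.ndarray  # (n_channels, n_voxels, 3)
    labels: tuple[str, ...]
    grid: SourceGrid
    reference: str = "infinite"  # {"infinite", "CAR", "linked-mastoid"}

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def gain2d(self) -> np.ndarray:
        """Gain reshaped to (channels, voxels*3) with orientation fastest."""
        return self.gain.reshape(self.gain.shape[0], -1)

    def column(self, voxel: int, orientation) -> np.ndarray:
        """Sensor topography of a unit dipole at `voxel` with moment `orientation`."""
        o = np.asarray(orientation, float)
        return self.gain[:, voxel, :] @ o


# ---------------------------------------------------------------------------
# Montage construction
# ---------------------------------------------------------------------------

def _ring_azimuths() -> dict[str, float]:
    """Azimuth (deg, from anterior midline, positive right) of outer-ring sites."""
    order = ["Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2", "Oz"]
    az = {name: 18.0 * i for i, name in enumerate(order)}
    mirror = {"Fp2": "Fp1", "AF8": "AF7", "F8": "F7", "FT8": "FT7", "T8": "T7",
              "TP8": "TP7", "P8": "P7", "PO8": "PO7", "O2": "O1"}
    for r, l in mirror.items():
        az[l] = -az[r]
    return az


# Rows interpolated between a midline anchor and the corresponding outer-ring
# anchors.  Each entry: (midline site, inclination of midline site in deg
# signed + anterior / - posterior, ring site right, intermediate labels from
# midline outward on the right side).
_ROWS = [
    ("AFz", 54.0, "AF8", ["AF4"]),
    ("Fz", 36.0, "F8", ["F2", "F4", "F6"]),
    ("FCz", 18.0, "FT8", ["FC2", "FC4", "FC6"]),
    ("Cz", 0.0, "T8", ["C2", "C4", "C6"]),
    ("CPz", -18.0, "TP8", ["CP2", "CP4", "CP6"]),
    ("Pz", -36.0, "P8", ["P2", "P4", "P6"]),
    ("POz", -54.0, "PO8", ["PO4", "PO6"]),
]

_MIDLINE_INCLINATION = {
    "Fpz": 72.0, "AFz": 54.0, "Fz": 36.0, "FCz": 18.0, "Cz": 0.0,
    "CPz": -18.0, "Pz": -36.0, "POz": -54.0, "Oz": -72.0,
}

_RING_INCLINATION = 72.0

# Mastoids: on the sphere, below and slightly posterior to T7/T8.
_MASTOID_INCLINATION = 108.0
_MASTOID_AZIMUTH = 100.0


def _mirror_label(label: str) -> str:
    """Map a right-hemisphere 10/10 label to its left homologue."""
    digits = "".join(c for c in label if c.isdigit())
    stem = label[: len(label) - len(digits)]
    return stem + str(int(digits) - 1)


def _flat_to_sphere(r_deg: float, az_deg: float, radius: float) -> np.ndarray:
    """Azimuthal-equidistant flat coordinates -> point on the sphere.

    r_deg is the inclination from the vertex; az_deg the azimuth from the
    anterior midline, positive toward the right ear.
    """
    inc = math.radians(r_deg)
    az = math.radians(az_deg)
    return radius * np.array(
        [math.sin(inc) * math.sin(az), math.sin(inc) * math.cos(az), math.cos(inc)]
    )


def standard_montage_1010(head_radius_cm: float = DEFAULT_HEAD_RADIUS_CM) -> Montage:
    """Idealized spherical 10/10 montage for the 64-channel study layout.

    Sites on the sagittal midline and the 10% outer ring have exact 10/10
    angular coordinates; intermediate rows (e.g. F5..F1) are placed by equal
    steps along the row's arc in the azimuthal-equidistant projection, the
    construction used for standard flat electrode layouts.  Cz is exactly at
    the apex (0, 0, R) and the montage is exactly mirror-symmetric about the
    sagittal plane.
    """
    if head_radius_cm <= 0:
        raise ValueError("head radius must be positive")
    R = head_radius_cm
    pos: dict[str, np.ndarray] = {}

    for name, inc in _MIDLINE_INCLINATION.items():
        # signed inclination: positive anterior
        pos[name] = _flat_to_sphere(abs(inc), 0.0 if inc >= 0 else 180.0, R)
    ring_az = _ring_azimuths()
    for name, az in ring_az.items():
        pos[name] = _flat_to_sphere(_RING_INCLINATION, az, R)

    def flat(r_deg, az_deg):
        a = math.radians(az_deg)
        return np.array([r_deg * math.sin(a), r_deg * math.cos(a)])

    for mid, mid_inc, ring_right, intermediates in _ROWS:
        p_mid = flat(abs(mid_inc), 0.0 if mid_inc >= 0 else 180.0)
        p_ring = flat(_RING_INCLINATION, ring_az[ring_right])
        n_steps = len(intermediates) + 1
        for k, name in enumerate(intermediates, start=1):
            p2 = p_mid + (k / n_steps) * (p_ring - p_mid)
            r = float(np.linalg.norm(p2))
            az = math.degrees(math.atan2(p2[0], p2[1]))
            pos[name] = _flat_to_sphere(r, az, R)
            left = _mirror_label(name)
            pos[left] = pos[name] * np.array([-1.0, 1.0, 1.0])

    pos["M2"] = _flat_to_sphere(_MASTOID_INCLINATION, _MASTOID_AZIMUTH, R)
    pos["M1"] = pos["M2"] * np.array([-1.0, 1.0, 1.0])

    positions = np.array([pos[l] for l in MONTAGE_64_LABELS])
    return Montage(tuple(MONTAGE_64_LABELS), positions, R)


def read_montage_sfp(path) -> Montage:
    """Read a .sfp-style montage file: one `label x y z` line per channel (cm)."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    positions = np.array(rows)
    radius = float(np.median(np.linalg.norm(positions, axis=1)))
    return Montage(tuple(labels), positions, radius)


def write_montage_sfp(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        for label, p in zip(montage.labels, montage.positions):
            fh.write(f"{label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Source grid
# ---------------------------------------------------------------------------

def build_source_grid(inner_radius_cm: float = 7.8, spacing_mm: float = 10.0) -> SourceGrid:
    """Cubic lattice of voxel centres with ``|p| < inner_radius``.

    The lattice is centred on the head origin (a voxel sits exactly at the
    centre), mirroring volumetric source spaces gridded at fixed spacing.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    h = spacing_mm / 10.0
    if h > 2 * inner_radius_cm:
        raise EmptyGridError("spacing exceeds the source-compartment diameter")
    n = int(math.floor(inner_radius_cm / h))
    if n < 0 or inner_radius_cm <= 0:
        raise EmptyGridError("no lattice points inside the given radius")
    axis = np.arange(-n, n + 1) * h
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = np.linalg.norm(pts, axis=1) < inner_radius_cm
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise EmptyGridError("no lattice points inside the given radius")
    return SourceGrid(pts, spacing_mm, inner_radius_cm)


# ---------------------------------------------------------------------------
# Lead field
# ---------------------------------------------------------------------------

def _sphere_dipole_gain(electrodes_cm: np.ndarray, dipoles_cm: np.ndarray,
                        head_radius_cm: float,
                        sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M) -> np.ndarray:
    """Closed-form surface potential of current dipoles in a homogeneous sphere.

    Returns gain with shape (n_electrodes, n_dipoles, 3): potential in uV at
    each electrode for unit dipole moments (1 nA*m) along x, y, z.

    The Legendre series for the bounded homogeneous sphere,

        V = 1/(4 pi sigma R^2) * sum_n (2n+1)/n * f^(n-1)
            * [ n q_r P_n(x) + q_t P_n^1(x) ],

    with f = b/R (b the dipole eccentricity) and x = cos(gamma) the cosine of
    the electrode-dipole angle, is summed in closed form using the Legendre
    generating function, giving

        V = 1/(4 pi sigma R^2) [ (q . b_hat) A + (q . (e_hat - x b_hat)) B ],
        A  = 2 (x - f)/g^3 + (1/g - 1)/f,
        B  = 2/g^3 + ((f - x)/g + x) / (f (1 - x^2)),
        g  = sqrt(1 - 2 f x + f^2)  (so that R*g is the electrode-dipole
             distance).
    """
    R_m = head_radius_cm / 100.0
    e = np.asarray(electrodes_cm, float) / 100.0      # (E, 3) m
    d = np.asarray(dipoles_cm, float) / 100.0          # (D, 3) m

    b = np.linalg.norm(d, axis=1)                      # (D,)
    if np.any(b >= R_m * (1 - 1e-9)):
        raise SingularGeometryError("dipole at or outside the electrode sphere")
    e_norm = np.linalg.norm(e, axis=1)
    if not np.allclose(e_norm, R_m, rtol=1e-6):
        raise SingularGeometryError("electrodes must lie on the head sphere")

    e_hat = e / e_norm[:, None]                        # (E, 3)
    # dipole radial unit vector; arbitrary axis for a central dipole (f -> 0
    # limit is rotationally well-defined, see below)
    safe_b = np.where(b > 0, b, 1.0)
    b_hat = d / safe_b[:, None]
    b_hat[b == 0] = np.array([0.0, 0.0, 1.0])

    f = b / R_m                                        # (D,)
    x = np.clip(e_hat @ b_hat.T, -1.0, 1.0)            # (E, D)
    g = np.sqrt(np.maximum(1.0 - 2.0 * f[None, :] * x + f[None, :] ** 2, 1e-300))

    small = f < 1e-6
    f_safe = np.where(small, 1.0, f)[None, :]

    # radial factor A
    A = 2.0 * (x - f[None, :]) / g**3 + (1.0 / g - 1.0) / f_safe
    # f -> 0 limit: A -> 3x  (n=1 term only)
    A = np.where(small[None, :], 3.0 * x, A)

    # tangential factor B = B_tilde / (1 - x^2), computed with its x -> +-1 limit
    sin2 = 1.0 - x**2
    degenerate = sin2 < 1e-12
    sin2_safe = np.where(degenerate, 1.0, sin2)
    B = 2.0 / g**3 + ((f[None, :] - x) / g + x) / (f_safe * sin2_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        # limit of ((f-x)/g + x)/(1-x^2) as x -> +-1
        gl = np.abs(1.0 - np.sign(x) * f[None, :])
        B_lim = 2.0 / gl**3 + np.sign(x) * (2.0 - np.sign(x) * f[None, :]) / (
            2.0 * gl**2
        )
    B = np.where(degenerate, B_lim, B)
    B = np.where(small[None, :], 3.0, B)               # f -> 0 limit: B -> 3

    # assemble vector form: V = C [ (q.b_hat) A + (q.(e_hat - x b_hat)) B ]
    # gain[e, d, :] = C * ( A[e,d] * b_hat[d] + B[e,d] * (e_hat[e] - x[e,d] b_hat[d]) )
    C = 1.0 / (4.0 * math.pi * sigma * R_m**2)
    gain = C * (
        A[:, :, None] * b_hat[None, :, :]
        + B[:, :, None] * (e_hat[:, None, :] - x[:, :, None] * b_hat[None, :, :])
    )
    # moments in nA*m (1e-9 A*m), potentials in uV (1e6): net factor 1e-3
    return gain * 1e-3


def _car_matrix(n: int) -> np.ndarray:
    return np.eye(n) - np.ones((n, n)) / n


def apply_reference(gain: np.ndarray, labels, scheme: str,
                    montage: Montage | None = None) -> np.ndarray:
    """Re-reference a gain array (channels first) in place of its raw reference."""
    flat = gain.reshape(gain.shape[0], -1)
    if scheme == "infinite":
        out = flat
    elif scheme == "CAR":
        out = _car_matrix(gain.shape[0]) @ flat
    elif scheme == "linked-mastoid":
        labels = list(labels)
        try:
            i1, i2 = labels.index("M1"), labels.index("M2")
        except ValueError:
            raise KeyError("linked-mastoid reference requires M1 and M2") from None
        out = flat - 0.5 * (flat[i1] + flat[i2])[None, :]
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return out.reshape(gain.shape)


def compute_leadfield(montage: Montage, grid: SourceGrid,
                      reference: str = "infinite",
                      channels: "list[str] | None" = None,
                      sigma: float = DEFAULT_CONDUCTIVITY_S_PER_M) -> LeadField:
    """Analytic single-sphere lead field for `montage` and `grid`.

    `channels` restricts the operator to a channel subset (e.g. the 62 scalp
    channels for source analysis); the reference is applied over exactly the
    channels present in the operator.
    """
    if grid.n_voxels == 0:
        raise EmptyGridError("source grid is empty")
    if channels is None:
        channels = list(montage.labels)
    sub = montage.subset(channels)
    gain = _sphere_dipole_gain(sub.positions, grid.positions,
                               montage.head_radius_cm, sigma)
    gain = apply_reference(gain, sub.labels, reference, montage=sub)
    return LeadField(gain, sub.labels, grid, reference)


def save_leadfield_hdf5(lf: LeadField, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("voxels", data=lf.grid.positions)
        f.attrs["reference"] = lf.reference
        f.attrs["spacing_mm"] = lf.grid.spacing_mm
        f.attrs["inner_radius_cm"] = lf.grid.inner_radius_cm
        f.create_dataset("labels", data=np.array(lf.labels, dtype="S"))


def load_leadfield_hdf5(path) -> LeadField:
    import h5py

    with h5py.File(path, "r") as f:
        gain = f["gain"][()]
        grid = SourceGrid(f["voxels"][()], float(f.attrs["spacing_mm"]),
                          float(f.attrs["inner_radius_cm"]))
        labels = tuple(s.decode() for s in f["labels"][()])
        return LeadField(gain, labels, grid, str(f.attrs["reference"]))
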