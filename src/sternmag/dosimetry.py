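"""Magnetostatic dosimetry for miniature audio-frequency solenoid stimulators.

The stimulator is a set of small multi-turn solenoids driven by an audio
signal.  The drive current follows from the series RLC impedance

    I = V / sqrt(R^2 + (L*w - 1/(C*w))^2),   w = 2*pi*f

(the parasitic-capacitance branch is open by default).  Each solenoid is
discretized as a helix of directed current elements and the magnetic
induction B at any point is the Biot–Savart superposition

    B(r) = mu0/(4*pi) * sum_i I * dl_i x (r - r'_i) / |r - r'_i|^3 .

Discretization uses midpoint quadrature of the line integral: element
midpoints lie exactly on the helix and dl is the local tangent times the
parameter step, which reproduces the loop-centre closed form exactly and
converges quickly on the coil axis.  A helper assembles the study geometry —
two coaxial solenoids per side of a head-width gap, mirror-symmetric, all in
series — and evaluates |B| over a lattice spanning the head volume.  The
induced eddy-current heating in a conductive tissue slab is summarized by
the power density per unit mass

    P = pi^2 * B^2 * d^2 * f^2 / (6 * rho * D)   [W/kg].

Units: SI internally (m, T, A); grid I/O in mm and field summaries in uT.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Vacuum permeability, H/m (value at the precision used throughout).
MU0 = 1.257e-6

#: Half the diameter of AWG-40 wire, m: evaluation points closer than this to
#: any current element sit "inside the wire" and are flagged invalid.
DEFAULT_GUARD_RADIUS = 4.0e-5


class DosimetryError(ValueError):
    pass


@dataclass(frozen=True)
class SolenoidSpec:
    """Geometry and lumped electrical model of one solenoid winding.

    Defaults are the stimulator coil: 6.5 mm long, 7 mm mean diameter,
    800 turns of AWG-40 copper wire, 96 ohm total resistance and 4.7 mH
    total inductance.  ``capacitance`` is the parasitic capacitance (None =
    open branch).  ``polarity`` flips the winding sense.
    """

    length: float = 6.5e-3
    mean_diameter: float = 7.0e-3
    turns: int = 800
    resistance: float = 96.0
    inductance: float = 4.7e-3
    capacitance: float | None = None
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mean_diameter <= 0:
            raise ValueError("solenoid dimensions must be positive")
        if self.turns < 1:
            raise ValueError("need at least one turn")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        n = np.linalg.norm(self.axis)
        if not np.isclose(n, 1.0, atol=1e-9):
            object.__setattr__(self, "axis", tuple(np.asarray(self.axis) / n))

    @property
    def radius(self) -> float:
        return self.mean_diameter / 2.0


@dataclass(frozen=True)
class DriveSignal:
    """Sinusoidal drive: generator voltage amplitude (V) and frequency (Hz)."""

    voltage_amplitude: float = 0.5
    frequency: float = 10_000.0
    enforce_audio_band: bool = True

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.enforce_audio_band and not (20.0 <= self.frequency <= 20_000.0):
            raise ValueError(
                f"frequency {self.frequency} Hz outside the audio band (20 Hz - 20 kHz); "
                "set enforce_audio_band=False to override"
            )

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency


@dataclass(frozen=True)
class TissueParams:
    """Conductive tissue slab for the eddy-current power estimate.

    Defaults: 1 cm slab under the scalp, resistivity 0.2 ohm*m (conductivity
    0.5 S/m), density 1000 kg/m^3.
    """

    slab_thickness: float = 0.01
    resistivity: float = 0.2
    density: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.slab_thickness, self.resistivity, self.density) <= 0:
            raise ValueError("tissue parameters must be positive")

    @property
    def conductivity(self) -> float:
        return 1.0 / self.resistivity


@dataclass
class SegmentSet:
    """Directed current elements of one discretized solenoid."""

    midpoints: np.ndarray  # (N, 3) m
    dl: np.ndarray  # (N, 3) m
    solenoid_id: str = "coil"

    @property
    def path_length(self) -> float:
        return float(np.linalg.norm(self.dl, axis=1).sum())

    def mirrored(self, z_plane: float) -> "SegmentSet":
        """Exact mirror image through the plane z = z_plane.

        Reflecting the current density preserves the dipole moment component
        normal to the plane, so a mirrored pair forms an aiding, exactly
        symmetric configuration.
        """
        mid = self.midpoints.copy()
        mid[:, 2] = 2.0 * z_plane - mid[:, 2]
        dl = self.dl.copy()
        dl[:, 2] = -dl[:, 2]
        return SegmentSet(midpoints=mid, dl=dl, solenoid_id=self.solenoid_id + "_mirror")


@dataclass
class FieldGrid:
    """Magnetic induction sampled on a set of points (tesla, SI positions)."""

    points: np.ndarray  # (M, 3) m
    B: np.ndarray  # (M, 3) T
    valid: np.ndarray  # (M,) bool; False inside a wire guard radius

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.B, axis=1)

    def to_frame(self) -> pd.DataFrame:
        mm = self.points * 1e3
        return pd.DataFrame(
            {
                "x_mm": mm[:, 0],
                "y_mm": mm[:, 1],
                "z_mm": mm[:, 2],
                "Bx_T": self.B[:, 0],
                "By_T": self.B[:, 1],
                "Bz_T": self.B[:, 2],
                "Bmag_uT": self.magnitude * 1e6,
                "valid": self.valid,
            }
        )


def solenoid_current(spec: SolenoidSpec, drive: DriveSignal) -> float:
    """RMS-consistent current amplitude from the series impedance model."""
    w = drive.omega
    reactance = spec.inductance * w
    if spec.capacitance is not None:
        reactance -= 1.0 / (spec.capacitance * w)
    z = float(np.hypot(spec.resistance, reactance))
    if z == 0.0:
        raise DosimetryError("zero impedance: current is unbounded")
    return drive.voltage_amplitude / z


def _axis_basis(axis) -> np.ndarray:
    """Right-handed orthonormal basis (u, v, w) with w along the coil axis."""
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(w[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w])


def discretize(spec: SolenoidSpec, segments_per_turn: int = 16) -> SegmentSet:
    """Helical midpoint-rule discretization into turns x segments_per_turn elements."""
    if segments_per_turn < 3:
        raise ValueError("need at least 3 segments per turn")
    n_seg = spec.turns * segments_per_turn
    dtheta = 2.0 * np.pi / segments_per_turn
    theta_mid = (np.arange(n_seg) + 0.5) * dtheta
    a = spec.radius
    pitch = spec.length / spec.turns
    sense = float(spec.polarity)
    # local frame: helix winds about +w, advancing from -length/2 to +length/2
    x = a * np.cos(sense * theta_mid)
    y = a * np.sin(sense * theta_mid)
    z = -spec.length / 2.0 + pitch * theta_mid / (2.0 * np.pi)
    dx = -a * sense * np.sin(sense * theta_mid) * dtheta
    dy = a * sense * np.cos(sense * theta_mid) * dtheta
    dz = np.full(n_seg, pitch / (2.0 * np.pi) * dtheta)
    basis = _axis_basis(spec.axis)  # rows u, v, w
    local_mid = np.column_stack([x, y, z])
    local_dl = np.column_stack([dx, dy, dz])
    mid = local_mid @ basis + np.asarray(spec.center)
    dl = local_dl @ basis
    return SegmentSet(midpoints=mid, dl=dl)


def biot_savart(
    segment_sets,
    current: float,
    points: np.ndarray,
    guard_radius: float = DEFAULT_GUARD_RADIUS,
    chunk_size: int | None = None,
) -> FieldGrid:
    """Superposed field of all segment sets at the given points.

    Points within ``guard_radius`` of any current element are flagged
    invalid (their field is reported as NaN): the filamentary approximation
    diverges inside the wire.
    """
    if isinstance(segment_sets, SegmentSet):
        segment_sets = [segment_sets]
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    mids = np.concatenate([s.midpoints for s in segment_sets], axis=0)
    dls = np.concatenate([s.dl for s in segment_sets], axis=0)
    B = np.zeros_like(pts)
    valid = np.ones(len(pts), dtype=bool)
    coef = MU0 * current / (4.0 * np.pi)
    if chunk_size is None:
        # keep point x segment temporaries around ~100 MB
        chunk_size = max(1, int(4e6 / max(len(mids), 1)))
    for start in range(0, len(pts), chunk_size):
        p = pts[start : start + chunk_size]
        r = p[:, None, :] - mids[None, :, :]  # (m, N, 3)
        dist = np.linalg.norm(r, axis=2)
        bad = dist.min(axis=1) < guard_radius
        dist = np.maximum(dist, 1e-300)
        cross = np.cross(np.broadcast_to(dls, r.shape), r)
        contrib = coef * (cross / dist[:, :, None] ** 3).sum(axis=1)
        contrib[bad] = np.nan
        B[start : start + chunk_size] = contrib
        valid[start : start + chunk_size] = ~bad
    return FieldGrid(points=pts, B=B, valid=valid)


def finite_solenoid_axis_field(
    spec: SolenoidSpec, z: np.ndarray, current: float
) -> np.ndarray:
    """Closed-form on-axis field of an ideal finite solenoid (z from the centre)."""
    z = np.asarray(z, dtype=float)
    n = spec.turns / spec.length
    a = spec.radius
    zp = z + spec.length / 2.0
    zm = z - spec.length / 2.0
    return (
        MU0 * n * current / 2.0 * (zp / np.hypot(zp, a) - zm / np.hypot(zm, a))
    )


def loop_center_field(radius: float, current: float) -> float:
    """Closed-form field magnitude at the centre of a single circular loop."""
    return MU0 * current / (2.0 * radius)


def build_head_coil_array(
    spec: SolenoidSpec = SolenoidSpec(),
    head_width: float = 0.14,
    coils_per_side: int = 2,
    coil_gap: float = 5.0e-4,
    segments_per_turn: int = 16,
) -> list[SegmentSet]:
    """Segment sets for the study geometry.

    ``coils_per_side`` coaxial solenoids are stacked along z on each side of
    the head; the innermost coil edge sits at z = 0 (resp. z = head_width).
    The far side is the exact mirror image, so the array fields are aiding
    and mirror-symmetric about the mid-plane z = head_width / 2.
    """
    sets: list[SegmentSet] = []
    for k in range(coils_per_side):
        center_z = -(spec.length / 2.0 + k * (spec.length + coil_gap))
        coil = replace(spec, center=(0.0, 0.0, center_z), axis=(0.0, 0.0, 1.0))
        seg = discretize(coil, segments_per_turn)
        seg.solenoid_id = f"left_{k}"
        sets.append(seg)
    mirrored = [s.mirrored(head_width / 2.0) for s in sets]
    for k, s in enumerate(mirrored):
        s.solenoid_id = f"right_{k}"
    return sets + mirrored


def make_grid(
    x_mm=(-30.0, 30.0, 10.0),
    y_mm=(-30.0, 30.0, 10.0),
    z_mm=(0.0, 140.0, 10.0),
) -> np.ndarray:
    """Regular lattice of evaluation points; each spec is (lo, hi, step) in mm."""
    axes = []
    for lo, hi, step in (x_mm, y_mm, z_mm):
        n = int(round((hi - lo) / step)) + 1
        axes.append(np.linspace(lo, hi, n) * 1e-3)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


def head_field_map(
    drive: DriveSignal = DriveSignal(),
    spec: SolenoidSpec = SolenoidSpec(),
    head_width: float = 0.14,
    coils_per_side: int = 2,
    segments_per_turn: int = 16,
    grid_points: np.ndarray | None = None,
) -> FieldGrid:
    """|B| over the head volume for the default (or a custom) lattice.

    All coils carry the same series current from the impedance model.
    """
    if grid_points is None:
        grid_points = make_grid()
    sets = build_head_coil_array(
        spec, head_width=head_width, coils_per_side=coils_per_side,
        segments_per_turn=segments_per_turn,
    )
    current = solenoid_current(spec, drive)
    return biot_savart(sets, current, grid_points)


def plane_slice(grid: FieldGrid, axis: str, value_mm: float, tol_mm: float = 1e-6) -> pd.DataFrame:
    """Extract the grid rows lying on a coordinate plane (axis in {x, y, z})."""
    idx = {"x": 0, "y": 1, "z": 2}[axis]
    frame = grid.to_frame()
    col = f"{axis}_mm"
    return frame[np.abs(frame[col] - value_mm) <= tol_mm].reset_index(drop=True)


def eddy_power_density(B: float, tissue: TissueParams, frequency: float) -> float:
    """Eddy-current Joule heating per unit mass of a conductive slab, W/kg."""
    if B < 0 or frequency <= 0:
        raise ValueError("field magnitude must be >= 0 and frequency > 0")
    return (
        np.pi**2
        * B**2
        * tissue.slab_thickness**2
        * frequency**2
        / (6.0 * tissue.resistivity * tissue.density)
    )
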