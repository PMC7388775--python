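"""Collagen fiber morphometrics on traced 3-D polylines.

Fibers traced from second-harmonic generation stacks are quantified by

* **direction** — the principal axis of the centred point cloud (largest
  eigenvector of the coordinate covariance), projected onto the imaging
  plane and folded to [0, 180) degrees relative to a reference axis (the
  crista terminalis / stretch direction, x by convention);
* **tortuosity** — traced path length divided by the endpoint chord (>= 1);
* **crimp wavelength** — peak-to-peak distance of the periodic lateral
  deviation from the fiber axis, measured after removing the long-range
  "bow" (a single half-period bend of the whole fiber) so that bowed but
  uncrimped fibers yield no spurious wavelengths.

Input starts at traced polylines (SWC or CSV); raw image processing is out
of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "FiberPath",
    "FiberMetrics",
    "OrientationHistogram",
    "fiber_direction",
    "orientation_histogram",
    "tortuosity",
    "crimp_wavelength",
    "measure_fiber",
    "read_swc",
    "write_swc",
    "read_fiber_csv",
    "write_fiber_csv",
]


@dataclass
class FiberPath:
    """Ordered 3-D polyline (µm) for one traced fiber."""

    points: np.ndarray
    label: str = "surface"  # surface | middle
    sample_id: str = ""
    fiber_id: int = 0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] == 2:  # allow planar traces
            pts = np.column_stack([pts, np.zeros(len(pts))])
        if pts.shape[0] < 3 or pts.shape[1] != 3:
            raise ValueError("fiber path needs >= 3 three-dimensional points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive points must be distinct")
        self.points = pts

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class FiberMetrics:
    direction_deg: float
    tortuosity: float
    crimp_wavelengths_um: list = field(default_factory=list)


@dataclass
class OrientationHistogram:
    """Per-sample orientation fractions on a common [0, 180) binning."""

    bin_edges_deg: np.ndarray
    sample_fractions: dict  # sample_id -> fractions array
    mean_fractions: np.ndarray
    alignment_fraction: float  # fraction within +/-20 deg of the reference axis


def fiber_direction(path: FiberPath, reference_deg: float = 0.0) -> float:
    """In-plane fiber direction in [0, 180) degrees from the reference axis.

    The principal axis is the largest-eigenvalue eigenvector of the centred
    coordinate covariance; its x-y projection defines the angle. The
    eigenvector sign ambiguity disappears under folding to the half circle.
    """
    pts = path.points - path.points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-18:
        raise ValueError("no dominant direction: degenerate point cloud")
    if np.isclose(evals[-1], evals[-2], rtol=1e-6) and evals[-2] > 1e-12:
        raise ValueError("no dominant direction: isotropic point cloud")
    axis = evecs[:, -1]
    vx, vy = axis[0], axis[1]
    if np.hypot(vx, vy) < 1e-12:
        raise ValueError("principal axis perpendicular to the imaging plane")
    ang = np.degrees(np.arctan2(vy, vx)) - reference_deg
    return float(np.mod(ang, 180.0))


def orientation_histogram(
    directions_by_sample: dict,
    bin_width_deg: float = 15.0,
    reference_deg: float = 0.0,
    alignment_halfwidth_deg: float = 20.0,
) -> OrientationHistogram:
    """Per-sample normalised orientation fractions and their unweighted mean.

    ``directions_by_sample`` maps sample id -> iterable of directions in
    degrees [0, 180). ``alignment_fraction`` is the pooled-mean fraction of
    fibers within +/- ``alignment_halfwidth_deg`` of the reference axis
    (folded, so 175 deg counts as 5 deg off axis).
    """
    if not directions_by_sample:
        raise ValueError("no samples supplied")
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    sample_fractions = {}
    aligned = []
    for sid, dirs in directions_by_sample.items():
        d = np.mod(np.asarray(list(dirs), dtype=float), 180.0)
        if d.size == 0:
            raise ValueError(f"sample {sid!r} has no directions")
        counts, _ = np.histogram(d, bins=edges)
        sample_fractions[sid] = counts / d.size
        off_axis = np.minimum(
            np.mod(d - reference_deg, 180.0), 180.0 - np.mod(d - reference_deg, 180.0)
        )
        aligned.append(np.mean(off_axis <= alignment_halfwidth_deg))
    mean_fractions = np.mean(np.stack(list(sample_fractions.values())), axis=0)
    return OrientationHistogram(
        bin_edges_deg=edges,
        sample_fractions=sample_fractions,
        mean_fractions=mean_fractions,
        alignment_fraction=float(np.mean(aligned)),
    )


def tortuosity(path: FiberPath) -> float:
    """Arc length along the trace divided by the endpoint chord length."""
    chord = path.chord_length
    if chord <= 0:
        raise ValueError("coincident endpoints: tortuosity undefined")
    return path.arc_length / chord


def _axis_frame(path: FiberPath) -> tuple[np.ndarray, np.ndarray]:
    """(s, lateral) coordinates: projection on the principal axis and signed
    in-plane deviation from it."""
    pts = path.points - path.points.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    # in-plane normal to the axis projection
    ax2 = np.array([axis[0], axis[1]])
    n = np.linalg.norm(ax2)
    if n < 1e-12:
        raise ValueError("fiber axis perpendicular to imaging plane")
    ax2 /= n
    normal = np.array([-ax2[1], ax2[0]])
    s = pts[:, :2] @ ax2
    lateral = pts[:, :2] @ normal
    order = np.argsort(s)
    return s[order], lateral[order]


def crimp_wavelength(
    path: FiberPath, min_prominence_frac: float = 0.2
) -> list[float]:
    """Peak-to-peak crimp wavelengths (µm) of the lateral deviation signal.

    The bow — one half-period bend spanning the whole fiber — is removed by
    least-squares fitting ``a + b*s + c*sin(pi*(s-s0)/L)`` before peak
    detection, so a bowed but uncrimped fiber returns an empty list. Peaks
    need prominence >= ``min_prominence_frac`` of the detrended deviation
    range; fewer than two peaks yields an empty list with a warning.
    """
    s, lateral = _axis_frame(path)
    span = s[-1] - s[0]
    if span <= 0:
        raise ValueError("degenerate axial extent")
    # half-period bow + affine trend, linear least squares
    basis = np.column_stack(
        [np.ones_like(s), s, np.sin(np.pi * (s - s[0]) / span)]
    )
    coef, *_ = np.linalg.lstsq(basis, lateral, rcond=None)
    resid = lateral - basis @ coef
    rng = resid.max() - resid.min()
    # floor guards against float residue of the bow fit masquerading as crimp
    if rng <= 1e-9 * max(path.chord_length, 1.0):
        warnings.warn("flat lateral deviation: no crimp detected", stacklevel=2)
        return []
    peaks, _ = find_peaks(resid, prominence=min_prominence_frac * rng)
    if len(peaks) < 2:
        warnings.warn("fewer than 2 crimp peaks detected", stacklevel=2)
        return []
    # straight-line distance between consecutive peaks, in the ordered frame
    return [float(np.hypot(s[b] - s[a], lateral[b] - lateral[a]))
            for a, b in zip(peaks[:-1], peaks[1:])]


def measure_fiber(path: FiberPath, reference_deg: float = 0.0) -> FiberMetrics:
    """Direction, tortuosity, and crimp wavelengths for one fiber."""
    return FiberMetrics(
        direction_deg=fiber_direction(path, reference_deg),
        tortuosity=tortuosity(path),
        crimp_wavelengths_um=crimp_wavelength(path),
    )


# ---------------------------------------------------------------------------
# SWC / CSV input-output. SWC: "id type x y z radius parent", one tree per
# fiber, '#' comments; soma-less paths accepted.

def read_swc(path) -> list[FiberPath]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            rows.append(
                (int(f[0]), float(f[2]), float(f[3]), float(f[4]), int(f[6]))
            )
    if not rows:
        raise ValueError(f"no SWC records in {path}")
    fibers: list[FiberPath] = []
    current: list[tuple[float, float, float]] = []
    for node_id, x, y, z, parent in rows:
        if parent == -1 and current:
            fibers.append(FiberPath(np.array(current), fiber_id=len(fibers)))
            current = []
        current.append((x, y, z))
    if current:
        fibers.append(FiberPath(np.array(current), fiber_id=len(fibers)))
    return fibers


def write_swc(fibers, path) -> None:
    with open(path, "w") as fh:
        fh.write("# SWC traced fibers, one tree per fiber\n")
        node_id = 0
        for fiber in fibers:
            parent = -1
            for x, y, z in fiber.points:
                node_id += 1
                fh.write(f"{node_id} 0 {x:.6g} {y:.6g} {z:.6g} 0.5 {parent}\n")
                parent = node_id


def read_fiber_csv(path) -> list[FiberPath]:
    """CSV with columns fiber_id, x, y, z."""
    df = pd.read_csv(path)
    return [
        FiberPath(g[["x", "y", "z"]].to_numpy(), fiber_id=int(fid))
        for fid, g in df.groupby("fiber_id", sort=True)
    ]


def write_fiber_csv(fibers, path) -> None:
    frames = []
    for fiber in fibers:
        df = pd.DataFrame(fiber.points, columns=["x", "y", "z"])
        df.insert(0, "fiber_id", fiber.fiber_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
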