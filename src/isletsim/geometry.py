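"""Labeled-volume IO and synthetic geometry / cohort generation.

The simulation consumes labelled voxel volumes with isotropic spacing:
label 0 = healthy organ interior, 1 = tumor (GTV), 2 = boundary
(everything outside the organ).  Two interchange formats are supported:

* NIfTI (``.nii`` / ``.nii.gz``) through nibabel, with the spacing and
  origin carried in the affine (axis-aligned, isotropic only);
* a portable raw format (``.lvol``): an ASCII header followed by the
  flat int8 label array, documented bit-exactly in :func:`write_volume`.

Because no clinical data ships with the package, synthetic geometries
emulate a prostate-like organ: an ellipsoidal organ containing one or
more spherical GTVs, with bladder-like and rectum-like structures
(ellipsoids or half-spaces) outside the organ.  A synthetic cohort
generator simulates each geometry once at known parameters to produce
(islet count, median diameter) observations for calibration tests.

Coordinate convention: 0-based voxel indices; the world position of a
voxel centre is ``origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import BOUNDARY, HEALTHY, TUMOR, Lattice, ModelParams

__all__ = [
    "LabeledVolume",
    "Ellipsoid",
    "Sphere",
    "HalfSpace",
    "SyntheticSpec",
    "PatientRecord",
    "CohortData",
    "read_volume",
    "write_volume",
    "make_geometry",
    "default_spec",
    "small_cohort_spec",
    "make_cohort",
    "save_cohort",
    "load_cohort",
]

_LEGEND = {0: "healthy", 1: "tumor", 2: "boundary"}
_MAGIC = "isletsim-labeled-volume 1"


@dataclass
class LabeledVolume:
    """Integer label grid with isotropic spacing and world origin (mm)."""

    labels: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        present = np.unique(self.labels)
        unknown = [int(v) for v in present if int(v) not in _LEGEND]
        if unknown:
            raise ValueError(f"labels outside legend {_LEGEND}: {unknown}")
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]

    def to_lattice(self, periodic=(False, False, False)) -> Lattice:
        return Lattice(self.labels.copy(), self.spacing, periodic)

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin[a] + (np.arange(self.labels.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def write_volume(volume: LabeledVolume, path: str | Path) -> None:
    """Write a labelled volume; format chosen by suffix.

    ``.lvol`` raw format, bit-exact specification: an ASCII header of
    exactly six LF-terminated lines ::

        isletsim-labeled-volume 1
        shape: <nx> <ny> <nz>
        spacing_mm: <float repr>
        origin_mm: <ox> <oy> <oz>
        legend: 0=healthy 1=tumor 2=boundary
        data: int8 C-order

    followed immediately by ``nx*ny*nz`` bytes: the int8 labels in
    C (row-major) order, last axis fastest.
    """
    path = Path(path)
    if path.suffix == ".lvol":
        nx, ny, nz = volume.labels.shape
        header = (
            f"{_MAGIC}\n"
            f"shape: {nx} {ny} {nz}\n"
            f"spacing_mm: {volume.spacing!r}\n"
            f"origin_mm: {volume.origin[0]!r} {volume.origin[1]!r} {volume.origin[2]!r}\n"
            f"legend: 0=healthy 1=tumor 2=boundary\n"
            f"data: int8 C-order\n"
        )
        with open(path, "wb") as fh:
            fh.write(header.encode("ascii"))
            fh.write(volume.labels.tobytes(order="C"))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([volume.spacing] * 3 + [1.0])
        affine[:3, 3] = np.asarray(volume.origin) + 0.5 * volume.spacing
        img = nib.Nifti1Image(volume.labels.astype(np.int8), affine)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unrecognized volume format: {path.name}")


def read_volume(path: str | Path) -> LabeledVolume:
    """Read a labelled volume written by :func:`write_volume`.

    Rejects non-isotropic spacing and unknown labels (the model requires
    an isotropic grid and the three-state legend).
    """
    path = Path(path)
    if path.suffix == ".lvol":
        with open(path, "rb") as fh:
            lines = [fh.readline().decode("ascii").rstrip("\n") for _ in range(6)]
            if lines[0] != _MAGIC:
                raise ValueError(f"not an .lvol file: bad magic {lines[0]!r}")
            shape = tuple(int(v) for v in lines[1].split(":", 1)[1].split())
            spacing = float(lines[2].split(":", 1)[1])
            origin = tuple(float(v) for v in lines[3].split(":", 1)[1].split())
            if lines[4].split(":", 1)[1].strip() != "0=healthy 1=tumor 2=boundary":
                raise ValueError("legend mismatch")
            raw = fh.read()
        n = shape[0] * shape[1] * shape[2]
        if len(raw) != n:
            raise ValueError(f"payload size {len(raw)} != {n} voxels")
        labels = np.frombuffer(raw, dtype=np.int8).reshape(shape).copy()
        return LabeledVolume(labels, spacing, origin)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        lin = affine[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
            raise ValueError("only axis-aligned volumes are supported")
        zooms = np.diag(lin)
        if not np.allclose(zooms, zooms[0], rtol=1e-6) or zooms[0] <= 0:
            raise ValueError(
                f"non-isotropic spacing {tuple(zooms)}; the model requires "
                "isotropic dx (resample externally)"
            )
        spacing = float(zooms[0])
        origin = tuple(float(v) for v in (affine[:3, 3] - 0.5 * spacing))
        labels = np.asarray(img.dataobj).astype(np.int8)
        return LabeledVolume(labels, spacing, origin)
    raise ValueError(f"unrecognized volume format: {path.name}")


# ---------------------------------------------------------------------------
# Synthetic geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        return (
            ((x - self.center[0]) / self.semi_axes[0]) ** 2
            + ((y - self.center[1]) / self.semi_axes[1]) ** 2
            + ((z - self.center[2]) / self.semi_axes[2]) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, x, y, z):
        return (
            (x - self.center[0]) ** 2
            + (y - self.center[1]) ** 2
            + (z - self.center[2]) ** 2
        ) <= self.radius**2


@dataclass(frozen=True)
class HalfSpace:
    """Points with normal . x >= offset (normal in mm coordinates)."""

    normal: tuple[float, float, float]
    offset: float

    def contains(self, x, y, z):
        return (
            self.normal[0] * x + self.normal[1] * y + self.normal[2] * z
        ) >= self.offset


@dataclass(frozen=True)
class SyntheticSpec:
    """Prostate-like synthetic geometry: organ + GTV(s) + organs at risk."""

    organ: Ellipsoid
    gtv: tuple[Sphere, ...]
    oars: dict[str, "Ellipsoid | HalfSpace | Sphere"] = field(default_factory=dict)
    spacing: float = 0.25
    margin_mm: float = 2.0


def default_spec(spacing: float = 0.25) -> SyntheticSpec:
    """Default prostate-like fixture.

    Organ semi-axes (25, 20, 22) mm; a 7 mm-radius GTV placed off-centre
    toward the rectum-like half-space below the organ, so that risk
    curves near the rectum rise sharply; a bladder-like ellipsoid sits
    above the organ.
    """
    return SyntheticSpec(
        organ=Ellipsoid(center=(0.0, 0.0, 0.0), semi_axes=(25.0, 20.0, 22.0)),
        gtv=(Sphere(center=(5.0, 0.0, -12.0), radius=7.0),),
        oars={
            "bladder": Ellipsoid(center=(0.0, 0.0, 42.0), semi_axes=(22.0, 22.0, 18.0)),
            "rectum": HalfSpace(normal=(0.0, 0.0, -1.0), offset=24.0),
        },
        spacing=spacing,
    )


def small_cohort_spec(spacing: float = 0.5) -> SyntheticSpec:
    """Reduced prostate-like geometry for fast cohort studies.

    A ~9 mm organ with a three-lobed GTV (overlapping spheres joined by
    narrow necks).  Under death-biased dynamics the necks erode first and
    the lobes pinch off as detached fragments -- the mechanism by which
    irregular gross tumors shed islets -- so cohorts built on this
    geometry show the clinically observed mixture of islet-free and
    islet-bearing cases at a small fraction of full prostate cost.
    """
    return SyntheticSpec(
        organ=Ellipsoid(center=(0.0, 0.0, 0.0), semi_axes=(9.0, 8.0, 8.5)),
        gtv=(
            Sphere(center=(-3.5, 0.0, -2.0), radius=2.3),
            Sphere(center=(-0.5, 1.0, -1.5), radius=2.1),
            Sphere(center=(2.5, -1.0, -2.5), radius=2.4),
        ),
        oars={},
        spacing=spacing,
        margin_mm=1.5,
    )


def make_geometry(spec: SyntheticSpec) -> tuple[LabeledVolume, dict[str, np.ndarray]]:
    """Voxelize a synthetic spec into a labelled volume plus structure masks.

    Voxel-centre inclusion test; deterministic for a given spec.  Returns
    (volume, masks) where masks holds boolean arrays "organ", "gtv" and
    one per organ at risk.  The domain covers the organ bounding box plus
    ``margin_mm`` (so a BOUNDARY shell always surrounds the organ); organ
    at risk structures are clipped to this domain.
    """
    dx = spec.spacing
    c = np.asarray(spec.organ.center)
    ax = np.asarray(spec.organ.semi_axes)
    lo = c - ax - spec.margin_mm
    hi = c + ax + spec.margin_mm
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / dx)) for a in range(3))
    origin = tuple(float(v) for v in lo)
    xs = lo[0] + (np.arange(shape[0]) + 0.5) * dx
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * dx
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * dx
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)

    organ = spec.organ.contains(x, y, z)
    gtv = np.zeros(shape, bool)
    for s in spec.gtv:
        gtv |= s.contains(x, y, z)
    if (gtv & ~organ).any():
        raise ValueError("GTV extends outside the organ")

    labels = np.full(shape, BOUNDARY, np.int8)
    labels[organ] = HEALTHY
    labels[gtv] = TUMOR

    masks: dict[str, np.ndarray] = {"organ": organ, "gtv": gtv}
    for name, shape_spec in spec.oars.items():
        m = shape_spec.contains(x, y, z)
        if (m & organ).any():
            raise ValueError(f"organ at risk {name!r} overlaps the organ interior")
        masks[name] = m
    return LabeledVolume(labels, dx, origin), masks


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """One patient: initial-condition volume plus observed islet summary."""

    patient_id: str
    volume: LabeledVolume
    observed_count: int
    observed_median_mm: float | None  # None when observed_count == 0


@dataclass
class CohortData:
    patients: list[PatientRecord]

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("cohort requires at least one patient")

    def __len__(self) -> int:
        return len(self.patients)

    def observations(self) -> tuple[np.ndarray, np.ndarray]:
        """(counts over all patients, medians over islet-bearing patients)."""
        counts = np.array([p.observed_count for p in self.patients], float)
        medians = np.array(
            [p.observed_median_mm for p in self.patients if p.observed_median_mm is not None],
            float,
        )
        return counts, medians


def make_cohort(
    n_patients: int,
    theta_star: ModelParams,
    seed: int,
    base_spec: SyntheticSpec | None = None,
    size_jitter: float = 0.15,
    tend: float | None = None,
) -> CohortData:
    """Generate a synthetic cohort with observations simulated at theta_star.

    Each patient gets an ellipsoidal organ and spherical GTV whose sizes
    are jittered by a uniform factor in ``1 +/- size_jitter``; one
    simulation per patient at ``theta_star`` (horizon ``tend`` or
    ``theta_star.tend``) provides the "observed" filtered islet count and
    median equivalent diameter.  Fully deterministic for a given seed.
    """
    from .calibration import simulate_patient

    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if base_spec is None:
        base_spec = default_spec(spacing=theta_star.dx)
    rng = np.random.default_rng(seed)
    patients = []
    for k in range(n_patients):
        f_org = 1.0 + size_jitter * rng.uniform(-1, 1, size=3)
        f_gtv = 1.0 + size_jitter * rng.uniform(-1, 1)
        organ = Ellipsoid(
            center=base_spec.organ.center,
            semi_axes=tuple(a * f for a, f in zip(base_spec.organ.semi_axes, f_org)),
        )
        gtv = tuple(
            Sphere(center=s.center, radius=s.radius * f_gtv) for s in base_spec.gtv
        )
        spec = SyntheticSpec(
            organ=organ, gtv=gtv, oars={}, spacing=base_spec.spacing,
            margin_mm=base_spec.margin_mm,
        )
        volume, _ = make_geometry(spec)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        count, median = simulate_patient(volume, theta_star, sim_seed, tend=tend)
        patients.append(
            PatientRecord(
                patient_id=f"patient{k:03d}",
                volume=volume,
                observed_count=count,
                observed_median_mm=median,
            )
        )
    return CohortData(patients)


def save_cohort(cohort: CohortData, directory: str | Path) -> None:
    """One subdirectory per patient (volume.lvol) + observations.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        sub = directory / p.patient_id
        sub.mkdir(exist_ok=True)
        write_volume(p.volume, sub / "volume.lvol")
        rows.append(
            {
                "patient_id": p.patient_id,
                "islet_count": p.observed_count,
                "median_diameter_mm": (
                    "" if p.observed_median_mm is None else p.observed_median_mm
                ),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "observations.tsv", sep="\t", index=False)


def load_cohort(directory: str | Path) -> CohortData:
    directory = Path(directory)
    table = pd.read_csv(directory / "observations.tsv", sep="\t")
    patients = []
    for _, row in table.iterrows():
        pid = str(row["patient_id"])
        volume = read_volume(directory / pid / "volume.lvol")
        med = row["median_diameter_mm"]
        med = None if (pd.isna(med) or med == "") else float(med)
        patients.append(
            PatientRecord(
                patient_id=pid,
                volume=volume,
                observed_count=int(row["islet_count"]),
                observed_median_mm=med,
            )
        )
    return CohortData(patients)
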