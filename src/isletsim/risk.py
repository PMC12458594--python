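"""Monte-Carlo tumor-probability maps near organs at risk.

For an organ at risk (bladder- or rectum-like structure) the region of
interest Omega(d) is the organ-interior voxel set within Euclidean
distance d (mm, voxel-centre metric) of the structure.  N independent
simulations are run from the GTV initial condition; a sample trips the
indicator for distance d when the tumor volume inside Omega(d) at the
final state reaches the volume of a 1 mm-diameter sphere (a plain voxel
count -- connectivity is not required).  The tumor probability is the
Monte-Carlo estimate

    P_N(d) = (1/N) * sum_k I(s_k, d),     SE = sqrt(P (1 - P) / N).

P_N(d) is nondecreasing in d on a shared sample set, and equals 1 for
every N as soon as Omega(d) reaches the GTV itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .engine import build, run_until
from .geometry import LabeledVolume
from .islets import ball_volume
from .lattice import BOUNDARY, TUMOR, ModelParams

__all__ = [
    "RiskRegion",
    "RiskCurve",
    "region_within",
    "indicator",
    "estimate_curve",
    "find_safe_distance",
]

#: Tumor volume (mm^3) a region must contain to count as involved.
INVOLVEMENT_VOLUME_MM3: float = ball_volume(1.0)


@dataclass
class RiskRegion:
    """Distance field to one organ at risk over an organ-interior grid."""

    oar_mask: np.ndarray  # boolean, True on the organ-at-risk structure
    interior_mask: np.ndarray  # True inside the organ of interest
    distance_mm: np.ndarray  # per-voxel Euclidean distance to the structure
    spacing: float

    @classmethod
    def from_masks(
        cls, oar_mask: np.ndarray, interior_mask: np.ndarray, spacing: float
    ) -> "RiskRegion":
        oar_mask = np.asarray(oar_mask, bool)
        if not oar_mask.any():
            raise ValueError("organ-at-risk mask is empty")
        dist = ndimage.distance_transform_edt(~oar_mask, sampling=spacing)
        return cls(oar_mask, np.asarray(interior_mask, bool), dist, float(spacing))

    def omega(self, d: float) -> np.ndarray:
        """Boolean mask of interior voxels within distance d (inclusive)."""
        return self.interior_mask & ~self.oar_mask & (self.distance_mm <= d)


def region_within(
    oar_mask: np.ndarray, volume: LabeledVolume, d: float
) -> np.ndarray:
    """Omega(d): organ-interior voxels within d mm of the organ at risk.

    Distances are voxel-centre Euclidean distances from a distance
    transform scaled by the spacing; BOUNDARY voxels are excluded, tumor
    voxels are included (the region is geometric, not state-dependent).
    """
    region = RiskRegion.from_masks(oar_mask, volume.labels != BOUNDARY, volume.spacing)
    return region.omega(d)


def indicator(states: np.ndarray, omega_mask: np.ndarray, spacing: float) -> int:
    """1 iff the tumor volume within the region reaches a 1 mm ball."""
    count = int(np.count_nonzero((np.asarray(states) == TUMOR) & omega_mask))
    return int(count * spacing**3 >= INVOLVEMENT_VOLUME_MM3)


@dataclass
class RiskCurve:
    """P_N(d) estimates with standard errors for one organ at risk."""

    distances: np.ndarray
    estimates: np.ndarray
    stderr: np.ndarray
    n_samples: int
    indicators: np.ndarray | None = None  # (N, n_distances) per-sample matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_mm": self.distances,
                "p_tumor": self.estimates,
                "stderr": self.stderr,
                "n_samples": self.n_samples,
            }
        )


def estimate_curve(
    volume: LabeledVolume,
    oar_mask: np.ndarray,
    params: ModelParams,
    distances,
    n_samples: int,
    seed: int,
    tend: float | None = None,
    keep_indicators: bool = True,
    frequency_volume: bool = False,
) -> RiskCurve | tuple[RiskCurve, np.ndarray]:
    """Monte-Carlo risk curve P_N(d) for one organ at risk.

    Runs ``n_samples`` independent simulations (seeds ``seed + k``) from
    the volume's GTV initial condition and evaluates every distance on
    the same samples.  With ``frequency_volume=True`` also returns the
    per-voxel fraction of samples whose final state is tumor.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    distances = np.asarray(sorted(float(d) for d in np.atleast_1d(distances)))
    region = RiskRegion.from_masks(oar_mask, volume.labels != BOUNDARY, volume.spacing)
    in_region = region.interior_mask & ~region.oar_mask
    dist = region.distance_mm
    # voxel count needed within Omega(d) to reach the 1 mm-ball volume
    min_count = int(np.ceil(INVOLVEMENT_VOLUME_MM3 / volume.spacing**3 - 1e-12))

    params = params.with_(dx=volume.spacing)
    horizon = tend if tend is not None else params.tend
    ind = np.zeros((n_samples, distances.size), np.int8)
    freq = np.zeros(volume.labels.shape, np.float64) if frequency_volume else None
    for k in range(n_samples):
        state = build(volume.to_lattice(), params, seed + k)
        run_until(state, horizon)
        tumor = state.lattice.states == TUMOR
        if freq is not None:
            freq += tumor
        dvals = np.sort(dist[tumor & in_region])
        # tumor voxels within distance d: searchsorted on the sorted values
        counts = np.searchsorted(dvals, distances, side="right")
        ind[k] = counts >= min_count
    p = ind.mean(axis=0)
    curve = RiskCurve(
        distances=distances,
        estimates=p,
        stderr=np.sqrt(p * (1.0 - p) / n_samples),
        n_samples=n_samples,
        indicators=ind if keep_indicators else None,
    )
    if frequency_volume:
        return curve, freq / n_samples
    return curve


def find_safe_distance(curve: RiskCurve, risk_threshold: float) -> float | None:
    """Largest evaluated d with P_N(d) <= threshold; None if none."""
    ok = curve.estimates <= risk_threshold
    if not ok.any():
        return None
    return float(curve.distances[np.nonzero(ok)[0].max()])
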