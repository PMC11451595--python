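"""Axial density profiles and membrane-plane position statistics.

The axial K+ density profile is computed inside a cylinder co-axial with
the pore (default diameter 12 Å) and normalized to the bulk concentration,
so 1.0 means bulk density; peaks mark the K+ binding sites.  The 2D
histogram projects selected atoms onto the plane perpendicular to the
pore axis (origin on the axis), which is how on-axis blockers are told
apart from wall binders; the radial quantile function operationalizes
statements like "rarely deviates more than 2 Å from the axis".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import InputError
from .frames import FrameSet
from .pore_model import PoreModel


def bulk_number_density(bulk_mM: float) -> float:
    """Ions per Å^3 at the given bulk concentration (mM)."""
    # mol/L -> ions/A^3 : * N_A / 1e27
    return bulk_mM * 1e-3 * constants.N_A / 1e27


@dataclass
class AxialDensityProfile:
    bin_centers: np.ndarray  # Å along the axis
    density: np.ndarray  # dimensionless, 1 = bulk
    bin_width: float
    cylinder_diameter: float
    bulk_mM: float


def axial_density(
    frames: FrameSet,
    model: PoreModel,
    bin_width: float = 0.5,
    diameter: float = 12.0,
    bulk_mM: float = 300.0,
    z_range: tuple[float, float] | None = None,
    kind: str = "ion",
) -> AxialDensityProfile:
    """Relative axial density of the selected atoms within the cylinder.

    Every selected atom contributes, but only while it resides inside the
    cylindrical volume; counts are divided by frames × bin volume × bulk
    number density.
    """
    if bulk_mM <= 0:
        raise InputError("bulk concentration must be positive")
    if frames.n_frames == 0:
        raise InputError("no frames")
    idx = frames.indices(kind=kind)
    if len(idx) == 0:
        raise InputError(f"no atoms of kind {kind!r}")
    pos = frames.coords(idx).reshape(-1, 3)
    z, r = model.axial_and_radial(pos)
    inside = r <= 0.5 * diameter
    z = z[inside]
    if z_range is None:
        z_range = (model.z_floor - 10.0, model.s0_ceiling + 10.0)
    lo, hi = z_range
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    hi = lo + n_bins * bin_width
    counts, edges = np.histogram(z, bins=n_bins, range=(lo, hi))
    bin_volume = np.pi * (0.5 * diameter) ** 2 * bin_width
    norm = frames.n_frames * bin_volume * bulk_number_density(bulk_mM)
    return AxialDensityProfile(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=counts / norm,
        bin_width=bin_width,
        cylinder_diameter=diameter,
        bulk_mM=bulk_mM,
    )


@dataclass
class XYHistogram:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # shape (nx, ny); integrates to frames × atoms

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def modal_bin_center(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            float(0.5 * (self.x_edges[i] + self.x_edges[i + 1])),
            float(0.5 * (self.y_edges[j] + self.y_edges[j + 1])),
        )


def xy_histogram(
    frames: FrameSet,
    model: PoreModel,
    bin_width: float = 0.5,
    extent: float = 12.0,
    **selection,
) -> XYHistogram:
    """2D histogram of atom positions projected on the membrane plane.

    ``selection`` keywords (kind=, name=, role=) pick the atoms; the
    origin lies on the pore axis.  Atoms outside ±``extent`` are clipped
    into the edge bins so mass is conserved.
    """
    idx = frames.indices(**selection)
    if len(idx) == 0:
        raise InputError(f"empty atom selection {selection!r}")
    pos = frames.coords(idx).reshape(-1, 3)
    xy = model.membrane_plane_coords(pos)
    xy = np.clip(xy, -extent + 1e-9, extent - 1e-9)
    n = max(int(round(2 * extent / bin_width)), 1)
    counts, xe, ye = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=n, range=[[-extent, extent], [-extent, extent]]
    )
    return XYHistogram(x_edges=xe, y_edges=ye, counts=counts)


def radial_percentile(
    frames: FrameSet, model: PoreModel, q: float, **selection
) -> float:
    """Empirical q-quantile (0 < q < 1) of the perpendicular distance to
    the pore axis for the selected atoms."""
    if not 0.0 < q < 1.0:
        raise InputError("quantile must lie strictly between 0 and 1")
    idx = frames.indices(**selection)
    if len(idx) == 0:
        raise InputError(f"empty atom selection {selection!r}")
    pos = frames.coords(idx).reshape(-1, 3)
    _, r = model.axial_and_radial(pos)
    return float(np.quantile(r, q))
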