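"""Volumetric map I/O (OpenDX scalar dialect) and map post-processing.

The OpenDX dialect written here is the plain orthogonal-grid scalar format
produced by common MD potential-map tools: a ``gridpositions`` object with
counts/origin/deltas, a ``gridconnections`` object, and a rank-0 data array
in C (row-major, z fastest) order.  Round-trips are lossless to printing
precision.

Post-processing mirrors the analysis geometry used for helical molecules:
z-averaged cylindrical (or wedge) radial profiles, and averaging of z-slabs
in the frame of the repeating unit by rotating each slab through the
accumulated twist before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumetricMap",
    "read_dx",
    "write_dx",
    "cylindrical_average",
    "helical_frame_average",
]


@dataclass
class VolumetricMap:
    """Scalar field on a regular orthogonal grid.

    ``values`` has shape ``counts`` (nx, ny, nz); voxel (i,j,k) sits at
    origin + (i·dx, j·dy, k·dz).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be length-3")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing[i] * np.arange(self.counts[i])

    @property
    def extent(self) -> np.ndarray:
        return self.spacing * (np.asarray(self.counts) - 1)


def write_dx(vmap: VolumetricMap, path) -> None:
    """Write the map as an OpenDX scalar file (text, 3 values per line)."""
    nx, ny, nz = vmap.counts
    with open(path, "w") as fh:
        fh.write(f"# {vmap.units or 'scalar field'}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.10g} {:.10g} {:.10g}\n".format(*vmap.origin))
        fh.write(f"delta {vmap.spacing[0]:.10g} 0 0\n")
        fh.write(f"delta 0 {vmap.spacing[1]:.10g} 0\n")
        fh.write(f"delta 0 0 {vmap.spacing[2]:.10g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx*ny*nz} "
            "data follows\n"
        )
        flat = vmap.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.17g}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')


class DXParseError(ValueError):
    def __init__(self, msg, line_no=None):
        super().__init__(msg if line_no is None else f"line {line_no}: {msg}")
        self.line_no = line_no


def read_dx(path) -> VolumetricMap:
    """Read an OpenDX scalar file; rejects non-orthogonal grids."""
    counts = None
    origin = None
    deltas = []
    values = []
    n_items = None
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if line.startswith("object") and "gridpositions" in line:
                try:
                    counts = tuple(int(t) for t in tok[-3:])
                except ValueError:
                    raise DXParseError("malformed gridpositions counts", line_no)
            elif line.startswith("origin"):
                if len(tok) != 4:
                    raise DXParseError("malformed origin", line_no)
                origin = np.array([float(t) for t in tok[1:]])
            elif line.startswith("delta"):
                if len(tok) != 4:
                    raise DXParseError("malformed delta", line_no)
                deltas.append(np.array([float(t) for t in tok[1:]]))
            elif "class array" in line and "data follows" in line:
                try:
                    n_items = int(tok[tok.index("items") + 1])
                except (ValueError, IndexError):
                    raise DXParseError("malformed array header", line_no)
            elif line.startswith(("attribute", "object", "component")):
                continue
            elif n_items is not None:
                try:
                    values.extend(float(t) for t in tok)
                except ValueError:
                    raise DXParseError(f"bad data token {tok!r}", line_no)
    if counts is None or origin is None or len(deltas) != 3 or n_items is None:
        raise DXParseError("incomplete OpenDX header")
    D = np.vstack(deltas)
    if not np.allclose(D, np.diag(np.diag(D))):
        raise DXParseError("non-orthogonal grid basis is not supported")
    spacing = np.diag(D).copy()
    if len(values) != n_items or n_items != int(np.prod(counts)):
        raise DXParseError(
            f"expected {n_items} values, found {len(values)}"
        )
    vals = np.asarray(values, dtype=float).reshape(counts, order="C")
    return VolumetricMap(origin=origin, spacing=spacing, values=vals)


def cylindrical_average(vmap: VolumetricMap, axis_xy: tuple[float, float] | None = None,
                        r_bin: float = 0.5, wedge_center_deg: float | None = None,
                        wedge_width_deg: float = 360.0):
    """z-averaged radial profile about an axis parallel to z.

    ``axis_xy`` defaults to the map center.  A wedge (center, width in
    degrees) restricts the azimuthal range; width 360° is the full average.
    Voxel-count weighting; returns a DataFrame with bin edges, centers,
    mean value and voxel counts.
    """
    import pandas as pd

    nx, ny, nz = vmap.counts
    x = vmap.axis(0)
    y = vmap.axis(1)
    if axis_xy is None:
        axis_xy = (0.5 * (x[0] + x[-1]), 0.5 * (y[0] + y[-1]))
    if not (x[0] <= axis_xy[0] <= x[-1] and y[0] <= axis_xy[1] <= y[-1]):
        raise ValueError("helix axis lies outside the map")
    X, Y = np.meshgrid(x - axis_xy[0], y - axis_xy[1], indexing="ij")
    Rxy = np.hypot(X, Y)
    zmean = vmap.values.mean(axis=2)
    sel = np.ones_like(Rxy, dtype=bool)
    if wedge_width_deg < 360.0 and wedge_center_deg is not None:
        ang = np.degrees(np.arctan2(Y, X))
        d = (ang - wedge_center_deg + 180.0) % 360.0 - 180.0
        sel = np.abs(d) <= wedge_width_deg / 2.0
    rmax = Rxy[sel].max()
    edges = np.arange(0.0, rmax + r_bin, r_bin)
    idx = np.digitize(Rxy[sel], edges) - 1
    vals = zmean[sel]
    n_bins = len(edges) - 1
    counts = np.bincount(idx, minlength=n_bins)[:n_bins]
    sums = np.bincount(idx, weights=vals, minlength=n_bins)[:n_bins]
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "R_lo": edges[:-1], "R_hi": edges[1:],
        "R": 0.5 * (edges[:-1] + edges[1:]),
        "value": mean, "n_voxels": counts,
    })


def helical_frame_average(vmap: VolumetricMap, twist_per_rise_deg: float,
                          rise: float, spline_order: int = 3) -> np.ndarray:
    """Average z-slabs in the co-rotating helical frame.

    Each slab of thickness ``rise`` is rotated about the map center by the
    accumulated twist (spline interpolation of the given order when the grid
    spacing is incommensurate with the rise) and the rotated slabs are
    averaged.  Twist 0 reduces to the plain z-average.  Returns the averaged
    2-D (x, y) slab.
    """
    from scipy import ndimage

    nz = vmap.counts[2]
    dz = vmap.spacing[2]
    slab_len = max(1, int(round(rise / dz)))
    n_slabs = nz // slab_len
    if n_slabs < 2:
        raise ValueError("map too short for helical-frame averaging (<2 slabs)")
    acc = np.zeros(vmap.counts[:2])
    for s in range(n_slabs):
        slab = vmap.values[:, :, s * slab_len:(s + 1) * slab_len].mean(axis=2)
        # undo the accumulated right-handed twist; ndimage rotates from
        # axis 0 toward axis 1, opposite to the atan2(y, x) azimuth here
        angle = -s * twist_per_rise_deg
        if angle % 360.0:
            slab = ndimage.rotate(slab, angle, reshape=False,
                                  order=spline_order, mode="nearest")
        acc += slab
    return acc / n_slabs
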