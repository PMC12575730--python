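"""Density maps: MRC/CCP4 I/O, map simulation from models, blurring, sampling.

Grid convention: ``origin`` is the Cartesian position (Å) of the *center* of
voxel index (0, 0, 0); the grid array is indexed ``[ix, iy, iz]`` so that the
position of voxel (i, j, k) is ``origin + (i, j, k) * voxel_size``. Maps are
held as float64 internally and written as float32 (MRC mode 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

from .structures import ParseError, StructureModel

__all__ = [
    "DensityMap",
    "SpreadConfig",
    "read_map",
    "write_map",
    "simulate_map",
    "gaussian_blur",
    "value_and_gradient",
    "sigma_from_resolution",
]


@dataclass
class DensityMap:
    grid: np.ndarray                    # (nx, ny, nz) float64
    voxel_size: np.ndarray              # (3,) Å/voxel
    origin: np.ndarray                  # (3,) Å, center of voxel (0,0,0)
    resolution_hint: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3D with at least 2 voxels per axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(),
                          self.origin.copy(), self.resolution_hint)


@dataclass
class SpreadConfig:
    """Gaussian spreading of atoms onto a grid (simulated density)."""

    sigma: float = 1.5                  # Å per-atom Gaussian width (std dev)
    amplitude_mode: str = "uniform"     # or "atomic_number"
    cutoff_sigmas: float = 4.0          # truncation radius in units of sigma

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cutoff_sigmas < 3.0:
            raise ValueError("cutoff must be at least 3 sigma")
        if self.amplitude_mode not in ("uniform", "atomic_number"):
            raise ValueError(f"unknown amplitude_mode: {self.amplitude_mode}")

    @property
    def cutoff(self) -> float:
        return self.cutoff_sigmas * self.sigma


def sigma_from_resolution(resolution: float) -> float:
    """Spreading width for a nominal resolution (FWHM ≈ resolution)."""
    return 0.425 * resolution


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (via gemmi)


def read_map(path: str) -> DensityMap:
    """Read an MRC/CCP4 map; axis order is normalized to (x, y, z).

    The origin comes from the MRC ORIGIN record when set, otherwise from
    NSTART × voxel size.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot read map {path!s}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError(f"non-orthogonal map cell unsupported: {cell}")
    # nstart in the *file* axis order, before normalization
    nstart_file = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
    axis_order = [m.header_i32(i) for i in (17, 18, 19)]  # MAPC, MAPR, MAPS
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    grid = np.array(m.grid, copy=True).astype(np.float64)
    if not np.all(np.isfinite(grid)):
        raise ParseError(f"{path!s}: map contains non-finite values")
    nx, ny, nz = grid.shape
    voxel = np.array([cell.a / nx, cell.b / ny, cell.c / nz])
    origin_rec = np.array([m.header_float(i) for i in (50, 51, 52)])
    if np.any(origin_rec != 0):
        origin = origin_rec
    else:
        nstart = np.empty(3)
        for file_axis, xyz_axis in enumerate(axis_order):
            nstart[xyz_axis - 1] = nstart_file[file_axis]
        origin = nstart * voxel
    return DensityMap(grid, voxel, origin)


def write_map(dmap: DensityMap, path: str) -> None:
    """Write as MRC mode 2 (float32); round-trips exactly at float32."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# simulation and filtering

_ATOMIC_NUMBER = {"C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "H": 1, "D": 1,
                  "SE": 34, "FE": 26, "ZN": 30, "MG": 12}


def simulate_map(
    model: StructureModel,
    voxel_size: float | np.ndarray = 1.0,
    spread: SpreadConfig | None = None,
    pad: float = 8.0,
    grid_like: DensityMap | None = None,
) -> DensityMap:
    """Simulate a density map by spreading heavy atoms as truncated Gaussians.

    Each heavy atom contributes ``A·exp(−|r−x|²/(2σ²))`` up to the truncation
    radius. With ``grid_like`` the map is computed on that map's exact grid
    (needed for voxel-by-voxel cross-correlation); otherwise the grid spans
    the model bounding box plus ``pad`` Å on every side.
    """
    spread = spread or SpreadConfig()
    heavy = model.heavy_mask & ~model.hetero_flags
    if not heavy.any():
        heavy = model.heavy_mask
    coords = model.positions[heavy]
    if coords.shape[0] < 1:
        raise ValueError("model has no heavy atoms")

    if grid_like is not None:
        voxel = grid_like.voxel_size.copy()
        origin = grid_like.origin.copy()
        shape = grid_like.shape
    else:
        voxel = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size, float)), (3,)).copy()
        if pad < spread.cutoff:
            warnings.warn(
                f"pad {pad} Å < truncation radius {spread.cutoff:.1f} Å: "
                "density will be clipped at the grid edge",
                stacklevel=2,
            )
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel[a])) + 1 for a in range(3))
        origin = lo

    grid = np.zeros(shape, dtype=np.float64)
    # unit-mass Gaussians (peak (2πσ²)^{-3/2}): blurring a σ₁ map by σ₂ then
    # equals simulating at √(σ₁²+σ₂²), and total simulated mass is atom count
    norm = (2.0 * np.pi * spread.sigma ** 2) ** -1.5
    if spread.amplitude_mode == "uniform":
        amps = np.full(coords.shape[0], norm)
    else:
        elems = model.elements[heavy]
        amps = norm * np.array([_ATOMIC_NUMBER.get(e.upper(), 6) for e in elems], float)

    cut = spread.cutoff
    inv2s2 = 1.0 / (2.0 * spread.sigma ** 2)
    cut2 = cut * cut
    nvox = np.array(shape)
    for amp, x in zip(amps, coords):
        # local voxel window around the atom
        lo_i = np.maximum(np.ceil((x - cut - origin) / voxel).astype(int), 0)
        hi_i = np.minimum(np.floor((x + cut - origin) / voxel).astype(int), nvox - 1)
        if np.any(lo_i > hi_i):
            continue
        axes = [origin[a] + voxel[a] * np.arange(lo_i[a], hi_i[a] + 1) - x[a]
                for a in range(3)]
        d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
              + axes[2][None, None, :] ** 2)
        contrib = np.where(d2 <= cut2, amp * np.exp(-d2 * inv2s2), 0.0)
        grid[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1] += contrib
    return DensityMap(grid, voxel, origin)


def gaussian_blur(dmap: DensityMap, sigma: float) -> DensityMap:
    """Convolve with an isotropic Gaussian of standard deviation ``sigma`` (Å).

    Reduces effective resolution before fitting; the width is interpreted as
    a standard deviation and converted to voxels per axis. Same grid/origin.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return dmap.copy()
    sig_vox = sigma / dmap.voxel_size
    blurred = ndimage.gaussian_filter(dmap.grid, sigma=sig_vox, mode="constant")
    return DensityMap(blurred, dmap.voxel_size.copy(), dmap.origin.copy(),
                      dmap.resolution_hint)


# ---------------------------------------------------------------------------
# sampling


class MapBoundaryError(ValueError):
    """A sample point lies outside the interpolable interior of the grid."""


def value_and_gradient(
    dmap: DensityMap, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear value and its analytic gradient (per Å) at Cartesian points.

    ``points`` may be a single 3-vector or an (n, 3) array. Points must lie
    within the grid (callers pad the map if atoms can drift outside).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    frac = (pts - dmap.origin) / dmap.voxel_size
    nvox = np.array(dmap.shape)
    if np.any(frac < 0) or np.any(frac > nvox - 1):
        raise MapBoundaryError("sample point outside grid; pad the map first")

    def evaluate(i0: np.ndarray):
        t = frac - i0
        g = dmap.grid
        ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
        c = np.empty((pts.shape[0], 2, 2, 2))
        for a in (0, 1):
            for b in (0, 1):
                for d in (0, 1):
                    c[:, a, b, d] = g[ix + a, iy + b, iz + d]
        tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
        wx = np.stack([1 - tx, tx], axis=1)
        wy = np.stack([1 - ty, ty], axis=1)
        wz = np.stack([1 - tz, tz], axis=1)
        dw = np.stack([-np.ones(len(pts)), np.ones(len(pts))], axis=1)
        value = np.einsum("na,nb,nd,nabd->n", wx, wy, wz, c)
        gx = np.einsum("na,nb,nd,nabd->n", dw, wy, wz, c) / dmap.voxel_size[0]
        gy = np.einsum("na,nb,nd,nabd->n", wx, dw, wz, c) / dmap.voxel_size[1]
        gz = np.einsum("na,nb,nd,nabd->n", wx, wy, dw, c) / dmap.voxel_size[2]
        return value, np.stack([gx, gy, gz], axis=1)

    i_lo = np.minimum(np.floor(frac).astype(int), nvox - 2)
    value, grad = evaluate(i_lo)
    # points exactly on a cell face have a one-sided trilinear derivative;
    # average with the neighbouring cell so the gradient is symmetric there
    on_face = (frac == i_lo) & (i_lo > 0)
    if on_face.any():
        _, grad_alt = evaluate(np.where(on_face, i_lo - 1, i_lo))
        grad = 0.5 * (grad + grad_alt)

    if np.asarray(points).ndim == 1:
        return float(value[0]), grad[0]
    return value, grad


def pad_map(dmap: DensityMap, pad: float) -> DensityMap:
    """Zero-pad a map by ``pad`` Å on every side (origin shifts accordingly)."""
    npad = np.ceil(pad / dmap.voxel_size).astype(int)
    grid = np.pad(dmap.grid, [(p, p) for p in npad], mode="constant")
    origin = dmap.origin - npad * dmap.voxel_size
    return DensityMap(grid, dmap.voxel_size.copy(), origin, dmap.resolution_hint)
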