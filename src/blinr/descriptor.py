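"""Voxel descriptors: coordinates, prior patches and their concatenation.

Each voxel is represented to the network by a descriptor f(p): its positional
encoding followed by a flattened patch (default 3×3×3) taken at the same voxel
from every prior volume — the other-b-value diffusion images first, in
ascending b-value, then the anatomical contrasts in their declared order.
Anatomical volumes acquired on a different grid are first resampled to the
target grid by trilinear interpolation (axis-aligned scaling from shapes and
spacings; full affine handling is out of scope).

Conventions fixed here for reproducibility:

* voxel indices are 0-based; index 0 maps to normalized coordinate −1 and
  index n−1 to +1 (voxel-centre semantics); a singleton axis maps to 0;
* patches are flattened x-fastest;
* out-of-volume patch positions are filled by edge replication, so a denoiser
  never sees artificial zeros at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .encoding import EncodingConfig, encode, encoding_length
from .volume import GridSpec, Volume3D

__all__ = [
    "PriorStack",
    "normalize_coordinates",
    "grid_coordinates",
    "extract_patch",
    "extract_all_patches",
    "resample_to_grid",
    "assemble_descriptor",
    "descriptor_length",
    "build_descriptor_matrix",
]


@dataclass
class PriorStack:
    """The prior volumes available for one denoising target.

    ``dwi`` holds (b-value, volume) pairs excluding the target b-value;
    ``anatomical`` holds (label, volume) pairs.  All volumes must live on the
    target grid — resample first if necessary.
    """

    dwi: list[tuple[float, Volume3D]] = field(default_factory=list)
    anatomical: list[tuple[str, Volume3D]] = field(default_factory=list)
    target_b: float | None = None

    def __post_init__(self):
        if self.target_b is not None:
            for b, _ in self.dwi:
                if float(b) == float(self.target_b):
                    raise ValueError(
                        f"prior stack must not contain the target b-value ({self.target_b})"
                    )
        grids = [v.grid for _, v in self.dwi] + [v.grid for _, v in self.anatomical]
        for g in grids:
            if g != grids[0]:
                raise ValueError("all prior volumes must share one grid")

    @property
    def n_priors(self) -> int:
        return len(self.dwi) + len(self.anatomical)

    def grid(self) -> GridSpec | None:
        if self.dwi:
            return self.dwi[0][1].grid
        if self.anatomical:
            return self.anatomical[0][1].grid
        return None

    def ordered_volumes(self) -> list[Volume3D]:
        """Priors in descriptor order: DWI ascending b, then anatomical as declared."""
        dwi_sorted = sorted(self.dwi, key=lambda bv: float(bv[0]))
        return [v for _, v in dwi_sorted] + [v for _, v in self.anatomical]

    def check_grid(self, grid: GridSpec) -> None:
        g = self.grid()
        if g is not None and g != grid:
            raise ValueError(f"prior grid {g} does not match target grid {grid}")


def normalize_coordinates(index, grid: GridSpec) -> np.ndarray:
    """Map 0-based voxel indices to [−1, 1] per axis (singleton axes map to 0).

    ``index`` may be a single triple or an (..., 3) array.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape[-1] != 3:
        raise ValueError("index must have 3 components")
    shape = np.asarray(grid.shape, dtype=float)
    if np.any(idx < 0) or np.any(idx > shape - 1):
        raise IndexError(f"index out of range for grid shape {grid.shape}")
    denom = np.where(shape > 1, shape - 1.0, 1.0)
    p = -1.0 + 2.0 * idx / denom
    return np.where(shape > 1, p, 0.0)


def grid_coordinates(grid: GridSpec) -> np.ndarray:
    """Normalized coordinates of every voxel, shape (n_voxels, 3), C index order."""
    nx, ny, nz = grid.shape
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
    return normalize_coordinates(idx, grid)


def extract_patch(vol: Volume3D, index, patch_size: int = 3) -> np.ndarray:
    """Flattened patch_size³ cube centred at ``index``, edges replicated.

    Flattening is x-fastest.  ``patch_size`` must be odd.
    """
    _check_patch_size(patch_size)
    i, j, k = (int(v) for v in index)
    nx, ny, nz = vol.grid.shape
    if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
        raise IndexError(f"index {index} outside grid {vol.grid.shape}")
    h = (patch_size - 1) // 2
    xi = np.clip(np.arange(i - h, i + h + 1), 0, nx - 1)
    yi = np.clip(np.arange(j - h, j + h + 1), 0, ny - 1)
    zi = np.clip(np.arange(k - h, k + h + 1), 0, nz - 1)
    cube = vol.data[np.ix_(xi, yi, zi)]
    return cube.flatten(order="F")


def _check_patch_size(patch_size: int) -> None:
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd and positive, got {patch_size}")


def extract_all_patches(data: np.ndarray, patch_size: int, dtype=np.float64) -> np.ndarray:
    """Patches at every voxel, shape (n_voxels, patch_size³), x-fastest within a patch.

    Vectorised equivalent of calling :func:`extract_patch` at each voxel in C
    index order.
    """
    _check_patch_size(patch_size)
    h = (patch_size - 1) // 2
    padded = np.pad(np.asarray(data, dtype=dtype), h, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (patch_size,) * 3)
    # window axes (3,4,5) = (dx,dy,dz); transpose so dx varies fastest on reshape
    win = win.transpose(0, 1, 2, 5, 4, 3)
    n = data.shape[0] * data.shape[1] * data.shape[2]
    return np.ascontiguousarray(win).reshape(n, patch_size**3)


def resample_to_grid(src: Volume3D, target_grid: GridSpec) -> Volume3D:
    """Trilinear resampling of ``src`` onto ``target_grid``.

    The grids are assumed axis-aligned with a shared origin at the centre of
    voxel (0,0,0); the correspondence is the per-axis scaling
    src_index = target_index · spacing_target / spacing_src.  Target voxels
    falling outside the source extent take the nearest edge value.
    """
    if src.grid == target_grid:
        return src.with_data(src.data.copy())
    scale = np.asarray(target_grid.spacing) / np.asarray(src.grid.spacing)
    axes = [np.arange(n, dtype=float) * scale[a] for a, n in enumerate(target_grid.shape)]
    ix, iy, iz = np.meshgrid(*axes, indexing="ij")
    out = map_coordinates(src.data, [ix, iy, iz], order=1, mode="nearest")
    return Volume3D(target_grid, out, role=src.role, meta=src.meta)


def descriptor_length(enc_cfg: EncodingConfig, n_priors: int, patch_size: int = 3) -> int:
    """encoding length + patch_size³ · (number of prior volumes)."""
    return encoding_length(enc_cfg) + patch_size**3 * n_priors


def assemble_descriptor(
    index,
    encoding_vec: np.ndarray,
    priors: PriorStack,
    patch_size: int = 3,
) -> np.ndarray:
    """f(p) for one voxel: [encoding, DWI patches (ascending b), anatomical patches]."""
    parts = [np.asarray(encoding_vec, dtype=float)]
    for vol in priors.ordered_volumes():
        parts.append(extract_patch(vol, index, patch_size))
    return np.concatenate(parts)


def build_descriptor_matrix(
    grid: GridSpec,
    enc_cfg: EncodingConfig,
    priors: PriorStack,
    patch_size: int = 3,
    prior_scales: list[float] | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Descriptors for every voxel of ``grid``, shape (n_voxels, D).

    ``prior_scales``, when given, divides each prior volume (in descriptor
    order) by its scale before patch extraction; used by the trainer to put
    heterogeneous contrasts on comparable intensity scales.
    """
    priors.check_grid(grid)
    coords = grid_coordinates(grid)
    enc = encode(coords, enc_cfg).astype(dtype)
    vols = priors.ordered_volumes()
    if prior_scales is not None and len(prior_scales) != len(vols):
        raise ValueError("prior_scales length must match number of prior volumes")
    blocks = [enc]
    for m, vol in enumerate(vols):
        data = vol.data
        if prior_scales is not None:
            data = data / prior_scales[m]
        blocks.append(extract_all_patches(data, patch_size, dtype=dtype))
    return np.concatenate(blocks, axis=1)
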