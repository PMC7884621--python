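"""Synthetic rodent-brain tissue phantom.

The phantom stands in for a segmented rat-brain atlas plus a DTI-derived
anisotropy field.  It is a labelled voxel volume (CSF / gray matter / white
matter / encapsulation) over a box domain, together with named region masks
for the two stimulation targets (an oblate STN-like nucleus and a compact
EPN-like nucleus), a thalamus slab and an internal-capsule-like white-matter
sheet, and a per-voxel unit-determinant conductivity-anisotropy tensor field.

Geometry is parametric (ellipsoids and slabs) rather than atlas-derived: the
stand-in preserves the topology that matters for cranial electrode
implantations — the target nucleus sits below the electrode tip, the thalamus
lies beside the upper shaft, and the white-matter sheet lies between the
EPN-analogue and the thalamus.

Coordinates are right-handed millimetres with the dorsoventral axis along +z;
the electrode is inserted along -z.  Voxel centres sit at
``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("dbsfem.phantom")

# tissue labels
CSF = 1
GM = 2
WM = 3
ENCAP = 4
# non-tissue labels used by the solver for embedded electrode elements
ELECTRODE_INS = 5
ELECTRODE_METAL = 6

LABEL_NAMES = {CSF: "CSF", GM: "GM", WM: "WM", ENCAP: "ENCAP",
               ELECTRODE_INS: "ELECTRODE_INS", ELECTRODE_METAL: "ELECTRODE_METAL"}

REGION_NAMES = ("STN", "EPN", "THALAMUS", "IC")


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        a = np.asarray(self.semi_axes)
        with np.errstate(divide="ignore"):
            q = ((pts - c) / a) ** 2
        return q.sum(axis=-1) <= 1.0


@dataclass
class Slab:
    """Axis-aligned box region, bounds as ((x0,x1),(y0,y1),(z0,z1)) in mm."""
    bounds: tuple[tuple[float, float], ...]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        m = np.ones(pts.shape[:-1], dtype=bool)
        for ax, (lo, hi) in enumerate(self.bounds):
            if hi <= lo:
                return np.zeros(pts.shape[:-1], dtype=bool)
            m &= (pts[..., ax] >= lo) & (pts[..., ax] <= hi)
        return m


@dataclass
class PhantomConfig:
    """Parametric description of the synthetic tissue volume.

    Default dimensions are chosen to be realistic for an adult rat:
    the STN-analogue is oblate (lateral extent larger than dorsoventral,
    volume ~0.8 mm^3), the EPN-analogue compact (~0.3 mm^3), and the
    domain is large enough that a 2 mm probe ball around either target's
    electrode stays inside brain tissue.
    """
    domain_extent: tuple[float, float, float] = (6.6, 6.6, 6.6)  # mm box
    voxel_size: float = 0.025  # mm; resolves a 0.1 mm capsule with 4 voxels
    stn: Ellipsoid = field(default_factory=lambda: Ellipsoid(
        center=(-1.0, 0.0, -0.8), semi_axes=(0.9, 0.7, 0.30)))
    epn: Ellipsoid = field(default_factory=lambda: Ellipsoid(
        center=(1.0, 0.0, -0.8), semi_axes=(0.42, 0.42, 0.38)))
    thalamus: Slab = field(default_factory=lambda: Slab(
        bounds=((-2.9, 2.9), (-2.9, 2.9), (0.5, 2.1))))
    ic_sheet: Slab = field(default_factory=lambda: Slab(
        bounds=((0.3, 2.5), (-2.9, 2.9), (0.05, 0.40))))
    csf_layer: float = 0.25          # mm CSF rind at the domain boundary
    wm_fa: float = 0.7               # fractional anisotropy of white matter
    center_jitter: float = 0.0       # mm random offset of nucleus centres
    random_seed: int = 0

    def validate(self) -> None:
        half = np.asarray(self.domain_extent) / 2.0
        for nm, e in (("stn", self.stn), ("epn", self.epn)):
            c = np.abs(np.asarray(e.center)) + np.asarray(e.semi_axes)
            if np.any(c > half):
                raise ValueError(f"target '{nm}' extends outside the domain")
        if not (0.0 <= self.wm_fa < 1.0):
            raise ValueError("wm_fa must lie in [0, 1)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


class VoxelTensorField:
    """Per-voxel symmetric unit-determinant tensors, identity by default.

    Only voxels whose tensor differs from the identity are stored (flat
    voxel indices + upper-triangle components), which keeps full-resolution
    phantoms cheap: anisotropy is typically confined to white matter.
    """

    _TRIU = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

    def __init__(self, shape: tuple[int, int, int],
                 flat_index: np.ndarray | None = None,
                 components: np.ndarray | None = None):
        self.shape = tuple(shape)
        self.flat_index = (np.empty(0, dtype=np.int64) if flat_index is None
                           else np.asarray(flat_index, dtype=np.int64))
        self.components = (np.empty((0, 6)) if components is None
                           else np.asarray(components, dtype=np.float64))
        order = np.argsort(self.flat_index)
        self.flat_index = self.flat_index[order]
        self.components = self.components[order]

    @staticmethod
    def pack(tensors: np.ndarray) -> np.ndarray:
        return np.stack([tensors[..., i, j] for i, j in VoxelTensorField._TRIU],
                        axis=-1)

    @staticmethod
    def unpack(components: np.ndarray) -> np.ndarray:
        t = np.zeros(components.shape[:-1] + (3, 3))
        for k, (i, j) in enumerate(VoxelTensorField._TRIU):
            t[..., i, j] = components[..., k]
            t[..., j, i] = components[..., k]
        return t

    def tensor_at_flat(self, flat: np.ndarray) -> np.ndarray:
        """Full 3x3 tensors for flat voxel indices (identity where unset)."""
        flat = np.asarray(flat)
        out = np.broadcast_to(np.eye(3), flat.shape + (3, 3)).copy()
        if self.flat_index.size:
            pos = np.searchsorted(self.flat_index, flat)
            pos = np.clip(pos, 0, self.flat_index.size - 1)
            hit = self.flat_index[pos] == flat
            if np.any(hit):
                out[hit] = self.unpack(self.components[pos[hit]])
        return out

    @property
    def n_anisotropic(self) -> int:
        return int(self.flat_index.size)


@dataclass
class TissuePhantom:
    label_grid: np.ndarray                      # int8 (nx, ny, nz)
    region_masks: dict[str, np.ndarray]         # name -> bool (nx, ny, nz)
    voxel_size: float                           # mm, isotropic
    origin: np.ndarray                          # mm position of voxel (0,0,0) corner
    tensor_field: VoxelTensorField
    config: PhantomConfig | None = None

    # ---- coordinate helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    @property
    def domain_bounds(self) -> np.ndarray:
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape) * self.voxel_size
        return np.stack([lo, hi])

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (clipped to the grid)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        return np.clip(idx, 0, np.asarray(self.shape) - 1)

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size
                     for a in range(3))

    def label_at(self, pts: np.ndarray) -> np.ndarray:
        i = self.world_to_index(pts)
        return self.label_grid[i[:, 0], i[:, 1], i[:, 2]]

    def mask_at(self, name: str, pts: np.ndarray) -> np.ndarray:
        if name not in self.region_masks:
            raise KeyError(f"unknown region '{name}'; have {sorted(self.region_masks)}")
        i = self.world_to_index(pts)
        return self.region_masks[name][i[:, 0], i[:, 1], i[:, 2]]

    def tensor_at(self, pts: np.ndarray) -> np.ndarray:
        i = self.world_to_index(pts)
        flat = np.ravel_multi_index((i[:, 0], i[:, 1], i[:, 2]), self.shape)
        return self.tensor_field.tensor_at_flat(flat)

    def region_centroid(self, name: str) -> np.ndarray:
        """Voxel-mass centroid of a region mask, in world mm."""
        if name not in self.region_masks:
            raise KeyError(f"unknown region '{name}'")
        m = self.region_masks[name]
        if not m.any():
            raise ValueError(f"region '{name}' mask is empty")
        idx = np.argwhere(m)
        return self.origin + (idx.mean(axis=0) + 0.5) * self.voxel_size

    def copy_labels(self) -> "TissuePhantom":
        """Shallow copy sharing masks/tensors but with a private label grid."""
        return TissuePhantom(self.label_grid.copy(),
                             dict(self.region_masks), self.voxel_size,
                             self.origin.copy(), self.tensor_field, self.config)

    # ---- I/O ----------------------------------------------------------------

    def to_nifti(self, prefix: str, include_tensors: bool = False) -> list[str]:
        """Write labels, masks and (optionally) the anisotropy tensors as
        NIfTI volumes; tensors go into one 6-component 4-D volume (upper
        triangle xx, xy, xz, yy, yz, zz)."""
        import nibabel as nib
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = self.origin + 0.5 * self.voxel_size
        written = []
        img = nib.Nifti1Image(self.label_grid.astype(np.int16), aff)
        nib.save(img, f"{prefix}_labels.nii")
        written.append(f"{prefix}_labels.nii")
        for name, m in self.region_masks.items():
            p = f"{prefix}_mask_{name}.nii"
            nib.save(nib.Nifti1Image(m.astype(np.uint8), aff), p)
            written.append(p)
        if include_tensors:
            comp = np.zeros(self.shape + (6,), dtype=np.float32)
            comp[..., [0, 3, 5]] = 1.0                 # identity default
            tf = self.tensor_field
            if tf.n_anisotropic:
                idx = np.unravel_index(tf.flat_index, self.shape)
                comp[idx] = tf.components.astype(np.float32)
            p = f"{prefix}_tensors.nii"
            nib.save(nib.Nifti1Image(comp, aff), p)
            written.append(p)
        return written

    @classmethod
    def from_nifti(cls, prefix: str) -> "TissuePhantom":
        """Load a phantom written by :meth:`to_nifti` (or user-supplied
        volumes following the same naming and affine conventions)."""
        import glob
        import nibabel as nib
        img = nib.load(f"{prefix}_labels.nii")
        labels = np.asarray(img.dataobj).astype(np.int8)
        voxel = float(img.affine[0, 0])
        origin = np.asarray(img.affine[:3, 3], dtype=float) - 0.5 * voxel
        masks = {}
        for p in sorted(glob.glob(f"{prefix}_mask_*.nii")):
            name = p.split("_mask_")[-1].removesuffix(".nii")
            masks[name] = np.asarray(nib.load(p).dataobj).astype(bool)
        tf = VoxelTensorField(labels.shape)
        try:
            comp = np.asarray(nib.load(f"{prefix}_tensors.nii").dataobj)
            ident = np.zeros(6)
            ident[[0, 3, 5]] = 1.0
            flat = np.flatnonzero(
                np.any(np.abs(comp - ident) > 1e-7, axis=-1))
            if flat.size:
                tf = VoxelTensorField(labels.shape, flat,
                                      comp.reshape(-1, 6)[flat])
        except FileNotFoundError:
            pass
        return cls(labels, masks, voxel, origin, tf)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_phantom(config: PhantomConfig | None = None) -> TissuePhantom:
    """Build the labelled synthetic phantom from a parametric config.

    Gray matter background; CSF rind at the domain boundary; white-matter
    sheet (internal-capsule analogue) between the EPN-analogue and the
    thalamus slab; the nuclei and the thalamus stay gray matter and are
    additionally recorded as region masks.  Deterministic for a fixed
    ``random_seed``.
    """
    config = config or PhantomConfig()
    config.validate()

    rng = np.random.default_rng(config.random_seed)
    cfg = copy.deepcopy(config)
    if cfg.center_jitter > 0:
        for e in (cfg.stn, cfg.epn):
            e.center = tuple(np.asarray(e.center)
                             + rng.uniform(-cfg.center_jitter, cfg.center_jitter, 3))

    ext = np.asarray(cfg.domain_extent, dtype=float)
    n = np.maximum(np.round(ext / cfg.voxel_size).astype(int), 1)
    origin = -ext / 2.0
    xs, ys, zs = (origin[a] + (np.arange(n[a]) + 0.5) * cfg.voxel_size for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    labels = np.full(tuple(n), GM, dtype=np.int8)
    masks: dict[str, np.ndarray] = {}

    masks["THALAMUS"] = cfg.thalamus.contains(pts)
    ic = cfg.ic_sheet.contains(pts)
    labels[ic] = WM
    masks["IC"] = ic

    stn = cfg.stn.contains(pts)
    epn = cfg.epn.contains(pts)
    if np.any(stn & epn):
        raise ValueError("target regions overlap: STN and EPN")
    labels[stn] = GM
    labels[epn] = GM
    masks["STN"] = stn
    masks["EPN"] = epn
    # nuclei punched out of any overlapping slab regions
    masks["THALAMUS"] &= ~(stn | epn)
    masks["IC"] &= ~(stn | epn)
    labels[stn | epn] = GM

    if cfg.csf_layer > 0:
        rind = np.zeros(tuple(n), dtype=bool)
        for ax in range(3):
            d = np.minimum(pts[..., ax] - origin[ax],
                           origin[ax] + ext[ax] - pts[..., ax])
            rind |= d <= cfg.csf_layer
        labels[rind] = CSF
        for m in masks.values():
            m &= ~rind

    ph = TissuePhantom(labels, masks, cfg.voxel_size, origin,
                       VoxelTensorField(tuple(n)), config=cfg)
    logger.info("phantom built: shape=%s voxel=%.3f mm", ph.shape, ph.voxel_size)
    return ph


# ---------------------------------------------------------------------------
# encapsulation layer
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Electrode track: a segment from tip ``p0`` to entry point ``p1`` with a
    shaft radius (scalar mm, or a callable of the axial distance from p0)."""
    p0: Sequence[float]
    p1: Sequence[float]
    radius: float | Callable[[np.ndarray], np.ndarray]

    def surface_distance(self, pts: np.ndarray) -> np.ndarray:
        """Approximate signed distance from the shaft surface (radially)."""
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        d = p1 - p0
        L = np.linalg.norm(d)
        u = d / L
        s = (pts - p0) @ u
        s_cl = np.clip(s, 0.0, L)
        closest = p0 + s_cl[:, None] * u
        dist_axis = np.linalg.norm(pts - closest, axis=1)
        r = self.radius(s_cl) if callable(self.radius) else float(self.radius)
        return dist_axis - r


def carve_encapsulation(phantom: TissuePhantom, track: Track,
                        thickness: float = 0.1) -> TissuePhantom:
    """Relabel a ~0.1 mm shell around the electrode track as encapsulation.

    Voxels strictly outside the shaft surface but within ``thickness`` of it
    become ENCAP.  If the requested shell is thinner than one voxel it is
    widened to one voxel (with a warning) so that a shell exists at all.
    Relabelled voxels are removed from the region masks: scar tissue is no
    longer counted as nucleus, thalamus or tract.
    """
    b = phantom.domain_bounds
    for p in (track.p0, track.p1):
        p = np.asarray(p, dtype=float)
        if np.any(p < b[0]) or np.any(p > b[1]):
            raise ValueError(f"track point {p} lies outside the phantom domain")

    eff = thickness
    if thickness < phantom.voxel_size:
        eff = phantom.voxel_size
        logger.warning("encapsulation thickness %.3g mm below voxel size %.3g mm; "
                       "widening to one voxel", thickness, phantom.voxel_size)

    out = phantom.copy_labels()
    xs, ys, zs = phantom.voxel_centers_1d()
    # bounding slab around the track to avoid evaluating the whole volume
    p0 = np.asarray(track.p0, dtype=float)
    p1 = np.asarray(track.p1, dtype=float)
    rmax = (float(np.max(track.radius(np.linspace(0, np.linalg.norm(p1 - p0), 64))))
            if callable(track.radius) else float(track.radius))
    pad = rmax + eff + phantom.voxel_size
    lo = np.minimum(p0, p1) - pad
    hi = np.maximum(p0, p1) + pad
    sl = tuple(slice(np.searchsorted(c, l), np.searchsorted(c, h) + 1)
               for c, l, h in zip((xs, ys, zs), lo, hi))
    Xs, Ys, Zs = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
    pts = np.stack([Xs.ravel(), Ys.ravel(), Zs.ravel()], axis=-1)
    d = track.surface_distance(pts).reshape(Xs.shape)
    shell = (d > 0) & (d <= eff)
    sub = out.label_grid[sl]
    sub[shell] = ENCAP
    out.label_grid[sl] = sub
    out.region_masks = {k: v.copy() for k, v in out.region_masks.items()}
    for m in out.region_masks.values():
        msub = m[sl]
        msub[shell] = False
        m[sl] = msub
    logger.info("encapsulation carved: %d voxels (shell %.3g mm)",
                int(shell.sum()), eff)
    return out


# ---------------------------------------------------------------------------
# anisotropy
# ---------------------------------------------------------------------------

def fa_to_eigenvalue_ratio(fa: float) -> float:
    """Prolate-tensor eigenvalue ratio lambda_par/lambda_perp for a given FA."""
    if not (0.0 <= fa < 1.0):
        raise ValueError("fa must lie in [0, 1)")
    if fa == 0.0:
        return 1.0
    a = 1.0 - fa * fa
    return (1.0 + np.sqrt(1.0 - a * (1.0 - 2.0 * fa * fa))) / a


def make_anisotropy(phantom: TissuePhantom,
                    principal_direction_field: Callable[[np.ndarray], np.ndarray]
                    | Sequence[float] | None = None,
                    fa_level: float | None = None,
                    tissue_labels: tuple[int, ...] = (WM,)) -> TissuePhantom:
    """Attach unit-determinant anisotropy tensors to the phantom.

    The tensor at each voxel of the selected tissue classes is prolate with
    its principal eigenvector taken from ``principal_direction_field`` and
    the eigenvalue ratio set by the fractional-anisotropy level; it is then
    volume-normalised to determinant one, so multiplying by a scalar tissue
    conductivity preserves the geometric-mean conductivity (the volume-
    normalised reading of conductivity tensor mapping from diffusion data).
    Other voxels keep the identity tensor.
    """
    if fa_level is None:
        fa_level = phantom.config.wm_fa if phantom.config is not None else 0.7
    rho = fa_to_eigenvalue_ratio(fa_level)

    sel = np.isin(phantom.label_grid, tissue_labels)
    flat = np.flatnonzero(sel)
    out = TissuePhantom(phantom.label_grid, phantom.region_masks,
                        phantom.voxel_size, phantom.origin,
                        VoxelTensorField(phantom.shape), phantom.config)
    if flat.size == 0 or rho == 1.0:
        logger.info("anisotropy: isotropic (fa=%.3g, %d voxels selected)",
                    fa_level, flat.size)
        return out

    idx = np.stack(np.unravel_index(flat, phantom.shape), axis=1)
    pts = phantom.origin + (idx + 0.5) * phantom.voxel_size
    if principal_direction_field is None:
        e1 = np.broadcast_to(np.array([1.0, 0.0, 0.0]), (flat.size, 3)).copy()
    elif callable(principal_direction_field):
        e1 = np.asarray(principal_direction_field(pts), dtype=float)
    else:
        v = np.asarray(principal_direction_field, dtype=float)
        e1 = np.broadcast_to(v, (flat.size, 3)).copy()
    norms = np.linalg.norm(e1, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-12):
        warnings.warn("principal directions are not unit vectors; normalizing")
    if np.any(norms == 0):
        raise ValueError("zero-length principal direction vector")
    e1 = e1 / norms[:, None]

    # det-normalised prolate eigenvalues
    lam = np.array([rho, 1.0, 1.0]) / rho ** (1.0 / 3.0)
    # T = lam_perp * I + (lam_par - lam_perp) e1 e1^T
    outer = np.einsum("ni,nj->nij", e1, e1)
    T = lam[1] * np.eye(3)[None] + (lam[0] - lam[1]) * outer
    out.tensor_field = VoxelTensorField(phantom.shape, flat,
                                        VoxelTensorField.pack(T))
    logger.info("anisotropy: fa=%.3g ratio=%.3g on %d voxels",
                fa_level, rho, flat.size)
    return out


def default_ic_direction_field(pts: np.ndarray) -> np.ndarray:
    """Default fibre orientation for the white-matter sheet: mediolateral."""
    e = np.zeros_like(pts)
    e[:, 0] = 1.0
    return e
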