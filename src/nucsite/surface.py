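"""Solvent-excluded-surface (SES) approximation and surface filters.

The SES interior is approximated on a regular grid as the morphological
closing of the van-der-Waals volume with a spherical probe: a grid
point is interior if it lies inside a vdW sphere or cannot be reached
by any probe sphere placed entirely outside the vdW volume.  Surface
vertices are the interior voxels bordering the exterior.  Predicted
fragments with any heavy atom inside the surface are rejected, and the
survivors must keep a module-type-specific minimum distance from the
nearest surface vertex (empirical thresholds observed on real bound
nucleotides: nucleobase 0.407 Å, carbohydrate 0.124 Å, phosphate
0.830 Å).

A precomputed vertex list (e.g. an MSMS ``.vert`` file) may be supplied
in place of the internal grid surface.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from .structio import (CARBOHYDRATE, NUCLEOBASE, PHOSPHATE,
                       EmptyStructureError, ModuleFragment, Structure)

PROBE_RADIUS = 1.4   # Å
GRID_SPACING = 0.4   # Å


def load_vdw_radii(path=None) -> tuple[dict[str, float], float]:
    if path is None:
        ref = importlib.resources.files("nucsite") / "data" / "vdw_radii.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {k.upper(): float(v) for k, v in raw["radii"].items()}, float(raw["default"])


@dataclass
class SurfaceThresholds:
    """Minimum allowed fragment–surface distance per module type (Å)."""
    min_distance: dict[str, float] = field(default_factory=lambda: {
        NUCLEOBASE: 0.407,
        CARBOHYDRATE: 0.124,
        PHOSPHATE: 0.830,
    })

    def __post_init__(self):
        if any(v < 0 for v in self.min_distance.values()):
            raise ValueError("surface thresholds must be non-negative")


@dataclass
class SurfaceMesh:
    vertices: np.ndarray                 # (n, 3) Å
    probe_radius: float = PROBE_RADIUS
    grid_spacing: float = GRID_SPACING
    source: str = "internal"
    # internal-grid context (absent for external meshes)
    _interior: np.ndarray | None = None
    _origin: np.ndarray | None = None
    # fallback inside test for external meshes: vdW spheres of the structure
    _atom_tree: cKDTree | None = None
    _atom_radii: np.ndarray | None = None
    _vertex_tree: cKDTree | None = None

    def __post_init__(self):
        if len(self.vertices) == 0:
            raise EmptyStructureError("surface mesh has no vertices")

    def vertex_tree(self) -> cKDTree:
        if self._vertex_tree is None:
            self._vertex_tree = cKDTree(self.vertices)
        return self._vertex_tree

    def is_inside(self, point: np.ndarray) -> bool:
        p = np.asarray(point, dtype=float)
        if self._interior is not None:
            idx = np.round((p - self._origin) / self.grid_spacing).astype(int)
            if np.any(idx < 0) or np.any(idx >= self._interior.shape):
                return False
            return bool(self._interior[tuple(idx)])
        if self._atom_tree is not None:
            d, i = self._atom_tree.query(p)
            return bool(d <= self._atom_radii[i])
        return False


def _chain_heavy_atoms(structure: Structure, chain_id: str):
    chain = structure.chain(chain_id)
    coords, elements = [], []
    for res in chain.residues:
        for a in res.atoms:
            if not a.is_hydrogen():
                coords.append(a.pos)
                elements.append(a.element)
    return np.array(coords), elements


def build_ses_mesh(structure: Structure, chain_id: str,
                   probe: float = PROBE_RADIUS,
                   spacing: float = GRID_SPACING,
                   vdw_radii=None) -> SurfaceMesh:
    """Grid SES for one chain (deterministic for a fixed spacing)."""
    coords, elements = _chain_heavy_atoms(structure, chain_id)
    if coords.size == 0:
        raise EmptyStructureError(f"chain {chain_id} has no heavy atoms")
    if vdw_radii is None:
        table, default = load_vdw_radii()
    else:
        table, default = vdw_radii
    radii = np.array([table.get(e.upper(), default) for e in elements])

    pad = radii.max() + probe + 2 * spacing
    origin = coords.min(axis=0) - pad
    top = coords.max(axis=0) + pad
    shape = np.ceil((top - origin) / spacing).astype(int) + 1
    axes = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    points = grid.reshape(-1, 3)

    # signed distance to the vdW surface: min over atoms of (|p-a| - r_a)
    D = np.full(len(points), np.inf)
    for r in np.unique(radii):
        tree = cKDTree(coords[radii == r])
        d, _ = tree.query(points, workers=-1)
        np.minimum(D, d - r, out=D)
    D = D.reshape(shape)

    accessible = D >= probe          # valid probe-centre positions
    # exterior = probe-ball dilation of the accessible region
    if accessible.any():
        dist_to_acc = ndimage.distance_transform_edt(
            ~accessible, sampling=(spacing,) * 3)
        exterior = dist_to_acc <= probe + 1e-9
    else:
        exterior = np.zeros(shape, dtype=bool)
    interior = ~exterior

    boundary = interior & ~ndimage.binary_erosion(interior)
    vertices = grid[boundary]
    return SurfaceMesh(vertices=vertices, probe_radius=probe,
                       grid_spacing=spacing, source="internal",
                       _interior=interior, _origin=origin)


def load_external_mesh(path, structure: Structure | None = None,
                       chain_id: str | None = None,
                       vdw_radii=None) -> SurfaceMesh:
    """Read a whitespace-separated ``x y z`` vertex list (MSMS ``.vert``
    leading columns accepted; its 3-line header is skipped).

    If the structure is supplied, the inside test falls back to the vdW
    spheres of the chain; otherwise every point counts as outside.
    """
    vertices = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            # '#' comments, short rows and the 4-5 column MSMS counts
            # header are skipped; vertex rows have 3 or >= 6 columns
            if line.lstrip().startswith("#") or len(parts) < 3 or \
                    len(parts) in (4, 5):
                continue
            try:
                xyz = [float(parts[0]), float(parts[1]), float(parts[2])]
            except ValueError:
                continue
            vertices.append(xyz)
    mesh = SurfaceMesh(vertices=np.array(vertices), source="external")
    if structure is not None and chain_id is not None:
        coords, elements = _chain_heavy_atoms(structure, chain_id)
        if vdw_radii is None:
            table, default = load_vdw_radii()
        else:
            table, default = vdw_radii
        mesh._atom_tree = cKDTree(coords)
        mesh._atom_radii = np.array([table.get(e.upper(), default)
                                     for e in elements])
    return mesh


def is_inside(point: np.ndarray, mesh: SurfaceMesh) -> bool:
    """True iff the point lies in the closed SES interior."""
    return mesh.is_inside(point)


def min_surface_distance(fragment: ModuleFragment, mesh: SurfaceMesh) -> float:
    """Minimum distance over all (heavy atom, surface vertex) pairs."""
    xyz = fragment.heavy_coords()
    if xyz.size == 0:
        raise ValueError("fragment has no heavy atoms")
    d, _ = mesh.vertex_tree().query(xyz)
    return float(np.min(d))


def surface_filter(predictions: list, mesh: SurfaceMesh,
                   thresholds: SurfaceThresholds | None = None):
    """Apply the inside test and the minimum-distance thresholds.

    ``predictions`` may be fragments or objects with a ``fragment``
    attribute.  Returns ``(kept, dropped)`` where dropped entries are
    ``(prediction, reason)`` tuples; the filter is order-independent
    and idempotent.
    """
    thresholds = thresholds or SurfaceThresholds()
    kept, dropped = [], []
    for pred in predictions:
        frag = getattr(pred, "fragment", pred)
        if any(mesh.is_inside(a.pos) for a in frag.atoms if not a.is_hydrogen()):
            dropped.append((pred, "atom-inside-surface"))
            continue
        dmin = min_surface_distance(frag, mesh)
        floor = thresholds.min_distance.get(frag.module_type, 0.0)
        if dmin < floor:
            dropped.append((pred, f"surface-distance {dmin:.3f} < {floor:.3f}"))
            continue
        kept.append(pred)
    return kept, dropped
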