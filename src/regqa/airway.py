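"""Airway segmentation, skeletonization and functional surface projection.

The airway lumen is segmented by seeded region growing under a fixed
homogeneity interval.  Its skeleton is built slice by slice: each axial
slice contributes one node per in-plane connected component, placed at the
component's centre of gravity, and nodes on adjacent slices are linked when
their components overlap in-plane.  Short terminal branches (fewer than six
nodes, unless they branch again before the sixth node) are pruned.  PET
activity is projected onto the airway boundary by sampling along the
outward surface normal up to a fixed depth (10 mm by default, the range of
a transbronchial needle), counting only samples outside the airway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, ValidationError
from .volume import BinaryMask, ScalarVolume

__all__ = ["SkeletonNode", "SkeletonTree", "SurfaceElements",
           "region_grow", "build_skeleton", "prune_skeleton",
           "surface_elements", "project_activity",
           "write_skeleton", "read_skeleton"]

_CONN26 = np.ones((3, 3, 3), bool)
_CONN8 = np.ones((3, 3), bool)
_CONN6 = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# region growing

def region_grow(ct: ScalarVolume, seed: tuple[int, int, int],
                homogeneity: tuple[float, float]) -> BinaryMask:
    """Maximal 26-connected region around ``seed`` inside an HU interval.

    ``homogeneity`` is the closed intensity interval (lo, hi); the seed voxel
    must satisfy it.
    """
    lo, hi = homogeneity
    if lo > hi:
        raise ValidationError("homogeneity interval is empty")
    seed = tuple(int(s) for s in seed)
    if any(not (0 <= s < n) for s, n in zip(seed, ct.shape)):
        raise ValidationError(f"seed {seed} outside volume of shape {ct.shape}")
    seed_value = ct.values[seed]
    if not (lo <= seed_value <= hi):
        raise ValidationError(
            f"seed voxel value {seed_value} HU outside homogeneity "
            f"interval [{lo}, {hi}]")
    window = (ct.values >= lo) & (ct.values <= hi)
    labels, _ = ndimage.label(window, structure=_CONN26)
    return BinaryMask(labels == labels[seed], ct.spacing, ct.origin)


# ---------------------------------------------------------------------------
# skeleton

@dataclass
class SkeletonNode:
    """One centre-of-gravity point: ordinal, world position, children."""

    index: int
    position: tuple[float, float, float]      # (x, y, z) mm
    children: list[int] = field(default_factory=list)


@dataclass
class SkeletonTree:
    """Slice-wise centre-of-gravity tree of the airway."""

    nodes: dict[int, SkeletonNode]
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def parents(self) -> dict[int, int]:
        par: dict[int, int] = {}
        for node in self.nodes.values():
            for c in node.children:
                par[c] = node.index
        return par

    def leaves(self) -> list[int]:
        return [i for i, n in self.nodes.items() if not n.children]

    def branching_nodes(self) -> list[int]:
        return [i for i, n in self.nodes.items() if len(n.children) >= 2]

    def validate(self) -> None:
        ids = set(self.nodes)
        if self.root not in ids:
            raise ValidationError("root is not a node")
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            i = stack.pop()
            if i in seen:
                raise ValidationError(f"cycle through node {i}")
            seen.add(i)
            missing = [c for c in self.nodes[i].children if c not in ids]
            if missing:
                raise ValidationError(f"node {i} references unknown {missing}")
            stack.extend(self.nodes[i].children)
        if seen != ids:
            raise ValidationError("tree is not connected from the root")


def build_skeleton(airway: BinaryMask, axis: int = 0) -> SkeletonTree:
    """Slice-wise centre-of-gravity skeleton of an airway mask.

    Per slice along ``axis`` (default 0, the axial/cranio-caudal axis of the
    (slice, row, column) array; slice 0 is taken as the cranial end), one
    node is created for every in-plane 8-connected component at that
    component's centroid in world mm.  Components on adjacent slices are
    linked when they overlap in-plane; a component overlapping two or more
    on the next slice becomes a branching node.  The tree is rooted at the
    most cranial slice; if that slice holds several components the largest
    becomes the root and a warning is emitted.  Nodes unreachable from the
    root (disconnected islands) are discarded with a warning.
    """
    if not airway.values.any():
        raise EmptyMaskError("empty airway mask")
    vol = np.moveaxis(airway.values, axis, 0)
    spacing = np.asarray(airway.spacing, float)
    origin = np.asarray(airway.origin, float)
    # per-axis mm spacing in the moved frame: axis 0 is the slicing axis
    order = [axis] + [a for a in range(3) if a != axis]

    nodes: dict[int, SkeletonNode] = {}
    next_id = 1
    prev: list[tuple[int, np.ndarray]] = []   # (node id, labelled slice) of k-1
    first_slice_nodes: list[tuple[int, int]] = []   # (size, node id)
    first_seen = None

    for k in range(vol.shape[0]):
        sl = vol[k]
        if not sl.any():
            prev = []
            continue
        labels, n = ndimage.label(sl, structure=_CONN8)
        current = []
        for lab in range(1, n + 1):
            comp = labels == lab
            rc = np.argwhere(comp).mean(axis=0)   # (row, col) in moved frame
            idx_moved = np.array([k, rc[0], rc[1]])
            idx = np.empty(3)
            for moved_pos, orig_axis in enumerate(order):
                idx[orig_axis] = idx_moved[moved_pos]
            mm = origin + idx * spacing           # (slice, row, col) mm
            pos = (float(mm[2]), float(mm[1]), float(mm[0]))   # (x, y, z)
            node = SkeletonNode(next_id, pos)
            nodes[next_id] = node
            current.append((next_id, comp, int(comp.sum())))
            next_id += 1
        if first_seen is None:
            first_seen = k
            first_slice_nodes = [(size, nid) for nid, _, size in current]
        # link: child on slice k attaches to the slice k-1 component with
        # the largest in-plane overlap
        for nid, comp, _ in current:
            best, best_ov = None, 0
            for pid, pcomp in prev:
                ov = int((comp & pcomp).sum())
                if ov > best_ov:
                    best, best_ov = pid, ov
            if best is not None:
                nodes[best].children.append(nid)
        prev = [(nid, comp) for nid, comp, _ in current]

    if len(first_slice_nodes) > 1:
        warnings.warn("cranial-most slice has multiple components; rooting "
                      "at the largest", stacklevel=2)
    root = max(first_slice_nodes)[1]

    # keep only nodes reachable from the root
    reachable: set[int] = set()
    stack = [root]
    while stack:
        i = stack.pop()
        if i in reachable:
            continue
        reachable.add(i)
        stack.extend(nodes[i].children)
    if len(reachable) < len(nodes):
        warnings.warn(f"discarding {len(nodes) - len(reachable)} skeleton "
                      "node(s) not connected to the cranial root",
                      stacklevel=2)
        nodes = {i: n for i, n in nodes.items() if i in reachable}
        for n in nodes.values():
            n.children = [c for c in n.children if c in reachable]

    tree = SkeletonTree(nodes=nodes, root=root)
    tree.validate()
    return tree


def _terminal_chain(tree: SkeletonTree, leaf: int,
                    parents: dict[int, int]) -> list[int]:
    """Nodes from the leaf up to (excluding) the nearest branching node."""
    chain = [leaf]
    cur = leaf
    while cur in parents:
        par = parents[cur]
        if len(tree.nodes[par].children) >= 2:
            break
        chain.append(par)
        cur = par
    return chain


def prune_skeleton(tree: SkeletonTree, min_branch_nodes: int = 6) -> SkeletonTree:
    """Erase short terminal branches.

    A terminal branch is the maximal chain from a leaf up to the nearest
    branching node (exclusive).  Branches with fewer than
    ``min_branch_nodes`` nodes are removed; a short twig that itself
    branches before its sixth node is, by this chain definition, not a
    single terminal branch and its stem therefore survives.  Removal is
    iterated to a fixed point.  A chain containing the root is never
    removed (the tree is never emptied).
    """
    nodes = {i: SkeletonNode(n.index, n.position, list(n.children))
             for i, n in tree.nodes.items()}
    out = SkeletonTree(nodes=nodes, root=tree.root)
    changed = True
    while changed:
        changed = False
        parents = out.parents()
        for leaf in out.leaves():
            chain = _terminal_chain(out, leaf, parents)
            if len(chain) >= min_branch_nodes or out.root in chain:
                continue
            top = chain[-1]
            par = parents.get(top)
            if par is not None:
                out.nodes[par].children.remove(top)
            for i in chain:
                del out.nodes[i]
            changed = True
            break   # recompute parents/leaves after each removal
    out.validate()
    return out


# ---------------------------------------------------------------------------
# skeleton file I/O: one node per line, "i x y z i1 i2 ..."

def write_skeleton(tree: SkeletonTree, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(tree.nodes):
            n = tree.nodes[i]
            parts = [str(n.index)] + [repr(c) for c in n.position]
            parts += [str(c) for c in n.children]
            fh.write(" ".join(parts) + "\n")


def read_skeleton(path, root: int | None = None) -> SkeletonTree:
    nodes: dict[int, SkeletonNode] = {}
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            idx = int(tokens[0])
            pos = tuple(float(t) for t in tokens[1:4])
            children = [int(t) for t in tokens[4:]]
            nodes[idx] = SkeletonNode(idx, pos, children)
    if not nodes:
        raise ValidationError(f"{path}: empty skeleton file")
    if root is None:
        with_parent = {c for n in nodes.values() for c in n.children}
        roots = [i for i in nodes if i not in with_parent]
        if len(roots) != 1:
            raise ValidationError(f"{path}: cannot infer a unique root")
        root = roots[0]
    tree = SkeletonTree(nodes=nodes, root=root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# surface and functional projection

@dataclass(frozen=True)
class SurfaceElements:
    """Boundary voxels of the airway with outward unit normals (mm frame)."""

    voxel_indices: np.ndarray    # (n, 3) int, (slice, row, col)
    positions: np.ndarray        # (n, 3) float mm, (x, y, z)
    normals: np.ndarray          # (n, 3) float, unit, (x, y, z), outward

    @property
    def n_elements(self) -> int:
        return len(self.voxel_indices)


def _index_to_xyz(idx: np.ndarray, spacing, origin) -> np.ndarray:
    mm = np.asarray(origin, float) + idx * np.asarray(spacing, float)
    return mm[:, ::-1]          # (slice,row,col) mm -> (x,y,z)


def surface_elements(airway: BinaryMask, smooth_mm: float = 1.0) -> SurfaceElements:
    """Airway voxels 6-adjacent to the outside, with outward normals.

    Normals are the normalised gradient of a Gaussian-smoothed signed
    distance field (positive outside), so they point away from the airway.
    """
    if not airway.values.any():
        raise EmptyMaskError("empty airway mask")
    inside = airway.values
    eroded = ndimage.binary_erosion(inside, structure=_CONN6, border_value=0)
    surf = inside & ~eroded
    idx = np.argwhere(surf)

    spacing = np.asarray(airway.spacing, float)
    d_out = ndimage.distance_transform_edt(~inside, sampling=spacing)
    d_in = ndimage.distance_transform_edt(inside, sampling=spacing)
    sdf = d_out - d_in
    sigma = smooth_mm / spacing
    sdf = ndimage.gaussian_filter(sdf, sigma=sigma)
    grads = np.gradient(sdf, *spacing)           # per array axis
    vecs = np.stack([g[surf] for g in grads], axis=1)   # (n, 3) slice,row,col
    norms = np.linalg.norm(vecs, axis=1)
    # fall back to the centroid direction where the smoothed field is flat
    flat = norms < 1e-9
    if flat.any():
        centroid = np.argwhere(inside).mean(axis=0) * spacing
        alt = idx[flat] * spacing - centroid
        alt_n = np.linalg.norm(alt, axis=1)
        alt[alt_n < 1e-9] = (1.0, 0.0, 0.0)
        vecs[flat] = alt
        norms = np.linalg.norm(vecs, axis=1)
    vecs /= norms[:, None]
    positions = _index_to_xyz(idx.astype(float), airway.spacing, airway.origin)
    normals = vecs[:, ::-1]                      # -> (x, y, z)
    return SurfaceElements(voxel_indices=idx, positions=positions,
                           normals=normals)


def _xyz_to_index_coords(points_xyz: np.ndarray, spacing, origin) -> np.ndarray:
    """(n, 3) xyz mm -> (3, n) fractional array indices (slice, row, col)."""
    mm = points_xyz[:, ::-1] - np.asarray(origin, float)
    return (mm / np.asarray(spacing, float)).T


def project_activity(pet: ScalarVolume, airway: BinaryMask,
                     surface: SurfaceElements, depth_mm: float = 10.0,
                     method: str = "ray") -> np.ndarray:
    """Project PET activity onto the airway surface.

    ``method="ray"`` (default): per surface element, activity is sampled
    trilinearly along the outward normal at steps of half the minimum
    spacing, from just outside the surface out to ``depth_mm``; samples
    falling inside the airway are discarded and the rest are summed.

    ``method="shell"``: every outside voxel within ``depth_mm`` of the
    airway surface is assigned to its nearest surface element and voxel
    activities are summed per element.

    Returns one projected value per surface element.
    """
    if depth_mm <= 0:
        raise ValidationError("depth_mm must be positive")
    if not pet.same_grid(airway):
        raise ValidationError("PET volume must live on the airway grid")
    if method == "ray":
        step = 0.5 * min(pet.spacing)
        ts = np.arange(step, depth_mm + 1e-9, step)
        pts = (surface.positions[:, None, :]
               + ts[None, :, None] * surface.normals[:, None, :])
        coords = _xyz_to_index_coords(pts.reshape(-1, 3), pet.spacing, pet.origin)
        samples = ndimage.map_coordinates(pet.values, coords, order=1,
                                          mode="constant", cval=0.0)
        inside = ndimage.map_coordinates(airway.values.astype(np.uint8),
                                         coords, order=0, mode="constant",
                                         cval=0)
        samples = samples * (inside == 0)
        return samples.reshape(surface.n_elements, ts.size).sum(axis=1)
    if method == "shell":
        spacing = np.asarray(pet.spacing, float)
        dist = ndimage.distance_transform_edt(~airway.values, sampling=spacing)
        shell = (~airway.values) & (dist <= depth_mm) & (dist > 0)
        vox = np.argwhere(shell)
        if len(vox) == 0:
            return np.zeros(surface.n_elements)
        tree = cKDTree(surface.voxel_indices * spacing)
        _, nearest = tree.query(vox * spacing)
        out = np.zeros(surface.n_elements)
        np.add.at(out, nearest, pet.values[shell])
        return out
    raise ValidationError(f"unknown projection method {method!r}")
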