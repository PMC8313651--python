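"""Region growing, slice-wise skeleton, pruning and surface projection."""

import numpy as np
import pytest

import regqa as rq
from regqa.airway import SkeletonNode, SkeletonTree
from regqa.errors import EmptyMaskError, ValidationError
from tests.conftest import make_volume


# ---------------------------------------------------------------------------
# region growing

def test_region_grow_recovers_tube_lumen(straight_tube):
    vol, lumen = straight_tube
    seed = tuple(np.argwhere(lumen.values)[0])
    grown = rq.region_grow(vol, seed, (-1024, -950))
    assert np.array_equal(grown.values, lumen.values)


def test_region_grow_seed_outside_interval(straight_tube):
    vol, _ = straight_tube
    with pytest.raises(ValidationError, match="0.0 HU"):
        rq.region_grow(vol, (0, 0, 0), (-1024, -950))   # wall voxel
    with pytest.raises(ValidationError):
        rq.region_grow(vol, (0, 0, 999), (-1024, -950))  # outside volume


@pytest.mark.parametrize("seed", range(3))
def test_region_grow_connected_and_contains_seed(seed):
    rng = np.random.default_rng(seed)
    vol = make_volume(rng.choice([-1000.0, 0.0], size=(8, 8, 8)))
    lumen_voxels = np.argwhere(vol.values == -1000.0)
    start = tuple(lumen_voxels[rng.integers(len(lumen_voxels))])
    grown = rq.region_grow(vol, start, (-1024, -950))
    assert grown.values[start]
    from scipy import ndimage
    labels, n = ndimage.label(grown.values, structure=np.ones((3, 3, 3)))
    assert n == 1


# ---------------------------------------------------------------------------
# skeleton construction

def test_straight_tube_skeleton_is_axial_chain(straight_tube):
    vol, lumen = straight_tube
    tree = rq.build_skeleton(lumen)
    assert tree.n_nodes == 30
    assert tree.branching_nodes() == []
    for node in tree.nodes.values():
        # centroids sit on the tube axis at (x, y) = (12, 12) mm
        assert node.position[0] == pytest.approx(12.0)
        assert node.position[1] == pytest.approx(12.0)
    # chain: each node except the leaf has exactly one child
    assert sum(len(n.children) for n in tree.nodes.values()) == 29


def test_y_phantom_has_one_bifurcation(y_thorax):
    tree = rq.prune_skeleton(rq.build_skeleton(y_thorax.airway))
    branching = tree.branching_nodes()
    assert len(branching) == 1
    assert len(tree.nodes[branching[0]].children) == 2


def test_skeleton_nodes_inside_airway(y_thorax):
    tree = rq.build_skeleton(y_thorax.airway)
    spacing = np.asarray(y_thorax.airway.spacing)
    hits = 0
    for node in tree.nodes.values():
        idx = np.round(np.asarray(node.position)[::-1] / spacing).astype(int)
        hits += bool(y_thorax.airway.values[tuple(idx)])
    assert hits == tree.n_nodes


def test_binary_tree_branching_node_count():
    spec = rq.PhantomSpec(shape=(56, 72, 72),
                          airway=rq.AirwayTreeSpec(branching_depth=2))
    thorax = rq.make_thorax(spec)
    tree = rq.prune_skeleton(rq.build_skeleton(thorax.airway))
    assert len(tree.branching_nodes()) == 2 ** 2 - 1


def test_empty_mask_rejected():
    with pytest.raises(EmptyMaskError):
        rq.build_skeleton(rq.BinaryMask(np.zeros((4, 4, 4), bool)))


# ---------------------------------------------------------------------------
# pruning

def chain_tree(n, start=1, parent=None, nodes=None):
    nodes = {} if nodes is None else nodes
    prev = parent
    for i in range(start, start + n):
        nodes[i] = SkeletonNode(i, (0.0, 0.0, float(i)))
        if prev is not None:
            nodes[prev].children.append(i)
        prev = i
    return nodes, prev


def test_prune_removes_short_twig():
    nodes, _ = chain_tree(30)
    nodes, _ = chain_tree(3, start=31, parent=10, nodes=nodes)  # 3-node twig
    tree = SkeletonTree(nodes=nodes, root=1)
    pruned = rq.prune_skeleton(tree)
    assert pruned.n_nodes == 30
    assert sorted(pruned.nodes) == list(range(1, 31))


def test_prune_keeps_twig_stem_that_branches_early():
    """A 3-node twig whose 2nd node spawns a 10-node branch keeps its stem."""
    nodes, _ = chain_tree(30)
    nodes, _ = chain_tree(3, start=31, parent=10, nodes=nodes)   # 31,32,33
    nodes, _ = chain_tree(10, start=34, parent=32, nodes=nodes)  # long branch
    tree = SkeletonTree(nodes=nodes, root=1)
    pruned = rq.prune_skeleton(tree)
    # stem 31-32 and the 10-node branch survive; terminal node 33 is a
    # 1-node branch below the new bifurcation and is erased
    assert 31 in pruned.nodes and 32 in pruned.nodes and 34 in pruned.nodes
    assert 33 not in pruned.nodes
    assert pruned.n_nodes == 30 + 2 + 10


def test_prune_idempotent_and_never_grows():
    nodes, _ = chain_tree(12)
    nodes, _ = chain_tree(7, start=13, parent=6, nodes=nodes)
    tree = SkeletonTree(nodes=nodes, root=1)
    once = rq.prune_skeleton(tree)
    assert once.n_nodes <= tree.n_nodes
    assert once.n_nodes == tree.n_nodes        # all branches >= 6 nodes
    twice = rq.prune_skeleton(once)
    assert sorted(twice.nodes) == sorted(once.nodes)


def test_prune_never_erases_root_chain():
    nodes, _ = chain_tree(4)
    tree = SkeletonTree(nodes=nodes, root=1)
    assert rq.prune_skeleton(tree).n_nodes == 4


def test_skeleton_file_round_trip(tmp_path, y_thorax):
    tree = rq.build_skeleton(y_thorax.airway)
    path = tmp_path / "skeleton.txt"
    rq.write_skeleton(tree, path)
    again = rq.read_skeleton(path)
    assert again.root == tree.root
    assert sorted(again.nodes) == sorted(tree.nodes)
    for i, node in tree.nodes.items():
        assert again.nodes[i].position == node.position
        assert again.nodes[i].children == node.children


# ---------------------------------------------------------------------------
# surface elements and activity projection

def test_surface_of_solid_cube():
    mask = np.zeros((7, 7, 7), bool)
    mask[2:5, 2:5, 2:5] = True
    surf = rq.surface_elements(rq.BinaryMask(mask))
    assert surf.n_elements == 26                 # all but the centre voxel
    assert np.allclose(np.linalg.norm(surf.normals, axis=1), 1.0, atol=1e-6)


def test_surface_of_single_voxel():
    mask = np.zeros((5, 5, 5), bool)
    mask[2, 2, 2] = True
    surf = rq.surface_elements(rq.BinaryMask(mask))
    assert surf.n_elements == 1
    assert np.allclose(np.linalg.norm(surf.normals, axis=1), 1.0, atol=1e-6)


def test_projection_zero_activity_is_zero(straight_tube):
    vol, lumen = straight_tube
    surf = rq.surface_elements(lumen)
    pet = make_volume(np.zeros(lumen.shape), spacing=lumen.spacing,
                      modality="PET")
    assert np.array_equal(rq.project_activity(pet, lumen, surf),
                          np.zeros(surf.n_elements))


@pytest.mark.parametrize("method", ["ray", "shell"])
def test_projection_linear_in_activity(straight_tube, method):
    vol, lumen = straight_tube
    surf = rq.surface_elements(lumen)
    rng = np.random.default_rng(4)
    p1 = make_volume(rng.random(lumen.shape), lumen.spacing, "PET")
    p2 = make_volume(rng.random(lumen.shape), lumen.spacing, "PET")
    combo = make_volume(2.5 * p1.values + p2.values, lumen.spacing, "PET")
    a = rq.project_activity(p1, lumen, surf, method=method)
    b = rq.project_activity(p2, lumen, surf, method=method)
    c = rq.project_activity(combo, lumen, surf, method=method)
    assert np.allclose(c, 2.5 * a + b, rtol=1e-9, atol=1e-9)


def test_projection_uniform_activity_symmetric_on_shaft(straight_tube):
    vol, lumen = straight_tube
    surf = rq.surface_elements(lumen)
    pet = make_volume(np.full(lumen.shape, 3.0), lumen.spacing, "PET")
    proj = rq.project_activity(pet, lumen, surf, depth_mm=6.0)
    # restrict to shaft elements away from the open tube ends
    z = surf.positions[:, 2]
    shaft = (z > 10.0) & (z < 34.0)
    vals = proj[shaft]
    assert vals.std() / vals.mean() < 0.05


def test_projection_hot_sphere_peaks_at_nearest_element(straight_tube):
    vol, lumen = straight_tube
    surf = rq.surface_elements(lumen)
    # hot sphere 5 mm outside the wall, mid-shaft, on the +x side
    center = np.array([12.0 + 4.0 + 5.0, 12.0, 22.5])    # (x, y, z) mm
    shape, spacing = lumen.shape, lumen.spacing
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s
                               for n, s in zip(shape, spacing)), indexing="ij")
    hot = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2
           + (zz - center[2]) ** 2) <= 3.0 ** 2
    pet = make_volume(hot * 100.0, spacing, "PET")
    proj = rq.project_activity(pet, lumen, surf, depth_mm=10.0)
    best = surf.positions[np.argmax(proj)]
    dists = np.linalg.norm(surf.positions - center, axis=1)
    assert np.linalg.norm(best - center) <= dists.min() + 2.0


def test_projection_rejects_bad_depth(straight_tube):
    vol, lumen = straight_tube
    surf = rq.surface_elements(lumen)
    pet = make_volume(np.zeros(lumen.shape), lumen.spacing, "PET")
    with pytest.raises(ValidationError):
        rq.project_activity(pet, lumen, surf, depth_mm=0.0)
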