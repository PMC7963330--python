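"""Branch-graph extraction, Sholl analysis and soma detection oracles."""

import numpy as np
import pytest
from scipy import ndimage

from astroglia_age import morphometry as mm
from astroglia_age import recovery, synthgen
from astroglia_age.containers import Image2D

SPACING = (1.0, 0.2, 0.2)


def _tube_mask(shape, start_um, end_um, radius=0.6):
    """Binary mask of a straight tube between two (z, y, x) µm points."""
    mask = np.zeros(shape, dtype=bool)
    start, end = np.asarray(start_um, float), np.asarray(end_um, float)
    n = int(np.linalg.norm(end - start) / 0.1) + 1
    sp = np.array(SPACING)
    for t in np.linspace(0, 1, n):
        c = start + t * (end - start)
        zc, yc, xc = np.round(c / sp).astype(int)
        rz = max(1, int(np.ceil(radius / SPACING[0])))
        ry = int(np.ceil(radius / SPACING[1]))
        sl = (slice(max(0, zc - rz), min(shape[0], zc + rz + 1)),
              slice(max(0, yc - ry), min(shape[1], yc + ry + 1)),
              slice(max(0, xc - ry), min(shape[2], xc + ry + 1)))
        zz, yy, xx = np.mgrid[sl]
        d2 = ((zz * sp[0] - c[0]) ** 2 + (yy * sp[1] - c[1]) ** 2
              + (xx * sp[2] - c[2]) ** 2)
        mask[sl] |= d2 <= radius ** 2
    return mask


def _soma_ball(shape, center_um, radius=3.0):
    sp = np.array(SPACING)
    zz, yy, xx = np.indices(shape)
    d2 = (((zz * sp[0] - center_um[0])) ** 2
          + ((yy * sp[1] - center_um[1])) ** 2
          + ((xx * sp[2] - center_um[2])) ** 2)
    return d2 <= radius ** 2


@pytest.fixture(scope="module")
def straight_cell():
    shape = (16, 176, 240)
    center = np.array([8.0, 16.0, 8.0])
    soma = _soma_ball(shape, center)
    tube = _tube_mask(shape, center, center + [0, 0, 23.0])
    return shape, center, soma, tube


def test_straight_tube_single_edge_length(straight_cell):
    """A 20-µm process gives one edge whose arc length matches the planted
    geometry within voxel tolerance."""
    shape, center, soma, tube = straight_cell
    bg = mm.extract_branch_graph(tube | soma, soma, SPACING,
                                 soma_center=center)
    lengths = bg.edge_lengths()
    assert len(lengths) == 1
    # planted free length: 23 µm minus soma radius 3 minus exclusion margin
    expected = 23.0 - 3.0 - 2.2
    assert lengths[0] == pytest.approx(expected, abs=1.5)
    assert len(bg.primary_edges()) == 1


def test_empty_mask_errors(straight_cell):
    shape, center, soma, _ = straight_cell
    with pytest.raises(ValueError, match="empty|segmented"):
        mm.extract_branch_graph(np.zeros(shape, bool), soma, SPACING)


def test_y_tube_topology(straight_cell):
    """A Y-shaped process: one branch point, three edges, one primary."""
    shape, center, soma, _ = straight_cell
    stem_end = center + [0, 0, 12.0]
    m = _tube_mask(shape, center, stem_end)
    m |= _tube_mask(shape, stem_end, stem_end + [0, 9.0, 7.0])
    m |= _tube_mask(shape, stem_end, stem_end + [0, -9.0, 7.0])
    bg = mm.extract_branch_graph(m | soma, soma, SPACING, soma_center=center)
    assert bg.n_edges == 3
    roles = [d["role"] for _, d in bg.graph.nodes(data=True)]
    assert roles.count("branchpoint") == 1
    assert len(bg.primary_edges()) == 1


def test_sholl_straddle_oracle(straight_cell):
    """A radial process spanning 8-30 µm crosses exactly the spheres with
    8 < r <= 30 and no others; two disjoint processes add."""
    shape, center, soma, _ = straight_cell
    import networkx as nx
    g = nx.MultiGraph()
    path = np.array([center + [0, 0, r] for r in np.linspace(8, 30, 100)])
    g.add_edge("a", "b", path=path, length=22.0)
    bg = mm.BranchGraph(graph=g, soma_center=center, spacing=SPACING)
    prof = mm.sholl_3d(bg)
    expected = ((prof.radii > 8) & (prof.radii <= 30)).astype(int)
    assert np.array_equal(prof.intersections, expected)
    # additivity
    path2 = np.array([center + [0, r, 0] for r in np.linspace(5.5, 20, 60)])
    g.add_edge("c", "d", path=path2, length=14.5)
    prof2 = mm.sholl_3d(mm.BranchGraph(g, center, SPACING))
    expected2 = expected + ((prof2.radii > 5.5) & (prof2.radii <= 20))
    assert np.array_equal(prof2.intersections, expected2)


def test_sholl_empty_graph_and_bad_radii(straight_cell):
    import networkx as nx
    _, center, _, _ = straight_cell
    bg = mm.BranchGraph(nx.MultiGraph(), center, SPACING)
    assert mm.sholl_3d(bg).intersections.sum() == 0
    with pytest.raises(ValueError):
        mm.sholl_3d(bg, radii=np.array([]))


def test_sholl_agrees_with_voxel_shell_oracle(straight_cell):
    """Polyline crossings match 26-connected shell components within ±1."""
    shape, center, soma, tube = straight_cell
    m = tube | _tube_mask(shape, center, center + [0, 18.0, 0])
    bg = mm.extract_branch_graph(m | soma, soma, SPACING, soma_center=center)
    prof = mm.sholl_3d(bg, radii=np.arange(7.0, 19.0))
    oracle = mm.sholl_voxel_oracle(m, center, SPACING,
                                   radii=np.arange(7.0, 19.0))
    assert np.all(np.abs(prof.intersections - oracle) <= 1)


def test_sholl_rotation_invariance(straight_cell):
    """90-degree lateral rotations of the mask leave the profile unchanged
    within ±1 crossing."""
    shape, center, soma, _ = straight_cell
    m = _tube_mask(shape, center, center + [0, 8.0, 18.0])
    base = mm.extract_branch_graph(m | soma, soma, SPACING,
                                   soma_center=center)
    p0 = mm.sholl_3d(base).intersections
    rot_m = np.rot90(m, axes=(1, 2)).copy()
    rot_s = np.rot90(soma, axes=(1, 2)).copy()
    c_rot = np.array([center[0],
                      (m.shape[2] - 1) * SPACING[2] - center[2], center[1]])
    rot = mm.extract_branch_graph(rot_m | rot_s, rot_s, SPACING,
                                  soma_center=c_rot)
    p1 = mm.sholl_3d(rot).intersections
    assert np.all(np.abs(p0 - p1) <= 1)


def test_domain_area_of_disc():
    """A cylinder footprint of radius 15.5 µm reads ~pi r^2."""
    shape = (6, 200, 200)
    yy, xx = np.mgrid[0:200, 0:200]
    disc = np.hypot((yy - 100) * 0.2, (xx - 100) * 0.2) <= 15.5
    mask = np.broadcast_to(disc, shape).copy()
    area = mm.projected_footprint_area(mask, SPACING)
    assert area == pytest.approx(np.pi * 15.5 ** 2, rel=0.05)


def test_count_somata_density_arithmetic():
    """5 planted somata in 300x300 µm² -> 0.556 per 100x100 µm²."""
    from astroglia_age.presets import Sr101Preset
    import dataclasses
    preset = Sr101Preset()
    found = 0
    for s in range(30):
        img, gt = synthgen.gen_sr101_field(preset, s)
        n = len(mm.detect_somata(img, soma_sigma=preset.soma_sigma))
        found += (n == gt["n_somata"])
        if gt["n_somata"] == 5:
            assert mm.count_somata(img) == pytest.approx(5 / 9 * 1.0, rel=1e-6)
    assert found >= 0.95 * 30          # >=95 % of fields counted exactly


def test_count_somata_blank_field():
    rng = np.random.default_rng(0)
    img = Image2D(rng.normal(20, 6, (300, 300)).astype(np.float32), 1.0)
    assert mm.count_somata(img) == 0.0


def test_count_coupled_trivials():
    from astroglia_age.presets import COUPLING_PRESETS
    import dataclasses
    single = dataclasses.replace(COUPLING_PRESETS["old"], n_coupled=0)
    img, _ = synthgen.gen_coupling_image(single, 1)
    assert mm.count_coupled(img) == 0
    img3, _ = synthgen.gen_coupling_image(COUPLING_PRESETS["old"], 1)
    assert mm.count_coupled(img3) == 3
    assert mm.count_coupled(Image2D(img3.data * 2.5, img3.pixel_size)) == 3


def test_primary_count_recovery(mini_astro_preset):
    """Planted primary-branch count recovered exactly on >=90 % of seeds of
    a sparse, well-separated test cell."""
    hits = 0
    n_seeds = 10
    for s in range(n_seeds):
        stack, gt = synthgen.gen_astrocyte_stack(mini_astro_preset, s,
                                                 domain_truth=False)
        mask, photons, enhanced, _ = recovery.segment_cell(stack, seed=s)
        soma = recovery.soma_mask_from_stack(stack)
        tm = mm.tracing_mask(enhanced, mask)
        bg = mm.extract_branch_graph(tm | soma, soma, spacing=stack.spacing)
        hits += (len(bg.primary_edges()) == gt["n_primary"])
    assert hits >= 0.9 * n_seeds
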