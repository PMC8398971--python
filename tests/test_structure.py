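"""Structure ingestion, superposition, neighbour classes and overlap geometry."""

import itertools

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.transform import Rotation

from frdex.sites import STANDARD_BASE_FRAMES, make_site
from frdex.structure import (
    StructureError,
    base_plane,
    classify_neighbors,
    com_distance,
    idealize_base,
    interface_overlap_totals,
    kabsch_superpose,
    read_structure,
    stacking_overlap_area,
    write_pdb,
)
from frdex.synthetic import GeneratorSpec, make_ideal_stack


def _rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


def _apply(sites, R, t):
    return [s.with_coords(s.coords() @ R.T + t) for s in sites]


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

class TestReadStructure:
    def test_roundtrip_of_generated_stack(self, stack, tmp_path):
        sites, _, _ = stack
        path = tmp_path / "stack.pdb"
        write_pdb([sites], path)
        back = read_structure(path)
        assert len(back) == 12
        assert all(s.base_type == "G" for s in back)
        for a, b in zip(sites, back):
            assert a.residue_label == b.residue_label
            np.testing.assert_allclose(
                a.coords(a.ring_atoms), b.coords(a.ring_atoms), atol=1e-3
            )

    def test_multi_model_coordinates_differ_labels_identical(self, stack, tmp_path):
        sites, _, _ = stack
        shifted = _apply(sites, np.eye(3), np.array([0.0, 0.0, 5.0]))
        path = tmp_path / "two_models.pdb"
        write_pdb([sites, shifted], path)
        m0 = read_structure(path, model_index=0)
        m1 = read_structure(path, model_index=1)
        assert [s.residue_label for s in m0] == [s.residue_label for s in m1]
        assert np.max(np.abs(m0[0].coords() - m1[0].coords())) > 1.0
        with pytest.raises(StructureError):
            read_structure(path, model_index=2)

    def test_backbone_and_ions_are_stripped(self, tmp_path):
        """Sugar atoms and inner ions must not survive ingestion."""
        lines = []
        serial = 1
        g = STANDARD_BASE_FRAMES["G"]
        for name, (x, y, z) in g.items():
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} DG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {name[0]}"
            )
            serial += 1
        for name, xyz in (("C1'", (-2.5, 5.4, 0.0)), ("P", (-4.0, 7.0, 1.0))):
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} DG A   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           {name[0]}"
            )
            serial += 1
        lines.append(
            f"HETATM{serial:5d} NA   NA  A   2       0.000   0.000   1.700"
            "  1.00  0.00          NA"
        )
        path = tmp_path / "with_backbone.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        sites = read_structure(path)
        assert len(sites) == 1
        names = {a.name for a in sites[0].atoms}
        assert "C1'" not in names and "P" not in names and "NA" not in names
        assert set(g) == names


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(0, 3, (7, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd < 1e-9
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_congruent_sets_superpose_exactly(self, rng):
        P = rng.normal(0, 3, (6, 3))
        Rm, tv = _rigid(rng)
        Q = P @ Rm.T + tv
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.isclose(np.linalg.det(R), 1.0)
        np.testing.assert_allclose(P @ R.T + t, Q, atol=1e-9)

    def test_beats_random_rigid_transforms(self, rng):
        """Brute-force oracle: no random rigid transform does better."""
        P = rng.normal(0, 2, (5, 3))
        Q = rng.normal(0, 2, (5, 3))
        _, _, rmsd = kabsch_superpose(P, Q)
        for _ in range(1000):
            Rm, tv = _rigid(rng)
            cand = np.sqrt(np.mean(np.sum((P @ Rm.T + tv - Q) ** 2, axis=1)))
            assert rmsd <= cand + 1e-12

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_flagged(self):
        P = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            kabsch_superpose(P, P)


# ---------------------------------------------------------------------------
# Base idealization
# ---------------------------------------------------------------------------

class TestIdealize:
    @pytest.fixture()
    def template(self):
        return make_site(0, "G", STANDARD_BASE_FRAMES["G"])

    def test_posed_copy_is_unchanged(self, template, rng):
        Rm, tv = _rigid(rng)
        posed = template.with_coords(template.coords() @ Rm.T + tv)
        out = idealize_base(posed, template)
        np.testing.assert_allclose(out.coords(), posed.coords(), atol=1e-9)

    def test_template_internal_geometry_is_copied_exactly(self, template, rng):
        distorted = template.with_coords(
            template.coords() + rng.normal(0, 0.15, template.coords().shape)
        )
        out = idealize_base(distorted, template)
        d_out = np.linalg.norm(
            out.coords()[:, None] - out.coords()[None, :], axis=2
        )
        d_tpl = np.linalg.norm(
            template.coords()[:, None] - template.coords()[None, :], axis=2
        )
        np.testing.assert_allclose(d_out, d_tpl, atol=1e-10)
        assert out.residue_label == distorted.residue_label

    def test_idempotent(self, template, rng):
        distorted = template.with_coords(
            template.coords() + rng.normal(0, 0.1, template.coords().shape)
        )
        once = idealize_base(distorted, template)
        twice = idealize_base(once, template)
        np.testing.assert_allclose(once.coords(), twice.coords(), atol=1e-9)

    def test_base_type_mismatch(self, template):
        other = make_site(1, "T", STANDARD_BASE_FRAMES["T"])
        with pytest.raises(ValueError, match="mismatch"):
            idealize_base(other, template)


# ---------------------------------------------------------------------------
# Neighbour classification
# ---------------------------------------------------------------------------

def _enumerate_expected(topology):
    """Literal enumeration oracle for pair classes."""
    tetrads = topology["tetrads"]
    strands = topology["strands"]
    hb = set()
    for t in tetrads:
        for k in range(len(t)):
            hb.add(frozenset((t[k], t[(k + 1) % len(t)])))
    st = set()
    for s in strands:
        st.update(frozenset(p) for p in zip(s, s[1:]))
    hb_of = {}
    for p in hb:
        a, b = tuple(p)
        hb_of.setdefault(a, set()).add(b)
        hb_of.setdefault(b, set()).add(a)
    dg = set()
    for p in st:
        a, b = tuple(p)
        for x, y in ((a, b), (b, a)):
            for h in hb_of.get(y, ()):
                q = frozenset((x, h))
                if len(q) == 2 and q not in st and q not in hb:
                    dg.add(q)
    return st, hb, dg


class TestNeighbors:
    def test_topology_mode_matches_enumeration_oracle(self, stack):
        sites, graph, topo = stack
        st, hb, dg = _enumerate_expected(topo)
        assert {frozenset(p) for p in graph.of_class("stacked")} == st
        assert {frozenset(p) for p in graph.of_class("hbonded")} == hb
        assert {frozenset(p) for p in graph.of_class("diagonal")} == dg
        assert len(st) == 8 and len(hb) == 12

    def test_antiparallel_basket_diagonal_pairs(self, stack):
        """Human-telomeric antiparallel basket: G1 is diagonal to G5 and G8.

        Tetrad cyclic orders chosen so that G2 (stacked on G1) hydrogen
        bonds to G5 and G8 (0-based ids are label minus 1).
        """
        sites, _, _ = stack
        topo = {
            "tetrads": [[0, 5, 6, 11], [4, 1, 7, 10], [2, 3, 8, 9]],
            "strands": [[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11]],
        }
        graph = classify_neighbors(sites, topology=topo)
        diag = {frozenset(p) for p in graph.of_class("diagonal")}
        assert frozenset((0, 4)) in diag   # G1-G5
        assert frozenset((0, 7)) in diag   # G1-G8
        assert graph.provenance == "topology_file"

    def test_geometric_mode_matches_topology_on_ideal_structure(self, stack):
        sites, graph, _ = stack
        geo = classify_neighbors(sites)
        assert geo.provenance == "geometric"
        assert geo.pairs == graph.pairs

    def test_geometric_mode_far_apart_bases(self):
        g = STANDARD_BASE_FRAMES["G"]
        a = make_site(0, "G", g)
        b = make_site(1, "G", {k: v + np.array([50.0, 0, 0]) for k, v in g.items()})
        graph = classify_neighbors([a, b])
        assert graph.pairs == {}

    def test_topology_with_unknown_sites_rejected(self, stack):
        sites, _, _ = stack
        with pytest.raises(StructureError):
            classify_neighbors(sites, topology={"tetrads": [[0, 1, 2, 99]], "strands": []})


# ---------------------------------------------------------------------------
# Planes, areas, distances
# ---------------------------------------------------------------------------

def _grid_overlap_oracle(site_i, site_j, step=0.02):
    """Dense-grid intersection-area oracle (independent of shapely)."""
    ci, cj = site_i.coords(site_i.ring_atoms), site_j.coords(site_j.ring_atoms)

    def normal(x):
        _, _, vh = np.linalg.svd(x - x.mean(0))
        return vh[2]

    ni, nj = normal(ci), normal(cj)
    if ni @ nj < 0:
        nj = -nj
    n = (ni + nj) / np.linalg.norm(ni + nj)
    c = 0.5 * (ci.mean(0) + cj.mean(0))
    u = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 0.1:
        u = np.cross(n, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n, u)

    def project(x):
        return np.column_stack([(x - c) @ u, (x - c) @ v])

    def inside(hull_pts, q):
        hull = ConvexHull(hull_pts)
        eq = hull.equations  # (n_facets, 3): a, b, offset
        return np.all(q @ eq[:, :2].T + eq[:, 2] <= 1e-12, axis=1)

    pi, pj = project(ci), project(cj)
    lo = np.minimum(pi.min(0), pj.min(0)) - 0.1
    hi = np.maximum(pi.max(0), pj.max(0)) + 0.1
    xs = np.arange(lo[0], hi[0], step)
    ys = np.arange(lo[1], hi[1], step)
    q = np.array(np.meshgrid(xs, ys)).reshape(2, -1).T
    both = inside(pi, q) & inside(pj, q)
    return both.sum() * step * step


class TestOverlap:
    def test_eclipsed_stack_gives_full_area(self):
        spec = GeneratorSpec(twist=0.0, slide=0.0)
        sites, graph, _ = make_ideal_stack(spec)
        a = stacking_overlap_area(sites[0], sites[4])
        hull = ConvexHull(sites[0].coords(sites[0].ring_atoms)[:, :2])
        assert a == pytest.approx(hull.volume, rel=1e-9)  # 2D hull volume = area

    def test_displaced_beyond_extent_gives_zero(self):
        g = STANDARD_BASE_FRAMES["G"]
        a = make_site(0, "G", g)
        b = make_site(1, "G", {k: v + np.array([30.0, 0, 3.4]) for k, v in g.items()})
        assert stacking_overlap_area(a, b) == 0.0

    def test_unit_squares_offset_half(self):
        sq = {"N1": (0, 0, 0), "C2": (1, 0, 0), "N3": (1, 1, 0), "C4": (0, 1, 0),
              "C5": (0.5, 0.5, 0), "C6": (0.5, 0.2, 0)}
        mk = lambda i, off, z: make_site(
            i, "T", {k: np.asarray(v, float) + np.array([off, 0, z]) for k, v in sq.items()}
        )
        assert stacking_overlap_area(mk(0, 0, 0), mk(1, 0.5, 1.0)) == pytest.approx(0.5, abs=1e-9)

    def test_matches_grid_oracle_on_real_pair(self, stack):
        sites, graph, _ = stack
        i, j = graph.of_class("stacked")[0]
        exact = stacking_overlap_area(sites[i], sites[j])
        approx = _grid_overlap_oracle(sites[i], sites[j])
        assert exact == pytest.approx(approx, rel=0.01)

    def test_overlap_bounded_by_min_area_and_rigid_invariant(self, stack, rng):
        sites, graph, _ = stack
        for i, j in graph.of_class("stacked")[:3]:
            a = stacking_overlap_area(sites[i], sites[j])
            hull_i = ConvexHull(sites[i].coords(sites[i].ring_atoms)[:, :2]).volume
            assert 0 <= a <= hull_i + 1e-9
            Rm, tv = _rigid(rng)
            si = sites[i].with_coords(sites[i].coords() @ Rm.T + tv)
            sj = sites[j].with_coords(sites[j].coords() @ Rm.T + tv)
            assert stacking_overlap_area(si, sj) == pytest.approx(a, abs=1e-9)

    def test_self_pair_rejected(self, stack):
        sites, _, _ = stack
        with pytest.raises(StructureError):
            stacking_overlap_area(sites[0], sites[0])


class TestPlane:
    def test_planar_ring_normal_is_z(self):
        site = make_site(0, "G", STANDARD_BASE_FRAMES["G"])
        n, p = base_plane(site)
        np.testing.assert_allclose(np.abs(n), [0, 0, 1], atol=1e-12)

    def test_normal_rotates_with_ring(self, rng):
        site = make_site(0, "G", STANDARD_BASE_FRAMES["G"])
        n0, _ = base_plane(site)
        Rm, tv = _rigid(rng)
        n1, _ = base_plane(site.with_coords(site.coords() @ Rm.T + tv))
        assert min(np.linalg.norm(n1 - Rm @ n0), np.linalg.norm(n1 + Rm @ n0)) < 1e-9

    def test_puckered_ring_beats_random_planes(self, rng):
        coords = np.array(list(STANDARD_BASE_FRAMES["G"].values()))
        coords = coords + np.column_stack(
            [np.zeros((len(coords), 2)), rng.normal(0, 0.2, len(coords))]
        )
        site = make_site(0, "G", dict(zip(STANDARD_BASE_FRAMES["G"], coords)))
        n, p = base_plane(site)
        fitted = np.max(np.abs((coords - p) @ n))
        rss_fit = np.sum(((coords - p) @ n) ** 2)
        for _ in range(10**4):
            nn = rng.normal(size=3)
            nn /= np.linalg.norm(nn)
            d = (coords - coords.mean(0)) @ nn
            assert rss_fit <= np.sum((d - d.mean()) ** 2) + 1e-12
        assert fitted < 0.6


class TestComDistance:
    def test_self_is_zero_and_symmetric(self, stack):
        sites, _, _ = stack
        assert com_distance(sites[0], sites[0]) == 0.0
        assert com_distance(sites[0], sites[5]) == com_distance(sites[5], sites[0])

    def test_pure_rise_construction(self):
        spec = GeneratorSpec(twist=0.0, slide=0.0, rise=3.4)
        sites, _, _ = make_ideal_stack(spec)
        assert com_distance(sites[0], sites[4]) == pytest.approx(3.4, abs=1e-9)


class TestInterfaceTotals:
    def test_symmetric_stack_totals(self, stack):
        sites, graph, topo = stack
        tetrad_of = {s: ti for ti, t in enumerate(topo["tetrads"]) for s in t}
        rep = interface_overlap_totals(sites, graph, tetrad_of)
        assert set(rep.interface_totals) == {(0, 1), (1, 2)}
        single = stacking_overlap_area(sites[0], sites[4])
        for tot in rep.interface_totals.values():
            assert tot == pytest.approx(4 * single, rel=1e-9)
        # totals are exactly the sum of their stacked-pair entries
        for (a, b), tot in rep.interface_totals.items():
            parts = [
                area for (i, j), area in rep.per_pair_area.items()
                if {tetrad_of[i], tetrad_of[j]} == {a, b}
            ]
            assert tot == pytest.approx(sum(parts), abs=1e-9)

    def test_doubling_twist_reduces_both_totals(self, spec, stack):
        sites, graph, topo = stack
        tetrad_of = {s: ti for ti, t in enumerate(topo["tetrads"]) for s in t}
        rep = interface_overlap_totals(sites, graph, tetrad_of)
        sites2, graph2, _ = make_ideal_stack(
            GeneratorSpec(twist=2 * spec.twist)
        )
        rep2 = interface_overlap_totals(sites2, graph2, tetrad_of)
        for key in rep.interface_totals:
            assert rep2.interface_totals[key] < rep.interface_totals[key]

    def test_stacked_pair_in_nonadjacent_tetrads_rejected(self, stack):
        sites, graph, topo = stack
        bad = {s: (0 if ti == 0 else 2) for ti, t in enumerate(topo["tetrads"]) for s in t}
        with pytest.raises(StructureError):
            interface_overlap_totals(sites, graph, bad)
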