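"""Structure ingestion and stacking geometry of base assemblies.

Reads multi-model PDB files (NMR ensembles, MD snapshots), strips every
residue down to its base chromophore, idealizes base internal geometries by
rigid template superposition, and computes the geometric descriptors the
excitonic model needs: neighbour classes (stacked / hydrogen-bonded /
diagonal), projected stacking overlap areas, and base centre-of-mass
distances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder
from scipy.spatial.transform import Rotation
from shapely.geometry import MultiPoint

from .sites import (
    Atom,
    BASE_HEAVY_ATOMS,
    BASE_RING_ATOMS,
    ChromophoreSite,
    HBOND_ACCEPTORS,
    HBOND_DONORS,
    base_type_of_resname,
    canonical_atom_name,
)

__all__ = [
    "NeighborGraph",
    "OverlapReport",
    "read_structure",
    "count_models",
    "write_pdb",
    "kabsch_superpose",
    "idealize_base",
    "classify_neighbors",
    "base_plane",
    "stacking_overlap_area",
    "com_distance",
    "interface_overlap_totals",
    "load_topology",
    "save_topology",
]


class StructureError(ValueError):
    pass


# -- geometric neighbour-inference defaults (exposed, the reference protocol
#    uses topology knowledge rather than cutoffs) ---------------------------
DEFAULT_CUTOFFS = {
    "stack_com_max": 5.0,       # Angstrom
    "plane_angle_max": 30.0,    # degrees
    "hbond_com_max": 9.0,       # Angstrom
    "hbond_contact_max": 3.5,   # Angstrom, donor-acceptor heavy atoms
    "hbond_min_contacts": 2,
}


@dataclass
class NeighborGraph:
    """Unordered site pairs labelled stacked / hbonded / diagonal."""

    pairs: dict[tuple[int, int], str]
    provenance: str  # "topology_file" | "geometric"

    def __post_init__(self):
        for (i, j), cls in self.pairs.items():
            if i == j:
                raise StructureError(f"self-pair ({i},{i}) in neighbour graph")
            if cls not in ("stacked", "hbonded", "diagonal"):
                raise StructureError(f"unknown pair class {cls!r}")

    def of_class(self, cls: str) -> list[tuple[int, int]]:
        return sorted(p for p, c in self.pairs.items() if c == cls)

    def to_json(self, path) -> None:
        data = {
            "provenance": self.provenance,
            "pairs": [[i, j, c] for (i, j), c in sorted(self.pairs.items())],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NeighborGraph":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            pairs={(int(i), int(j)): c for i, j, c in data["pairs"]},
            provenance=data["provenance"],
        )


@dataclass
class OverlapReport:
    """Stacking overlap areas and COM distances for a structure."""

    per_pair_area: dict[tuple[int, int], float]
    interface_totals: dict[tuple[int, int], float]
    per_pair_com_distance: dict[tuple[int, int], float]
    structure_id: str = ""

    def to_json(self, path) -> None:
        data = {
            "structure_id": self.structure_id,
            "per_pair_area": [[i, j, a] for (i, j), a in sorted(self.per_pair_area.items())],
            "interface_totals": [[a, b, t] for (a, b), t in sorted(self.interface_totals.items())],
            "per_pair_com_distance": [
                [i, j, d] for (i, j), d in sorted(self.per_pair_com_distance.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def _pair_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def count_models(path) -> int:
    parser = PDBParser(QUIET=True)
    return len(parser.get_structure("s", str(path)))


def read_structure(path, model_index: int = 0) -> list[ChromophoreSite]:
    """Read one model of a PDB file and reduce it to base chromophores.

    Sugar/phosphate backbone atoms, hydrogens, ions and solvent are
    discarded; each remaining nucleobase residue becomes one
    :class:`ChromophoreSite` (ordered as in the file).  A base residue with
    missing ring atoms is an error naming the residue.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not 0 <= model_index < len(models):
        raise StructureError(
            f"model_index {model_index} out of range (file has {len(models)} models)"
        )
    model = models[model_index]
    multi_chain = len(list(model)) > 1

    sites: list[ChromophoreSite] = []
    for chain in model:
        for res in chain:
            base = base_type_of_resname(res.get_resname())
            if base is None:
                continue  # ion, water, ligand
            wanted = BASE_HEAVY_ATOMS[base]
            coords = {}
            for atom in res:
                name = canonical_atom_name(atom.get_name())
                if name in wanted:
                    coords[name] = np.asarray(atom.get_coord(), dtype=float)
            missing = [n for n in BASE_RING_ATOMS[base] if n not in coords]
            if missing:
                raise StructureError(
                    f"residue {res.get_resname()}{res.id[1]} (chain {chain.id}): "
                    f"missing ring atoms {missing}"
                )
            label = f"{base}{res.id[1]}"
            if multi_chain:
                label = f"{chain.id}:{label}"
            atoms = [
                Atom(n, n[0], coords[n]) for n in wanted if n in coords
            ]
            sites.append(
                ChromophoreSite(
                    site_id=len(sites),
                    residue_label=label,
                    base_type=base,
                    atoms=atoms,
                    ring_atoms=tuple(n for n in wanted if n in coords),
                )
            )
    return sites


def write_pdb(models: list[list[ChromophoreSite]], path) -> None:
    """Write one or more site lists as a (multi-)model PDB file."""
    builder = StructureBuilder()
    builder.init_structure("frdex")
    for i_model, sites in enumerate(models):
        builder.init_model(i_model)
        builder.init_chain("A")
        builder.init_seg("    ")
        for site in sites:
            resname = {"G": "DG", "A": "DA", "T": "DT"}[site.base_type]
            builder.init_residue(resname, " ", site.site_id + 1, " ")
            for atom in site.atoms:
                builder.init_atom(
                    atom.name, atom.xyz, 0.0, 1.0, " ", atom.name, None,
                    element=atom.element,
                )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


# ---------------------------------------------------------------------------
# Rigid superposition and base idealization
# ---------------------------------------------------------------------------

def kabsch_superpose(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rigid transform of point set P onto Q.

    Returns ``(rotation, translation, rmsd)`` with ``R @ p + t`` the
    superposed points.  Collinear/degenerate point sets are flagged with a
    warning (the in-plane component of the rotation is then arbitrary).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (N, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 points for superposition")
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - Pc, Q - Qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        warnings.warn("degenerate (collinear) point set in superposition")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on rank-deficient sets
        rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = Qc - R @ Pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def idealize_base(site: ChromophoreSite, template: ChromophoreSite) -> ChromophoreSite:
    """Replace a base's internal geometry by the template's, rigidly posed.

    The template (an optimized methylated base in practice) is superposed
    onto the site over the atoms they share by name; the returned site has
    exactly the template's interatomic geometry, in the site's pose, with
    the site's identity preserved.
    """
    if template.base_type != site.base_type:
        raise ValueError(
            f"base-type mismatch: site {site.base_type} vs template {template.base_type}"
        )
    common = [a.name for a in template.atoms if a.name in site._coord_index]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared atoms between site and template")
    R, t, _ = kabsch_superpose(template.coords(common), site.coords(common))
    new_xyz = template.coords() @ R.T + t
    atoms = [Atom(a.name, a.element, x) for a, x in zip(template.atoms, new_xyz)]
    return ChromophoreSite(
        site_id=site.site_id,
        residue_label=site.residue_label,
        base_type=site.base_type,
        atoms=atoms,
        ring_atoms=template.ring_atoms,
        monomer_data=site.monomer_data,
    )


# ---------------------------------------------------------------------------
# Planes, overlap areas, distances
# ---------------------------------------------------------------------------

def _fit_plane(points: np.ndarray):
    """Least-squares mean plane; returns (unit normal, centroid)."""
    c = points.mean(axis=0)
    X = points - c
    _, s, vh = np.linalg.svd(X, full_matrices=False)
    if s[1] < 1e-10:
        raise StructureError("degenerate geometry: points are collinear")
    n = vh[2]
    # sign convention: positive z, then positive x, then positive y
    for k in range(3):
        if abs(n[k]) > 1e-12:
            if n[k] < 0:
                n = -n
            break
    return n, c


def base_plane(site: ChromophoreSite):
    """Mean plane of the ring + exocyclic atoms: (unit normal, point)."""
    return _fit_plane(site.coords(site.ring_atoms))


def com_distance(site_i: ChromophoreSite, site_j: ChromophoreSite) -> float:
    """Distance between base heavy-atom centres of mass (Angstrom)."""
    return float(np.linalg.norm(site_i.com - site_j.com))


def _projected_polygon(coords: np.ndarray, origin, u, v):
    pts = [( float((x - origin) @ u), float((x - origin) @ v)) for x in coords]
    poly = MultiPoint(pts).convex_hull
    if poly.geom_type != "Polygon":
        raise StructureError("degenerate polygon in overlap projection")
    return poly


def stacking_overlap_area(site_i: ChromophoreSite, site_j: ChromophoreSite) -> float:
    """Overlap area (A^2) of the two bases' projections on their mean plane.

    Both bases' ring + exocyclic atoms are projected onto one common plane
    through the midpoint of the two ring centroids, normal to the bisector
    of the two base-plane normals (symmetric in the pair); each base's
    outline is the convex hull of its projected atoms and the returned
    value is the exact polygon-intersection area.
    """
    if site_i is site_j or site_i.site_id == site_j.site_id:
        raise StructureError("overlap area of a site with itself is undefined")
    ci = site_i.coords(site_i.ring_atoms)
    cj = site_j.coords(site_j.ring_atoms)
    ni, _ = _fit_plane(ci)
    nj, _ = _fit_plane(cj)
    if ni @ nj < 0:
        nj = -nj
    n = ni + nj
    n /= np.linalg.norm(n)
    origin = 0.5 * (ci.mean(axis=0) + cj.mean(axis=0))
    # in-plane orthonormal basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    pi = _projected_polygon(ci, origin, u, v)
    pj = _projected_polygon(cj, origin, u, v)
    return float(pi.intersection(pj).area)


# ---------------------------------------------------------------------------
# Neighbour classification
# ---------------------------------------------------------------------------

def _pairs_from_topology(topology: dict) -> dict[tuple[int, int], str]:
    tetrads = [list(t) for t in topology["tetrads"]]
    strands = [list(s) for s in topology.get("strands", [])]
    tetrad_of = {}
    for ti, t in enumerate(tetrads):
        for s in t:
            tetrad_of[s] = ti

    hbond_neighbors: dict[int, list[int]] = {}
    pairs: dict[tuple[int, int], str] = {}
    # hydrogen bonds: cyclic adjacency within each tetrad
    for t in tetrads:
        n = len(t)
        for k in range(n if n > 2 else n - 1):
            a, b = t[k], t[(k + 1) % n]
            pairs[_pair_key(a, b)] = "hbonded"
            hbond_neighbors.setdefault(a, []).append(b)
            hbond_neighbors.setdefault(b, []).append(a)
    # stacking: consecutive bases along a strand, in adjacent tetrads
    stacked = []
    for s in strands:
        for a, b in zip(s, s[1:]):
            if abs(tetrad_of[a] - tetrad_of[b]) != 1:
                raise StructureError(
                    f"strand neighbours {a},{b} are not in adjacent tetrads"
                )
            pairs[_pair_key(a, b)] = "stacked"
            stacked.append((a, b))
    # diagonal: a site with the H-bond neighbours of its stacking partner
    for a, b in stacked:
        for x, y in ((a, b), (b, a)):
            for h in hbond_neighbors.get(y, []):
                key = _pair_key(x, h)
                if key not in pairs:
                    pairs[key] = "diagonal"
    return pairs


def classify_neighbors(
    sites: list[ChromophoreSite],
    topology: dict | None = None,
    cutoffs: dict | None = None,
) -> NeighborGraph:
    """Label nearest-neighbour pairs as stacked, hbonded or diagonal.

    With an explicit topology (preferred; dict with "tetrads" as cyclically
    ordered id lists and "strands" as stacking-ordered id lists) the result
    is purely combinatorial.  Without one, geometric cutoffs are used:
    stacked pairs are close (COM distance) and near-parallel; H-bonded
    pairs are coplanar with at least two short donor-acceptor contacts; the
    diagonal class is composed from the other two.
    """
    ids = {s.site_id for s in sites}
    if topology is not None:
        listed = {s for t in topology["tetrads"] for s in t}
        if not listed <= ids:
            raise StructureError(
                f"topology references sites {sorted(listed - ids)} not in structure"
            )
        return NeighborGraph(_pairs_from_topology(topology), "topology_file")

    cfg = dict(DEFAULT_CUTOFFS)
    if cutoffs:
        cfg.update(cutoffs)
    by_id = {s.site_id: s for s in sites}
    planes = {s.site_id: base_plane(s)[0] for s in sites}
    coms = {s.site_id: s.com for s in sites}

    pairs: dict[tuple[int, int], str] = {}
    ambiguous = []
    sid = sorted(ids)
    for ii, i in enumerate(sid):
        for j in sid[ii + 1:]:
            d = float(np.linalg.norm(coms[i] - coms[j]))
            if d > cfg["hbond_com_max"]:
                continue
            cosang = abs(float(planes[i] @ planes[j]))
            angle = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
            if angle >= cfg["plane_angle_max"]:
                continue
            is_stacked = d < cfg["stack_com_max"]
            n_contacts = _count_hbond_contacts(by_id[i], by_id[j], cfg["hbond_contact_max"])
            is_hbonded = n_contacts >= cfg["hbond_min_contacts"]
            if is_stacked and is_hbonded:
                ambiguous.append((i, j))
            elif is_stacked:
                pairs[(i, j)] = "stacked"
            elif is_hbonded:
                pairs[(i, j)] = "hbonded"
    if ambiguous:
        raise StructureError(
            f"ambiguous geometric assignment (stacked and H-bonded): {ambiguous}"
        )
    # diagonal class by composition stacked . hbonded
    hb: dict[int, list[int]] = {}
    for (a, b), c in pairs.items():
        if c == "hbonded":
            hb.setdefault(a, []).append(b)
            hb.setdefault(b, []).append(a)
    for (a, b), c in list(pairs.items()):
        if c != "stacked":
            continue
        for x, y in ((a, b), (b, a)):
            for h in hb.get(y, []):
                key = _pair_key(x, h)
                if key not in pairs:
                    pairs[key] = "diagonal"
    return NeighborGraph(pairs, "geometric")


def _count_hbond_contacts(si: ChromophoreSite, sj: ChromophoreSite, rmax: float) -> int:
    n = 0
    for a, b in ((si, sj), (sj, si)):
        donors = [x for x in HBOND_DONORS[a.base_type] if x in a._coord_index]
        accs = [x for x in HBOND_ACCEPTORS[b.base_type] if x in b._coord_index]
        if not donors or not accs:
            continue
        dmat = np.linalg.norm(
            a.coords(donors)[:, None, :] - b.coords(accs)[None, :, :], axis=2
        )
        n += int((dmat < rmax).sum())
    return n


# ---------------------------------------------------------------------------
# Interface overlap totals
# ---------------------------------------------------------------------------

def interface_overlap_totals(
    sites: list[ChromophoreSite],
    graph: NeighborGraph,
    tetrad_assignment: dict[int, int],
    structure_id: str = "",
) -> OverlapReport:
    """Sum stacked-pair overlap areas per adjacent-tetrad interface.

    ``tetrad_assignment`` maps site_id -> tetrad index.  Also reports the
    per-pair areas and COM distances for every pair in the graph.
    """
    by_id = {s.site_id: s for s in sites}
    missing = [i for i in {x for p in graph.pairs for x in p} if i not in tetrad_assignment]
    if missing:
        raise StructureError(f"tetrad assignment missing sites {sorted(missing)}")

    per_area: dict[tuple[int, int], float] = {}
    totals: dict[tuple[int, int], float] = {}
    per_dist: dict[tuple[int, int], float] = {}
    for (i, j), cls in sorted(graph.pairs.items()):
        per_dist[(i, j)] = com_distance(by_id[i], by_id[j])
        if cls != "stacked":
            continue
        ta, tb = sorted((tetrad_assignment[i], tetrad_assignment[j]))
        if tb - ta != 1:
            raise StructureError(
                f"stacked pair ({i},{j}) spans non-adjacent tetrads {ta},{tb}"
            )
        area = stacking_overlap_area(by_id[i], by_id[j])
        per_area[(i, j)] = area
        totals[(ta, tb)] = totals.get((ta, tb), 0.0) + area
    return OverlapReport(per_area, totals, per_dist, structure_id)


# ---------------------------------------------------------------------------
# Topology file I/O
# ---------------------------------------------------------------------------

def load_topology(path) -> dict:
    with open(path) as fh:
        topo = json.load(fh)
    if "tetrads" not in topo:
        raise StructureError("topology file lacks a 'tetrads' entry")
    return topo


def save_topology(topology: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(topology, fh, indent=1)
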