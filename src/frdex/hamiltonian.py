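"""Assembly of the excitonic Hamiltonian.

Two flavours are built on the same basis machinery:

* the fragment-diabatization Hamiltonian (LE + CT basis), assembled from
  intra-molecular parameters and diabatized nearest-neighbour pair blocks
  over a neighbour graph — H = H_intra + H_inter;
* the Frenkel/Coulombic baseline (FHC): LE-only, isolated-monomer site
  energies, electrostatic couplings (point-dipole or atomic transition
  charges), with no nearest-neighbour restriction.

Units: Hamiltonian in eV, dipoles in a.u., positions in Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM_BOHR, HARTREE_EV
from .diabatization import IntraParams, PairBlock, StateLabel
from .sites import ChromophoreSite, STANDARD_BASE_FRAMES
from .structure import NeighborGraph, kabsch_superpose

__all__ = [
    "ExcitonBasis",
    "ExcitonHamiltonian",
    "point_dipole_coupling",
    "transition_charge_coupling",
    "site_le_properties",
    "assemble_frdex",
    "assemble_fhc",
]

#: pair classes whose CT states enter the basis, per policy
CT_POLICIES = {
    "all": ("stacked", "hbonded", "diagonal"),
    "stacked": ("stacked",),
    "none": (),
}


@dataclass
class ExcitonBasis:
    """Ordered LE + CT basis labels.

    LE labels come first, ordered by (site, alpha); CT labels follow,
    ordered by (donor, acceptor, gamma).  The ordering is deterministic so
    eigenvector files are comparable across runs.
    """

    labels: list[StateLabel]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("basis-label collision")
        kinds = [l.kind for l in self.labels]
        if "CT" in kinds and "LE" in kinds[kinds.index("CT"):]:
            raise ValueError("LE block must precede CT block")

    @classmethod
    def build(cls, le_sites, alphas, ct_pairs, n_ct_per_direction):
        labels = [
            StateLabel("LE", site=s, alpha=a) for s in sorted(le_sites) for a in alphas
        ]
        ct = []
        for i, j in ct_pairs:
            for d, a in ((i, j), (j, i)):
                for g in range(n_ct_per_direction):
                    ct.append(StateLabel("CT", donor=d, acceptor=a, gamma=g))
        ct.sort(key=lambda l: (l.donor, l.acceptor, l.gamma))
        return cls(labels + ct)

    def __len__(self):
        return len(self.labels)

    def index(self, label: StateLabel) -> int:
        return self.labels.index(label)

    @property
    def n_le(self) -> int:
        return sum(1 for l in self.labels if l.kind == "LE")

    @property
    def le_slice(self) -> slice:
        return slice(0, self.n_le)

    @property
    def ct_slice(self) -> slice:
        return slice(self.n_le, len(self.labels))


@dataclass
class ExcitonHamiltonian:
    """Excitonic Hamiltonian with the geometric/optical data spectra need."""

    basis: ExcitonBasis
    H: np.ndarray                     # (n, n), eV, symmetric
    state_positions: np.ndarray       # (n, 3), Angstrom
    state_elec_tdip: np.ndarray       # (n, 3), a.u.
    state_mag_tdip: np.ndarray        # (n, 3), a.u. (imaginary part)
    site_positions: dict[int, np.ndarray] = field(default_factory=dict)
    elec_gauge: str = "velocity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.basis)
        if self.H.shape != (n, n):
            raise ValueError("Hamiltonian dimension does not match basis")
        if np.max(np.abs(self.H - self.H.T)) > 1e-10:
            raise ValueError("Hamiltonian must be symmetric to 1e-10")

    @property
    def dim(self) -> int:
        return len(self.basis)

    def to_json(self, path) -> None:
        data = {
            "labels": [repr(l) for l in self.basis.labels],
            "H_eV": self.H.tolist(),
            "state_positions_A": self.state_positions.tolist(),
            "state_elec_tdip_au": self.state_elec_tdip.tolist(),
            "state_mag_tdip_au": self.state_mag_tdip.tolist(),
            "elec_gauge": self.elec_gauge,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)


# ---------------------------------------------------------------------------
# Coulombic couplings
# ---------------------------------------------------------------------------

def point_dipole_coupling(mu_i, r_i, mu_j, r_j) -> float:
    """Point-dipole coupling in eV (dipoles a.u., positions Angstrom)."""
    mu_i, mu_j = np.asarray(mu_i, float), np.asarray(mu_j, float)
    dr = (np.asarray(r_j, float) - np.asarray(r_i, float)) * ANGSTROM_BOHR
    R = np.linalg.norm(dr)
    if R < 1e-9:
        raise ValueError("zero separation between dipole centres")
    n = dr / R
    V_au = (mu_i @ mu_j - 3.0 * (mu_i @ n) * (mu_j @ n)) / R**3
    return float(V_au * HARTREE_EV)


def transition_charge_coupling(charges_i, coords_i, charges_j, coords_j) -> float:
    """Coulomb coupling between atomic transition charges, in eV.

    Charges in e, coordinates in Angstrom.  A discretized stand-in for the
    transition-density Coulomb integral.
    """
    qi = np.asarray(charges_i, float)
    qj = np.asarray(charges_j, float)
    ri = np.asarray(coords_i, float) * ANGSTROM_BOHR
    rj = np.asarray(coords_j, float) * ANGSTROM_BOHR
    if qi.size == 0 or qj.size == 0:
        raise ValueError("empty charge set")
    d = np.linalg.norm(ri[:, None, :] - rj[None, :, :], axis=2)
    if np.min(d) < 1e-6:
        raise ValueError("coincident atoms across sites")
    return float((qi[:, None] * qj[None, :] / d).sum() * HARTREE_EV)


# ---------------------------------------------------------------------------
# Per-site LE properties in the lab frame
# ---------------------------------------------------------------------------

def site_le_properties(site: ChromophoreSite) -> dict[str, dict]:
    """Monomer LE data posed in the site's lab frame.

    Electric dipoles are rebuilt from the atomic transition charges at the
    site's actual atom positions (mu = sum q_a r_a, origin-free since the
    charges sum to zero); magnetic dipoles are rotated by the rigid
    transform from the standard base frame to the site pose.
    """
    md = site.monomer_data
    if md is None:
        raise ValueError(f"site {site.residue_label} has no monomer data")
    template = STANDARD_BASE_FRAMES[site.base_type]
    common = [a.name for a in site.atoms if a.name in template]
    R, _, _ = kabsch_superpose(
        np.array([template[n] for n in common]), site.coords(common)
    )
    out = {}
    for alpha, st in md.states.items():
        names = [n for n in st["charges"] if n in site._coord_index]
        q = np.array([st["charges"][n] for n in names])
        xyz = site.coords(names)
        mu = (q[:, None] * xyz * ANGSTROM_BOHR).sum(axis=0)
        out[alpha] = {
            "energy_ev": st["energy_ev"],
            "elec_tdip": mu,
            "mag_tdip": R @ np.asarray(st["mag_tdip"], float),
            "charges": q,
            "charge_coords": xyz,
        }
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_frdex(
    sites: list[ChromophoreSite],
    graph: NeighborGraph,
    intra: IntraParams,
    pairs: dict[tuple[int, int], PairBlock],
    ct_policy: str = "all",
    n_ct_per_direction: int | None = None,
) -> ExcitonHamiltonian:
    """Assemble the full LE+CT Hamiltonian from intra parameters and pair
    blocks over the neighbour graph.

    The diagonal carries the intra-molecular LE energies and the
    diabatized CT energies; off-diagonals come from the pair blocks
    (cross-site LE-LE, LE-CT and CT-CT) and the same-site La-Lb intra
    couplings.  Couplings between non-neighbour sites are exactly zero.
    """
    by_id = {s.site_id: s for s in sites}
    site_ids = sorted(by_id)
    missing = [p for p in graph.pairs if p not in pairs]
    if missing:
        raise ValueError(f"missing pair blocks for graph pairs {missing}")
    for s in site_ids:
        if not any((s, a) in intra.energies for a in intra.alphas()):
            raise ValueError(f"intra parameters missing site {s}")

    classes = CT_POLICIES[ct_policy]
    ct_pairs = sorted(p for p, c in graph.pairs.items() if c in classes)
    if n_ct_per_direction is None:
        n_ct_per_direction = (
            pairs[ct_pairs[0]].n_ct_per_direction if ct_pairs else 0
        )
    alphas = intra.alphas()
    basis = ExcitonBasis.build(site_ids, alphas, ct_pairs, n_ct_per_direction)
    n = len(basis)
    idx = {l: i for i, l in enumerate(basis.labels)}

    H = np.zeros((n, n))
    pos = np.zeros((n, 3))
    mu = np.zeros((n, 3))
    mg = np.zeros((n, 3))
    coms = {s: by_id[s].com for s in site_ids}

    # H_intra: LE energies and same-site La-Lb couplings
    for s in site_ids:
        le = [StateLabel("LE", site=s, alpha=a) for a in alphas]
        for l in le:
            H[idx[l], idx[l]] = intra.energies[(l.site, l.alpha)]
            pos[idx[l]] = coms[s]
        v = intra.la_lb_coupling.get(s, 0.0)
        for i, a in enumerate(le):
            for b in le[i + 1:]:
                H[idx[a], idx[b]] = H[idx[b], idx[a]] = v

    # H_inter from pair blocks; LE dipoles averaged over the blocks that
    # contain them, CT dipoles taken from their own block.
    mu_acc: dict[StateLabel, list[np.ndarray]] = {}
    mg_acc: dict[StateLabel, list[np.ndarray]] = {}
    for key in sorted(graph.pairs):
        pb = pairs[key]
        with_ct = key in ct_pairs
        block_labels = [
            l for l in pb.labels if l.kind == "LE" or (with_ct and l.gamma < n_ct_per_direction)
        ]
        for i, a in enumerate(block_labels):
            if a.kind == "CT":
                H[idx[a], idx[a]] = pb.energy(a)
                pos[idx[a]] = 0.5 * (coms[a.donor] + coms[a.acceptor])
                mu[idx[a]] = pb.elec_tdip(a)
                mg[idx[a]] = pb.mag_tdip(a)
            else:
                mu_acc.setdefault(a, []).append(pb.elec_tdip(a))
                mg_acc.setdefault(a, []).append(pb.mag_tdip(a))
            for b in block_labels[:i]:
                if a.kind == "LE" and b.kind == "LE":
                    if a.site == b.site:
                        continue  # same-site couplings come from H_intra
                    v = pb.coupling(a, b)
                else:
                    v = pb.coupling(a, b)
                H[idx[a], idx[b]] = H[idx[b], idx[a]] = v
    for l, vals in mu_acc.items():
        mu[idx[l]] = np.mean(vals, axis=0)
    for l, vals in mg_acc.items():
        mg[idx[l]] = np.mean(vals, axis=0)

    gauge = next(iter(pairs.values())).result.elec_gauge if pairs else "velocity"
    return ExcitonHamiltonian(
        basis=basis, H=H, state_positions=pos,
        state_elec_tdip=mu, state_mag_tdip=mg,
        site_positions=coms, elec_gauge=gauge,
        meta={
            "model": "frdex",
            "intra_mode": intra.provenance,
            "ct_policy": ct_policy,
            "n_ct_per_direction": n_ct_per_direction,
        },
    )


def assemble_fhc(
    sites: list[ChromophoreSite],
    graph: NeighborGraph | None = None,
    method: str = "charges",
    all_pairs: bool = True,
) -> ExcitonHamiltonian:
    """Frenkel Hamiltonian with Coulombic couplings (LE-only baseline).

    Site energies are the isolated-monomer LE energies; couplings are
    Coulombic (point-dipole or transition-charge).  By default every pair
    is coupled (the Coulomb interaction is long-range); pass a graph with
    ``all_pairs=False`` to truncate to the same connectivity as the
    diabatized model for controlled comparisons.
    """
    if method not in ("dipole", "charges"):
        raise ValueError(f"unknown coupling method {method!r}")
    props = {s.site_id: site_le_properties(s) for s in sites}
    site_ids = sorted(props)
    alphas = sorted(
        {a for p in props.values() for a in p},
        key=lambda a: {"La": 0, "Lb": 1}.get(a, 99),
    )
    basis = ExcitonBasis.build(site_ids, alphas, [], 0)
    n = len(basis)
    idx = {l: i for i, l in enumerate(basis.labels)}
    coms = {s.site_id: s.com for s in sites}

    H = np.zeros((n, n))
    pos = np.zeros((n, 3))
    mu = np.zeros((n, 3))
    mg = np.zeros((n, 3))
    for l in basis.labels:
        p = props[l.site][l.alpha]
        H[idx[l], idx[l]] = p["energy_ev"]
        pos[idx[l]] = coms[l.site]
        mu[idx[l]] = p["elec_tdip"]
        mg[idx[l]] = p["mag_tdip"]

    if all_pairs or graph is None:
        coupled = [
            (a, b) for i, a in enumerate(site_ids) for b in site_ids[i + 1:]
        ]
    else:
        coupled = sorted(graph.pairs)
    for si, sj in coupled:
        for a in alphas:
            for b in alphas:
                la = StateLabel("LE", site=si, alpha=a)
                lb = StateLabel("LE", site=sj, alpha=b)
                pa, pb_ = props[si][a], props[sj][b]
                if method == "dipole":
                    v = point_dipole_coupling(
                        pa["elec_tdip"], coms[si], pb_["elec_tdip"], coms[sj]
                    )
                else:
                    v = transition_charge_coupling(
                        pa["charges"], pa["charge_coords"],
                        pb_["charges"], pb_["charge_coords"],
                    )
                H[idx[la], idx[lb]] = H[idx[lb], idx[la]] = v

    gauge = sites[0].monomer_data.elec_gauge if sites[0].monomer_data else "velocity"
    return ExcitonHamiltonian(
        basis=basis, H=H, state_positions=pos,
        state_elec_tdip=mu, state_mag_tdip=mg,
        site_positions=coms, elec_gauge=gauge,
        meta={"model": "fhc", "coupling_method": method, "all_pairs": bool(all_pairs or graph is None)},
    )
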