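"""Synthetic parametrization generator.

Stands in for the quantum-chemistry upstream so the whole pipeline is
testable offline: builds idealized guanine-tetrad stacks with controllable
helical parameters (rise / twist / slide), monomer transition data with
atomic transition charges, and — crucially — internally consistent
adiabatic datasets derived from a known "true" diabatic Hamiltonian, so
that diabatization is verifiable by exact parameter recovery.

None of the generated energies or dipoles are quantum-chemistry results;
they are documented, physically plausible placeholders.  The CT energy
model is deliberately simple — linear in the donor-acceptor distance,
eps_CT(R) = e0 + c (R - R0) with c > 0 — so stacking-distance series
reproduce, qualitatively, the mechanism linking tetrad overlap to CT
involvement at the bottom of the exciton bands.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .constants import ANGSTROM_BOHR
from .diabatization import AdiabaticSet, ReferenceOverlap, StateLabel
from .hamiltonian import site_le_properties, transition_charge_coupling
from .sites import (
    ChromophoreSite,
    MonomerTransitionData,
    STANDARD_BASE_FRAMES,
    make_site,
)
from .structure import NeighborGraph, classify_neighbors, com_distance

__all__ = [
    "GeneratorSpec",
    "make_monomer_data",
    "make_ideal_stack",
    "make_dimer_stack",
    "make_md_like_series",
    "pair_true_hamiltonian",
    "make_consistent_sc",
    "contaminated_sc",
    "make_pair_dataset",
    "make_strand_sc",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic world; same spec + seed => identical output.

    Geometry: ``n_tetrads`` stacked G-tetrads related by ``rise`` (Angstrom),
    ``twist`` (degrees) and ``slide`` (Angstrom); noise_* are MD-like
    perturbation amplitudes.  Electronic settings: the two guanine pi-pi*
    LE energies (eV), in-plane dipole magnitudes (a.u.) and directions
    (degrees from the base-frame x axis), and the CT ladder parameters
    (eV, eV/Angstrom).
    """

    seed: int = 0
    n_tetrads: int = 3
    rise: float = 3.4
    twist: float = 30.0
    slide: float = 0.0
    # LE settings
    eps_la: float = 4.95
    eps_lb: float = 5.25
    mu_la: float = 1.1
    mu_lb: float = 0.75
    angle_la_deg: float = 35.0
    angle_lb_deg: float = 125.0
    mag_la: float = 0.0
    mag_lb: float = 0.0
    la_lb_intra_coupling: float = 0.02
    # CT model
    ct_e0: float = 5.6
    ct_slope: float = 0.5
    ct_r0: float = 3.4
    ct_gamma_spacing: float = 0.3
    ct_far_energy: float = 7.5
    le_ct_v0: float = 0.12
    le_ct_decay: float = 0.8
    ct_ct_same: float = 0.05
    ct_ct_opp: float = 0.03
    ct_dipole: float = 0.08
    # MD-like noise amplitudes
    noise_rise: float = 0.0
    noise_twist: float = 0.0
    noise_slide: float = 0.0
    noise_jitter: float = 0.0

    def __post_init__(self):
        for name in ("noise_rise", "noise_twist", "noise_slide", "noise_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


# ---------------------------------------------------------------------------
# Monomer data
# ---------------------------------------------------------------------------

def _transition_charges(frame: dict[str, np.ndarray], mu_au: np.ndarray):
    """Minimal-norm atomic charges with sum 0 reproducing the dipole.

    Solves q = X^T (X X^T)^-1 b with X = [1; x; y; z] (bohr) and
    b = (0, mu); exact by construction.
    """
    names = list(frame)
    r = np.array([frame[n] for n in names]) * ANGSTROM_BOHR
    X = np.vstack([np.ones(len(names)), r.T])       # (4, N)
    b = np.concatenate([[0.0], mu_au])
    # a planar base cannot carry an out-of-plane moment: drop degenerate rows
    keep = np.ptp(X, axis=1) > 1e-9
    keep[0] = True
    if np.any(np.abs(b[~keep]) > 1e-12):
        raise ValueError("dipole has a component the atom plane cannot represent")
    X, b = X[keep], b[keep]
    q = X.T @ np.linalg.solve(X @ X.T, b)
    return dict(zip(names, q))


def make_monomer_data(spec: GeneratorSpec, base_type: str = "G") -> MonomerTransitionData:
    """Guanine La/Lb monomer data in the standard base frame."""
    frame = STANDARD_BASE_FRAMES[base_type]
    states = {}
    for alpha, e, mu, ang, mag in (
        ("La", spec.eps_la, spec.mu_la, spec.angle_la_deg, spec.mag_la),
        ("Lb", spec.eps_lb, spec.mu_lb, spec.angle_lb_deg, spec.mag_lb),
    ):
        t = np.radians(ang)
        mu_vec = mu * np.array([np.cos(t), np.sin(t), 0.0])
        states[alpha] = {
            "energy_ev": e,
            "elec_tdip": mu_vec,
            "mag_tdip": np.array([0.0, 0.0, mag]),
            "charges": _transition_charges(frame, mu_vec),
        }
    md = MonomerTransitionData(base_type=base_type, states=states)
    md.validate()
    return md


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _rz(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


@functools.lru_cache(maxsize=1)
def _tetrad_pose() -> tuple[float, float, float]:
    """Pose (phi, dx, dy) of one guanine within a C4-symmetric tetrad.

    Solved once by least squares against Hoogsteen geometry targets: the
    N1 -> O6 and N2 -> N7 hydrogen bonds to the 90-degree-rotated neighbour
    at 2.9 Angstrom, with O6 2.3 Angstrom from the central axis (the
    cation-coordination distance).
    """
    G = STANDARD_BASE_FRAMES["G"]

    def posed(p):
        phi, dx, dy = p
        R = _rz(phi)
        return {k: R @ v + np.array([dx, dy, 0.0]) for k, v in G.items()}

    R90 = _rz(90.0)

    def resid(p):
        b0 = posed(p)
        b1 = {k: R90 @ v for k, v in b0.items()}
        return [
            np.linalg.norm(b0["N1"] - b1["O6"]) - 2.90,
            np.linalg.norm(b0["N2"] - b1["N7"]) - 2.90,
            np.linalg.norm(b0["O6"][:2]) - 2.30,
        ]

    best = None
    for phi0 in (0.0, 90.0, 180.0, 270.0):
        sol = least_squares(resid, x0=[phi0, 0.0, -2.0], xtol=1e-14, ftol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    return tuple(best.x)


def _build_stack(
    spec: GeneratorSpec,
    rises: np.ndarray,
    twists: np.ndarray,
    slides: np.ndarray,
    rng: np.random.Generator | None = None,
) -> list[ChromophoreSite]:
    """Stack of tetrads with per-interface helical parameters."""
    phi, dx, dy = _tetrad_pose()
    G = STANDARD_BASE_FRAMES["G"]
    base0 = {k: _rz(phi) @ v + np.array([dx, dy, 0.0]) for k, v in G.items()}
    md = make_monomer_data(spec)

    sites = []
    z, tw, sl = 0.0, 0.0, 0.0
    for t in range(spec.n_tetrads):
        if t > 0:
            z += rises[t - 1]
            tw += twists[t - 1]
            sl += slides[t - 1]
        for k in range(4):
            R = _rz(tw) @ _rz(90.0 * k)
            coords = {
                name: R @ (v + np.array([sl, 0.0, 0.0])) + np.array([0.0, 0.0, z])
                for name, v in base0.items()
            }
            if rng is not None and spec.noise_jitter > 0:
                c = np.mean(list(coords.values()), axis=0)
                Rj = Rotation.from_rotvec(
                    rng.normal(0.0, np.radians(spec.noise_jitter * 2.0), 3)
                ).as_matrix()
                tj = rng.normal(0.0, spec.noise_jitter, 3)
                coords = {n: Rj @ (v - c) + c + tj for n, v in coords.items()}
            sid = 4 * t + k
            sites.append(
                make_site(sid, "G", coords, residue_label=f"G{sid + 1}",
                          monomer_data=md)
            )
    return sites


def stack_topology(n_tetrads: int, n_per_tetrad: int = 4) -> dict:
    """Topology of an aligned tetrad stack: cyclic tetrads, vertical strands."""
    return {
        "tetrads": [
            [n_per_tetrad * t + k for k in range(n_per_tetrad)]
            for t in range(n_tetrads)
        ],
        "strands": [
            [n_per_tetrad * t + k for t in range(n_tetrads)]
            for k in range(n_per_tetrad)
        ],
        "loops": [],
    }


def make_ideal_stack(spec: GeneratorSpec):
    """Idealized tetrad stack -> (sites, NeighborGraph, topology dict)."""
    n = spec.n_tetrads
    rises = np.full(max(n - 1, 0), spec.rise)
    twists = np.full(max(n - 1, 0), spec.twist)
    slides = np.full(max(n - 1, 0), spec.slide)
    sites = _build_stack(spec, rises, twists, slides)
    topo = stack_topology(n)
    graph = classify_neighbors(sites, topology=topo)
    return sites, graph, topo


def make_dimer_stack(spec: GeneratorSpec, interface_rise: float | None = None):
    """Two tetrad stacks joined tail-to-tail at a 5'-5'-like interface.

    The second unit is flipped (180 degrees about x) and stacked below the
    first, emulating a dimer of two quadruplex subunits; with the default
    three tetrads per unit this yields 24 guanines.
    """
    sites_a, _, _ = make_ideal_stack(spec)
    sites_b, _, _ = make_ideal_stack(spec)
    gap = interface_rise if interface_rise is not None else spec.rise
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    shift = np.array([0.0, 0.0, -gap])
    out = list(sites_a)
    for s in sites_b:
        xyz = s.coords() @ flip.T + shift
        s2 = s.with_coords(xyz)
        s2.site_id = len(out)
        s2.residue_label = f"G{len(out) + 1}"
        out.append(s2)
    return out


def make_md_like_series(spec: GeneratorSpec, n_snapshots: int):
    """Seeded MD-like snapshot series.

    Per snapshot, the per-interface rise/twist/slide drift around the
    ideal values and each base gets a small rigid jitter; with all noise
    amplitudes zero every snapshot equals the ideal stack.  Returns a list
    of (sites, graph, topology) triples.
    """
    if n_snapshots < 1:
        raise ValueError("n_snapshots must be >= 1")
    rng = np.random.default_rng(spec.seed)
    topo = stack_topology(spec.n_tetrads)
    ni = max(spec.n_tetrads - 1, 0)
    out = []
    for _ in range(n_snapshots):
        rises = spec.rise + spec.noise_rise * rng.standard_normal(ni)
        rises = np.clip(rises, 0.3 * spec.rise, None)
        twists = spec.twist + spec.noise_twist * rng.standard_normal(ni)
        slides = spec.slide + spec.noise_slide * rng.standard_normal(ni)
        sites = _build_stack(spec, rises, twists, slides, rng=rng)
        graph = classify_neighbors(sites, topology=topo)
        out.append((sites, graph, topo))
    return out


# ---------------------------------------------------------------------------
# The "true" diabatic model and consistent adiabatic data
# ---------------------------------------------------------------------------

def pair_labels(m: int, n: int, n_ct_per_direction: int) -> list[StateLabel]:
    labels = [StateLabel("LE", site=s, alpha=a) for s in (m, n) for a in ("La", "Lb")]
    for d, a in ((m, n), (n, m)):
        for g in range(n_ct_per_direction):
            labels.append(StateLabel("CT", donor=d, acceptor=a, gamma=g))
    return labels


def pair_true_hamiltonian(
    site_m: ChromophoreSite,
    site_n: ChromophoreSite,
    pair_class: str,
    spec: GeneratorSpec,
    n_ct_per_direction: int = 2,
):
    """The generator's ground-truth diabatic pair Hamiltonian + properties.

    LE-LE couplings are genuine transition-charge Coulomb couplings at the
    actual geometry; CT energies follow the linear distance model (only
    stacked pairs have low-lying CT states); LE-CT couplings decay
    exponentially with the stacking distance.  Returns
    (labels, H_true (eV), elec_tdip (a.u.), mag_tdip (a.u.)).
    """
    m, n = site_m.site_id, site_n.site_id
    labels = pair_labels(m, n, n_ct_per_direction)
    nb = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    H = np.zeros((nb, nb))
    elec = np.zeros((nb, 3))
    mag = np.zeros((nb, 3))

    props = {m: site_le_properties(site_m), n: site_le_properties(site_n)}
    coms = {m: site_m.com, n: site_n.com}
    R = com_distance(site_m, site_n)

    for l in labels:
        if l.kind == "LE":
            p = props[l.site][l.alpha]
            H[idx[l], idx[l]] = p["energy_ev"]
            elec[idx[l]] = p["elec_tdip"]
            mag[idx[l]] = p["mag_tdip"]
        else:
            if pair_class == "stacked":
                e = spec.ct_e0 + spec.ct_slope * (R - spec.ct_r0)
            else:
                e = spec.ct_far_energy
            H[idx[l], idx[l]] = e + spec.ct_gamma_spacing * l.gamma
            u = coms[l.acceptor] - coms[l.donor]
            elec[idx[l]] = spec.ct_dipole * u / np.linalg.norm(u)

    # same-site La-Lb (environment-induced) coupling
    for s in (m, n):
        a, b = idx[StateLabel("LE", site=s, alpha="La")], idx[StateLabel("LE", site=s, alpha="Lb")]
        H[a, b] = H[b, a] = spec.la_lb_intra_coupling

    # cross-site LE-LE: Coulombic
    for aa in ("La", "Lb"):
        for bb in ("La", "Lb"):
            i = idx[StateLabel("LE", site=m, alpha=aa)]
            j = idx[StateLabel("LE", site=n, alpha=bb)]
            pa, pb = props[m][aa], props[n][bb]
            H[i, j] = H[j, i] = transition_charge_coupling(
                pa["charges"], pa["charge_coords"], pb["charges"], pb["charge_coords"]
            )

    # LE-CT couplings: distance-decaying, scaled per alpha / gamma / side
    v_base = spec.le_ct_v0 * np.exp(-(R - spec.ct_r0) / spec.le_ct_decay)
    if pair_class != "stacked":
        v_base *= 0.2
    for l in labels:
        if l.kind != "CT":
            continue
        j = idx[l]
        for s in (m, n):
            for ai, aa in enumerate(("La", "Lb")):
                i = idx[StateLabel("LE", site=s, alpha=aa)]
                side = 1.0 if s == l.donor else 0.8   # hole- vs electron-side
                v = v_base * side * (0.6 ** ai) * (0.7 ** l.gamma)
                H[i, j] = H[j, i] = v

    # CT-CT couplings
    cts = [l for l in labels if l.kind == "CT"]
    for i, a in enumerate(cts):
        for b in cts[:i]:
            same_dir = (a.donor, a.acceptor) == (b.donor, b.acceptor)
            v = spec.ct_ct_same if same_dir else spec.ct_ct_opp
            H[idx[a], idx[b]] = H[idx[b], idx[a]] = v

    return labels, H, elec, mag


def make_consistent_sc(
    H_true: np.ndarray,
    labels: list[StateLabel],
    elec_true: np.ndarray,
    mag_true: np.ndarray,
    n_adiabatic: int | None = None,
    sc_id: str = "sc",
):
    """Adiabatic data exactly consistent with a known diabatic model.

    Diagonalizes H_true; the overlap of the (reference = diabatic) states
    with the adiabatic states is the eigenvector matrix itself, so an
    untruncated diabatization recovers H_true to machine precision.
    ``n_adiabatic`` keeps only the lowest adiabatic states (truncation).
    """
    H_true = np.asarray(H_true, float)
    if np.max(np.abs(H_true - H_true.T)) > 1e-10:
        raise ValueError("H_true must be symmetric")
    w, V = np.linalg.eigh(H_true)
    keep = len(w) if n_adiabatic is None else int(n_adiabatic)
    if not 1 <= keep <= len(w):
        raise ValueError("n_adiabatic out of range")
    S = V[:, :keep]
    overlap = ReferenceOverlap(labels=list(labels), S=S)
    adiabatic = AdiabaticSet(
        sc_id=sc_id,
        energies=w[:keep],
        elec_tdip=(V.T @ np.asarray(elec_true, float))[:keep],
        mag_tdip=(V.T @ np.asarray(mag_true, float))[:keep],
    )
    return overlap, adiabatic


def contaminated_sc(
    H_true: np.ndarray,
    labels: list[StateLabel],
    elec_true: np.ndarray,
    mag_true: np.ndarray,
    n_spectators: int,
    mixing_angle: float,
    seed: int,
    spectator_offset: float = 3.0,
):
    """Adiabatic data whose states mix with out-of-reference spectators.

    Each true adiabatic state is rotated by ``mixing_angle`` (radians)
    towards a random high-lying spectator state outside the reference
    space, degrading the projection completeness; recovery error grows
    with the angle.
    """
    rng = np.random.default_rng(seed)
    w, V = np.linalg.eigh(np.asarray(H_true, float))
    nd = len(w)
    S = np.zeros((nd, nd + n_spectators))
    S[:, :nd] = V
    energies = np.concatenate([w, w.max() + spectator_offset * (1 + np.arange(n_spectators))])
    # rotate each kept adiabatic state towards a random spectator
    c, s = np.cos(mixing_angle), np.sin(mixing_angle)
    for a in range(nd):
        b = nd + int(rng.integers(n_spectators))
        col_a, col_b = S[:, a].copy(), S[:, b].copy()
        S[:, a] = c * col_a + s * col_b     # exact Givens rotation: columns of
        S[:, b] = -s * col_a + c * col_b    # the extended unitary stay orthonormal
    order = np.argsort(energies, kind="stable")
    S = S[:, order][:, :nd]
    energies = energies[order][:nd]
    elec = np.vstack([V.T @ elec_true, np.zeros((n_spectators, 3))])[order][:nd]
    mag = np.vstack([V.T @ mag_true, np.zeros((n_spectators, 3))])[order][:nd]
    return ReferenceOverlap(labels=list(labels), S=S), AdiabaticSet(
        sc_id="contaminated", energies=energies, elec_tdip=elec, mag_tdip=mag
    )


def make_pair_dataset(
    sites: list[ChromophoreSite],
    graph: NeighborGraph,
    spec: GeneratorSpec,
    n_ct_per_direction: int = 2,
    n_adiabatic: int | None = None,
    ct_energy_override: float | None = None,
):
    """Consistent (overlap, adiabatic) data for every graph pair.

    ``ct_energy_override`` replaces every CT diagonal energy (used for the
    decoupled-CT limit in which the model must collapse onto the Frenkel/
    Coulombic baseline).
    """
    by_id = {s.site_id: s for s in sites}
    out = {}
    for (i, j), cls in sorted(graph.pairs.items()):
        labels, H, elec, mag = pair_true_hamiltonian(
            by_id[i], by_id[j], cls, spec, n_ct_per_direction
        )
        if ct_energy_override is not None:
            for k, l in enumerate(labels):
                if l.kind == "CT":
                    H[k, k] = ct_energy_override
        out[(i, j)] = make_consistent_sc(
            H, labels, elec, mag, n_adiabatic, sc_id=f"pair_{i}_{j}"
        )
    return out


def make_strand_sc(
    sites: list[ChromophoreSite],
    strand: list[int],
    spec: GeneratorSpec,
):
    """LE-only supramolecular complex over one strand (for intra-mode
    parametrization): true Hamiltonian = monomer energies, same-site La-Lb
    couplings and Coulombic cross couplings over the strand."""
    by_id = {s.site_id: s for s in sites}
    labels = [StateLabel("LE", site=s, alpha=a) for s in strand for a in ("La", "Lb")]
    nb = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    H = np.zeros((nb, nb))
    elec = np.zeros((nb, 3))
    mag = np.zeros((nb, 3))
    props = {s: site_le_properties(by_id[s]) for s in strand}
    for l in labels:
        p = props[l.site][l.alpha]
        H[idx[l], idx[l]] = p["energy_ev"]
        elec[idx[l]] = p["elec_tdip"]
        mag[idx[l]] = p["mag_tdip"]
    for i, a in enumerate(labels):
        for b in labels[:i]:
            if a.site == b.site:
                H[idx[a], idx[b]] = H[idx[b], idx[a]] = spec.la_lb_intra_coupling
            else:
                pa, pb = props[a.site][a.alpha], props[b.site][b.alpha]
                H[idx[a], idx[b]] = H[idx[b], idx[a]] = transition_charge_coupling(
                    pa["charges"], pa["charge_coords"], pb["charges"], pb["charge_coords"]
                )
    return make_consistent_sc(H, labels, elec, mag, sc_id=f"strand_{strand}")
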