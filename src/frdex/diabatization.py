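"""Fragment diabatization: from adiabatic supramolecular-complex states to
diabatic local-excitation (LE) and charge-transfer (CT) states.

Given the overlap matrix S between reference fragment states and the
adiabatic states of a supramolecular complex (SC), the diabatizing
transform is the Loewdin / symmetric-orthogonalization solution

    D = S^T (S S^T)^(-1/2),

the column-orthonormal matrix closest to S^T in Frobenius norm.  The
diabatic Hamiltonian follows as H_d = D^T H_a D with H_a the diagonal
matrix of adiabatic energies; transition properties transform by the same
columns of D.  Pair SCs yield the inter-molecular Hamiltonian blocks
(LE-LE, LE-CT and CT-CT energies and couplings); pair averages or LE-only
strand/tetrad SCs yield the intra-molecular parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "StateLabel",
    "AdiabaticSet",
    "ReferenceOverlap",
    "DiabatizationResult",
    "PairBlock",
    "IntraParams",
    "RankDeficiencyError",
    "lowdin_transform",
    "diabatic_hamiltonian",
    "fix_phases",
    "transform_properties",
    "diabatize",
    "build_pair_block",
    "build_intra_params",
]

SVD_THRESHOLD = 1e-6
COMPLETENESS_WARN = 0.5


class RankDeficiencyError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class StateLabel:
    """Label of a reference diabatic state.

    LE states: ``StateLabel("LE", site=m, alpha="La")``.
    CT states: ``StateLabel("CT", donor=m, acceptor=n, gamma=g)`` for the
    g-th orbital-pair transition moving an electron m -> n.
    """

    kind: str
    site: int = -1
    alpha: str = ""
    donor: int = -1
    acceptor: int = -1
    gamma: int = -1

    def __post_init__(self):
        if self.kind not in ("LE", "CT"):
            raise ValueError(f"unknown state kind {self.kind!r}")

    def __repr__(self):
        if self.kind == "LE":
            return f"LE({self.site},{self.alpha})"
        return f"CT({self.donor}->{self.acceptor},{self.gamma})"


@dataclass
class AdiabaticSet:
    """Adiabatic states of one supramolecular complex (energies in eV,
    transition dipoles in a.u.)."""

    sc_id: str
    energies: np.ndarray
    elec_tdip: np.ndarray  # (n, 3)
    mag_tdip: np.ndarray   # (n, 3)
    elec_gauge: str = "velocity"

    def __post_init__(self):
        self.energies = np.asarray(self.energies, float)
        self.elec_tdip = np.asarray(self.elec_tdip, float)
        self.mag_tdip = np.asarray(self.mag_tdip, float)
        n = len(self.energies)
        if np.any(np.diff(self.energies) < -1e-12):
            raise ValueError("adiabatic energies must be sorted ascending")
        if self.elec_tdip.shape != (n, 3) or self.mag_tdip.shape != (n, 3):
            raise ValueError("property arrays must be (n_adiabatic, 3)")

    @property
    def n_adiabatic(self) -> int:
        return len(self.energies)


@dataclass
class ReferenceOverlap:
    """Overlap S = <R_frags | a_SC> of reference states with SC adiabats."""

    labels: list[StateLabel]
    S: np.ndarray  # (n_ref, n_adiabatic)

    def __post_init__(self):
        self.S = np.asarray(self.S, float)
        if self.S.ndim != 2 or self.S.shape[0] != len(self.labels):
            raise ValueError("S must be (n_ref, n_adiabatic) matching labels")
        if self.S.shape[0] > self.S.shape[1]:
            raise ValueError("more reference states than adiabatic states")

    @property
    def completeness(self) -> np.ndarray:
        """Row norms of S: how much of each reference state the adiabatic
        manifold captures (1 = fully contained)."""
        return np.linalg.norm(self.S, axis=1)


@dataclass
class DiabatizationResult:
    labels: list[StateLabel]
    D: np.ndarray           # (n_adiabatic, n_ref)
    H_d: np.ndarray         # (n_ref, n_ref), eV
    diab_elec_tdip: np.ndarray
    diab_mag_tdip: np.ndarray
    completeness: np.ndarray
    elec_gauge: str = "velocity"

    def index(self, label: StateLabel) -> int:
        return self.labels.index(label)

    def coupling(self, a: StateLabel, b: StateLabel) -> float:
        return float(self.H_d[self.index(a), self.index(b)])


def lowdin_transform(S: np.ndarray, svd_threshold: float = SVD_THRESHOLD,
                     labels: list[StateLabel] | None = None) -> np.ndarray:
    """D = S^T (S S^T)^(-1/2): the orthogonal Procrustes solution.

    Computed from the SVD S = U diag(s) V^T as D = V U^T, which is also
    the column-orthonormal matrix nearest S^T.  Singular values below
    ``svd_threshold`` indicate (near-)linearly-dependent or missing
    reference states and raise :class:`RankDeficiencyError` naming the
    offending reference combination.
    """
    S = np.asarray(S, float)
    U, s, Vh = np.linalg.svd(S, full_matrices=False)
    if s[-1] < svd_threshold:
        bad = np.argmax(np.abs(U[:, -1]))
        name = labels[bad] if labels else f"row {bad}"
        raise RankDeficiencyError(
            f"S S^T is rank deficient: smallest singular value {s[-1]:.3e} "
            f"(dominant reference state: {name})"
        )
    return Vh.T @ U.T


def diabatic_hamiltonian(D: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """H_d = D^T H_a D with H_a = diag(adiabatic energies)."""
    D = np.asarray(D, float)
    energies = np.asarray(energies, float)
    if D.shape[0] != len(energies):
        raise ValueError(
            f"shape mismatch: D has {D.shape[0]} adiabatic rows, "
            f"{len(energies)} energies given"
        )
    H = D.T @ (energies[:, None] * D)
    return 0.5 * (H + H.T)


def fix_phases(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the arbitrary sign of each adiabatic state.

    Each column of S is flipped so its largest-magnitude entry is positive
    (exact ties resolved by the lowest reference index, which is what
    ``argmax`` returns).  Returns ``(S_fixed, signs)``; the sign vector
    must also be applied to any adiabatic property vectors so that
    properties stay consistent with the flipped states.
    """
    S = np.asarray(S, float)
    idx = np.argmax(np.abs(S), axis=0)
    signs = np.where(S[idx, np.arange(S.shape[1])] < 0, -1.0, 1.0)
    return S * signs[None, :], signs


def transform_properties(D: np.ndarray, props: np.ndarray) -> np.ndarray:
    """Diabatic property vectors: prop_d[i] = sum_a D[a, i] * prop_a[a]."""
    D = np.asarray(D, float)
    props = np.asarray(props, float)
    if props.shape[0] != D.shape[0]:
        raise ValueError("one property vector per adiabatic state required")
    return D.T @ props


def diabatize(overlap: ReferenceOverlap, adiabatic: AdiabaticSet,
              svd_threshold: float = SVD_THRESHOLD) -> DiabatizationResult:
    """Full diabatization of one SC: phase fixing, Loewdin transform,
    diabatic Hamiltonian and transition properties."""
    if overlap.S.shape[1] != adiabatic.n_adiabatic:
        raise ValueError(
            f"S has {overlap.S.shape[1]} adiabatic columns but the adiabatic "
            f"set has {adiabatic.n_adiabatic} states"
        )
    comp = overlap.completeness
    low = [str(l) for l, c in zip(overlap.labels, comp) if c < COMPLETENESS_WARN]
    if low:
        warnings.warn(
            f"low diabatization completeness (<{COMPLETENESS_WARN}) for {low}"
        )
    S, signs = fix_phases(overlap.S)
    D = lowdin_transform(S, svd_threshold, overlap.labels)
    H_d = diabatic_hamiltonian(D, adiabatic.energies)
    mu = transform_properties(D, signs[:, None] * adiabatic.elec_tdip)
    m = transform_properties(D, signs[:, None] * adiabatic.mag_tdip)
    return DiabatizationResult(
        labels=list(overlap.labels), D=D, H_d=H_d,
        diab_elec_tdip=mu, diab_mag_tdip=m,
        completeness=comp, elec_gauge=adiabatic.elec_gauge,
    )


# ---------------------------------------------------------------------------
# Pair blocks and intra-molecular parameters
# ---------------------------------------------------------------------------

@dataclass
class PairBlock:
    """Diabatized energies/couplings of one nearest-neighbour pair.

    Houses every inter-molecular Hamiltonian symbol: per-site LE energies
    and same-site LE-LE couplings as seen in this pair, cross-site LE-LE
    couplings, CT energies for both directions, LE-CT couplings (hole- and
    electron-side) and CT-CT couplings (same and opposite direction), plus
    diabatic transition dipoles for every state.
    """

    site_m: int
    site_n: int
    result: DiabatizationResult
    n_ct_per_direction: int

    @property
    def labels(self) -> list[StateLabel]:
        return self.result.labels

    @property
    def le_labels(self) -> list[StateLabel]:
        return [l for l in self.labels if l.kind == "LE"]

    @property
    def ct_labels(self) -> list[StateLabel]:
        return [l for l in self.labels if l.kind == "CT"]

    def energy(self, label: StateLabel) -> float:
        return self.result.coupling(label, label)

    def coupling(self, a: StateLabel, b: StateLabel) -> float:
        return self.result.coupling(a, b)

    def elec_tdip(self, label: StateLabel) -> np.ndarray:
        return self.result.diab_elec_tdip[self.result.index(label)]

    def mag_tdip(self, label: StateLabel) -> np.ndarray:
        return self.result.diab_mag_tdip[self.result.index(label)]


def build_pair_block(
    overlap: ReferenceOverlap,
    adiabatic: AdiabaticSet,
    n_ct_per_direction: int,
    svd_threshold: float = SVD_THRESHOLD,
) -> PairBlock:
    """Diabatize one pair SC and wrap the result as a :class:`PairBlock`.

    The reference set must contain the LE states of both sites and
    ``n_ct_per_direction`` CT states in each direction (2 per direction for
    the minimal 4-CT setting, 6 for the 12-CT one); a CT-free reference set
    (``n_ct_per_direction=0``) yields an LE-only block.
    """
    le = [l for l in overlap.labels if l.kind == "LE"]
    ct = [l for l in overlap.labels if l.kind == "CT"]
    sites = sorted({l.site for l in le})
    if len(sites) != 2:
        raise ValueError(f"pair reference set must span 2 sites, got {sites}")
    m, n = sites
    for d, a in ((m, n), (n, m)):
        k = sum(1 for l in ct if l.donor == d and l.acceptor == a)
        if k != n_ct_per_direction:
            raise ValueError(
                f"expected {n_ct_per_direction} CT states {d}->{a}, found {k}"
            )
    result = diabatize(overlap, adiabatic, svd_threshold)
    return PairBlock(site_m=m, site_n=n, result=result,
                     n_ct_per_direction=n_ct_per_direction)


@dataclass
class IntraParams:
    """Per-site LE energies and same-site La-Lb couplings (eV)."""

    energies: dict[tuple[int, str], float]       # (site, alpha) -> eV
    la_lb_coupling: dict[int, float] = field(default_factory=dict)
    provenance: str = "monomer"

    def sites(self) -> list[int]:
        return sorted({s for s, _ in self.energies})

    def alphas(self) -> list[str]:
        order = {"La": 0, "Lb": 1}
        return sorted({a for _, a in self.energies}, key=lambda a: order.get(a, 99))


def build_intra_params(
    mode: str,
    pair_blocks: Iterable[PairBlock] | None = None,
    overlap: ReferenceOverlap | None = None,
    adiabatic: AdiabaticSet | None = None,
    update_couplings: bool = True,
) -> IntraParams:
    """Intra-molecular LE parameters from pairs or a larger LE-only SC.

    mode="pair_averaged": unweighted mean, over every pair block containing
    a site, of that site's LE energies and same-site La-Lb coupling.
    mode="strand"/"tetrad": diabatize an LE-only SC covering the sites and
    read the per-site energies (and couplings if ``update_couplings``)
    directly from its diabatic Hamiltonian.
    """
    if mode == "pair_averaged":
        if not pair_blocks:
            raise ValueError("pair_averaged mode needs pair blocks")
        acc_e: dict[tuple[int, str], list[float]] = {}
        acc_v: dict[int, list[float]] = {}
        for pb in pair_blocks:
            les = pb.le_labels
            for l in les:
                acc_e.setdefault((l.site, l.alpha), []).append(pb.energy(l))
            for site in (pb.site_m, pb.site_n):
                mine = [l for l in les if l.site == site]
                for i, a in enumerate(mine):
                    for b in mine[i + 1:]:
                        acc_v.setdefault(site, []).append(pb.coupling(a, b))
        return IntraParams(
            energies={k: float(np.mean(v)) for k, v in acc_e.items()},
            la_lb_coupling={k: float(np.mean(v)) for k, v in acc_v.items()},
            provenance="pair_averaged",
        )

    if mode in ("strand", "tetrad"):
        if overlap is None or adiabatic is None:
            raise ValueError(f"{mode} mode needs an overlap and adiabatic set")
        if any(l.kind != "LE" for l in overlap.labels):
            raise ValueError(f"{mode} reference set must be LE-only")
        res = diabatize(overlap, adiabatic)
        energies = {}
        coupl: dict[int, float] = {}
        for i, a in enumerate(res.labels):
            energies[(a.site, a.alpha)] = float(res.H_d[i, i])
            for j, b in enumerate(res.labels[:i]):
                if b.site == a.site:
                    coupl[a.site] = float(res.H_d[i, j])
        return IntraParams(
            energies=energies,
            la_lb_coupling=coupl if update_couplings else {},
            provenance=mode,
        )

    raise ValueError(f"unknown intra mode {mode!r}")
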