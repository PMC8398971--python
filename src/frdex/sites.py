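"""Chromophore sites: nucleobases reduced to their ring + exocyclic heavy atoms.

A G-quadruplex (or any stacked nucleic-acid assembly) is reduced to a list
of :class:`ChromophoreSite` objects — one per base, with the sugar/phosphate
backbone and ions stripped.  Each site optionally carries
:class:`MonomerTransitionData` describing its local excitations (for
guanine: the two pi-pi* states La and Lb).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ATOMIC_MASSES

# ---------------------------------------------------------------------------
# Base atom tables.  Stripping is done by atom-name whitelist per base type:
# the aromatic ring plus the exocyclic heavy atoms that carry transition
# density (O6/N2 for G, N6 for A, O2/O4/C7 for T).
# ---------------------------------------------------------------------------

BASE_RING_ATOMS = {
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

BASE_EXOCYCLIC_ATOMS = {
    "G": ("O6", "N2"),
    "A": ("N6",),
    "T": ("O2", "O4", "C7"),
}

#: full heavy-atom whitelist used when reading structures
BASE_HEAVY_ATOMS = {
    b: BASE_RING_ATOMS[b] + BASE_EXOCYCLIC_ATOMS[b] for b in BASE_RING_ATOMS
}

#: canonical renaming applied before any atom-name matching (PDB dialects)
ATOM_NAME_ALIASES = {"C5M": "C7", "C5A": "C7", "O1P": "OP1", "O2P": "OP2"}

#: Hoogsteen donor / acceptor heavy atoms used by geometric H-bond detection
HBOND_DONORS = {"G": ("N1", "N2"), "A": ("N6",), "T": ("N3",)}
HBOND_ACCEPTORS = {"G": ("O6", "N7", "N3"), "A": ("N7", "N1", "N3"), "T": ("O2", "O4")}

_RESNAME_TO_BASE = {
    "G": "G", "DG": "G", "GUA": "G", "DG3": "G", "DG5": "G", "RG": "G",
    "A": "A", "DA": "A", "ADE": "A", "DA3": "A", "DA5": "A", "RA": "A",
    "T": "T", "DT": "T", "THY": "T", "DT3": "T", "DT5": "T",
}

_ELEMENT_OF = {"N": "N", "C": "C", "O": "O"}


def base_type_of_resname(resname: str) -> str | None:
    """Map a PDB residue name to a base type, or ``None`` for non-bases."""
    return _RESNAME_TO_BASE.get(resname.strip().upper())


def canonical_atom_name(name: str) -> str:
    name = name.strip().upper()
    return ATOM_NAME_ALIASES.get(name, name)


# ---------------------------------------------------------------------------
# Idealized planar base geometries (standard base reference frame, z = 0;
# coordinates in Angstrom).  Used as templates when replacing MD-distorted
# bases by an optimized internal geometry, and by the synthetic generator.
# ---------------------------------------------------------------------------

STANDARD_BASE_FRAMES: dict[str, dict[str, np.ndarray]] = {
    "G": {
        "N9": (-1.289, 4.551, 0.0),
        "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0),
        "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0),
        "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0),
        "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0),
        "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
    },
    "A": {
        "N9": (-1.291, 4.498, 0.0),
        "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0),
        "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0),
        "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0),
        "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0),
        "C4": (-1.267, 3.124, 0.0),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.0),
        "C2": (-1.462, 3.135, 0.0),
        "O2": (-2.562, 2.608, 0.0),
        "N3": (-0.298, 2.407, 0.0),
        "C4": (0.994, 2.897, 0.0),
        "O4": (1.944, 2.119, 0.0),
        "C5": (1.106, 4.338, 0.0),
        "C7": (2.466, 4.961, 0.0),
        "C6": (-0.024, 5.057, 0.0),
    },
}
STANDARD_BASE_FRAMES = {
    b: {k: np.asarray(v, dtype=float) for k, v in d.items()}
    for b, d in STANDARD_BASE_FRAMES.items()
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))


@dataclass
class MonomerTransitionData:
    """Per-monomer local-excitation data in the base's standard frame.

    ``states`` maps an LE label (e.g. "La", "Lb") to a dict with keys
    ``energy_ev``, ``elec_tdip`` (3-vector, a.u.), ``mag_tdip`` (3-vector,
    a.u., imaginary part as a real vector) and ``charges`` (atom name ->
    transition charge, e).  ``elec_gauge`` records the provenance of the
    electric dipoles ("velocity" or "length").
    """

    base_type: str
    states: dict[str, dict]
    elec_gauge: str = "velocity"

    def validate(self, tol: float = 1e-6) -> None:
        for label, st in self.states.items():
            q = np.array(list(st["charges"].values()), dtype=float)
            if abs(q.sum()) > tol:
                raise ValueError(
                    f"transition charges of {label} sum to {q.sum():.2e}, not 0"
                )


@dataclass
class ChromophoreSite:
    """One nucleobase chromophore: identity, geometry and monomer data."""

    site_id: int
    residue_label: str
    base_type: str
    atoms: list[Atom]
    ring_atoms: tuple[str, ...]
    monomer_data: MonomerTransitionData | None = None
    _coord_index: dict[str, np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        names = {a.name for a in self.atoms}
        missing = [n for n in self.ring_atoms if n not in names]
        if missing:
            raise ValueError(
                f"site {self.residue_label}: ring atoms {missing} absent from atom list"
            )
        self._coord_index = {a.name: a.xyz for a in self.atoms}

    def coords(self, names=None) -> np.ndarray:
        """(N, 3) array of atom coordinates, optionally for named atoms."""
        if names is None:
            return np.array([a.xyz for a in self.atoms])
        return np.array([self._coord_index[n] for n in names])

    @property
    def com(self) -> np.ndarray:
        """Mass-weighted centre of the base heavy atoms (Angstrom)."""
        m = np.array([ATOMIC_MASSES.get(a.element, 12.0) for a in self.atoms])
        xyz = self.coords()
        return (m[:, None] * xyz).sum(axis=0) / m.sum()

    def with_coords(self, new_xyz: np.ndarray) -> "ChromophoreSite":
        atoms = [
            Atom(a.name, a.element, xyz) for a, xyz in zip(self.atoms, new_xyz)
        ]
        return replace(self, atoms=atoms, _coord_index=None)


def make_site(
    site_id: int,
    base_type: str,
    coords_by_name: dict[str, np.ndarray],
    residue_label: str | None = None,
    monomer_data: MonomerTransitionData | None = None,
) -> ChromophoreSite:
    """Build a :class:`ChromophoreSite` from a name->xyz mapping."""
    atoms = [
        Atom(n, _ELEMENT_OF.get(n[0], n[0]), xyz) for n, xyz in coords_by_name.items()
    ]
    ring = tuple(
        n for n in BASE_HEAVY_ATOMS[base_type] if n in coords_by_name
    )
    return ChromophoreSite(
        site_id=site_id,
        residue_label=residue_label or f"{base_type}{site_id + 1}",
        base_type=base_type,
        atoms=atoms,
        ring_atoms=ring,
        monomer_data=monomer_data,
    )
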