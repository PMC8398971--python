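"""Excitonic states and ECD / absorption spectra.

Diagonalizes the excitonic Hamiltonian, computes per-state oscillator
strengths and origin-independent rotational strengths, and turns the stick
spectrum into shifted, Gaussian-broadened curves on a wavelength grid,
with snapshot averaging and peak normalization.

Rotational strength convention
------------------------------
For excitonic state k with coefficients C_ik over basis states i carrying
velocity-gauge electric transition dipoles mu_i (a.u.), intrinsic magnetic
transition dipoles m_i (a.u., imaginary part as a real vector) and centres
r_i, we evaluate (atomic units)

    R_k = sum_i C_ik^2 (mu_i . m_i)
        - sum_{i<j} C_ik C_jk w_ij (r_i - r_j) . (mu_i x mu_j),

with the state-independent pair prefactor w_ij = (E_i + E_j) / (4 c) built
from the basis-state energies.  Only coordinate differences enter, so every
R_k is exactly invariant under rigid translations; because the extrinsic
weight does not depend on k, eigenvector orthonormality makes the extrinsic
part cancel in sum_k R_k, which therefore equals the intrinsic total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .constants import (
    ANGSTROM_BOHR,
    DEFAULT_SHIFT_EV,
    DEFAULT_SIGMA_EV,
    EV_NM,
    HARTREE_EV,
    ROTSTR_AU_TO_CGS40,
    SPEED_OF_LIGHT_AU,
)
from .hamiltonian import ExcitonHamiltonian

__all__ = [
    "ExcitonStates",
    "SpectrumCurve",
    "diagonalize",
    "rotational_strengths",
    "oscillator_strengths",
    "make_states",
    "stick_to_curve",
    "average_curves",
    "normalize_to_peak",
    "DEFAULT_GRID_NM",
]

#: default wavelength grid: 220-340 nm at 0.5 nm
DEFAULT_GRID_NM = (220.0, 340.0, 0.5)


@dataclass
class ExcitonStates:
    """Eigenstates of an excitonic Hamiltonian with their intensities."""

    energies: np.ndarray          # eV, ascending
    coefficients: np.ndarray      # (n_basis, n_states), columns orthonormal
    R: np.ndarray | None = None   # rotational strengths
    f: np.ndarray | None = None   # oscillator strengths
    R_units: str = "1e-40 cgs"

    @property
    def n_states(self) -> int:
        return len(self.energies)


def diagonalize(ham: ExcitonHamiltonian) -> ExcitonStates:
    """Eigenstates in ascending energy order with fixed phases.

    Each eigenvector's sign is chosen so its largest-magnitude coefficient
    is positive; degenerate states are ordered by the basis index of that
    coefficient.
    """
    H = ham.H
    if np.max(np.abs(H - H.T)) > 1e-10:
        raise ValueError("Hamiltonian is not symmetric")
    evals, evecs = scipy.linalg.eigh(H)
    # stable ordering inside (numerically) degenerate clusters
    lead = np.argmax(np.abs(evecs), axis=0)
    order = np.lexsort((lead, np.round(evals / 1e-10).astype(np.int64)))
    evals, evecs, lead = evals[order], evecs[:, order], lead[order]
    signs = np.where(evecs[lead, np.arange(evecs.shape[1])] < 0, -1.0, 1.0)
    return ExcitonStates(energies=evals, coefficients=evecs * signs[None, :])


def rotational_strengths(
    states: ExcitonStates, ham: ExcitonHamiltonian, units: str = "1e-40 cgs"
) -> np.ndarray:
    """Origin-independent velocity-gauge rotational strengths per state.

    See the module docstring for the convention.  Units: "au" or the
    customary "1e-40 cgs".
    """
    mu = ham.state_elec_tdip
    m = ham.state_mag_tdip
    r = ham.state_positions * ANGSTROM_BOHR
    C = states.coefficients

    intrinsic = np.einsum("id,id->i", mu, m)
    R = (C**2).T @ intrinsic

    # Pairwise extrinsic term.  The prefactor must not depend on the state
    # index (that is what makes sum_k R_k collapse onto the intrinsic
    # total), so a single reference energy is used: the mean LE site
    # energy, across which the band varies by only a few percent.
    diag = np.diag(ham.H)
    le = diag[ham.basis.le_slice]
    E_ref = (le.mean() if le.size else diag.mean()) / HARTREE_EV
    cross = np.cross(mu[:, None, :], mu[None, :, :])        # (n, n, 3)
    dr = r[:, None, :] - r[None, :, :]
    G = np.einsum("ijd,ijd->ij", dr, cross)                 # antisym x antisym -> sym
    M = G * (E_ref / (2.0 * SPEED_OF_LIGHT_AU))
    np.fill_diagonal(M, 0.0)
    R -= 0.5 * np.einsum("ik,ij,jk->k", C, M, C)

    if units == "1e-40 cgs":
        R = R * ROTSTR_AU_TO_CGS40
    elif units != "au":
        raise ValueError(f"unknown rotational-strength units {units!r}")
    return R


def oscillator_strengths(states: ExcitonStates, ham: ExcitonHamiltonian) -> np.ndarray:
    """f_k = (2/3) E_k |sum_i C_ik mu_i|^2 (dimensionless, a.u. input)."""
    mu_k = states.coefficients.T @ ham.state_elec_tdip     # (n_states, 3)
    E_h = states.energies / HARTREE_EV
    return (2.0 / 3.0) * E_h * np.einsum("kd,kd->k", mu_k, mu_k)


def make_states(ham: ExcitonHamiltonian, units: str = "1e-40 cgs") -> ExcitonStates:
    """Diagonalize and attach rotational and oscillator strengths."""
    st = diagonalize(ham)
    st.R = rotational_strengths(st, ham, units=units)
    st.f = oscillator_strengths(st, ham)
    st.R_units = units
    return st


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

@dataclass
class SpectrumCurve:
    """Broadened spectrum on a wavelength grid (signed for CD)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    shift_applied: float
    sigma: float
    normalization: dict = field(default_factory=lambda: {"scale": 1.0, "reference": "none"})
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.diff(self.wavelength_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength grid must be strictly monotone")

    @property
    def energy_ev(self) -> np.ndarray:
        return EV_NM / self.wavelength_nm

    def write_tsv(self, path) -> None:
        arr = np.column_stack([self.wavelength_nm, self.intensity])
        header = "wavelength_nm\tintensity"
        np.savetxt(path, arr, delimiter="\t", header=header, comments="")
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(
                {
                    "shift_applied_eV": self.shift_applied,
                    "sigma_eV": self.sigma,
                    "normalization": self.normalization,
                    **self.meta,
                },
                fh,
                indent=1,
            )


def stick_to_curve(
    sticks,
    sigma: float = DEFAULT_SIGMA_EV,
    shift: float = DEFAULT_SHIFT_EV,
    grid_nm=DEFAULT_GRID_NM,
    meta: dict | None = None,
) -> SpectrumCurve:
    """Broaden (energy, intensity) sticks into a curve.

    Each stick becomes a unit-area Gaussian in the energy domain centred at
    E_k + shift (so halving sigma doubles the peak height), evaluated on
    the wavelength grid.  ``sticks`` is an iterable of (energy_eV, value)
    pairs; CD curves are signed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo, hi, step = grid_nm
    wl = np.arange(lo, hi + 0.5 * step, step)
    E = EV_NM / wl
    sticks = list(sticks)
    if not sticks:
        warnings.warn("empty stick list: returning a zero curve")
        y = np.zeros_like(wl)
    else:
        centres = np.array([e for e, _ in sticks]) + shift
        vals = np.array([v for _, v in sticks])
        g = np.exp(-0.5 * ((E[:, None] - centres[None, :]) / sigma) ** 2)
        y = g @ vals / (sigma * np.sqrt(2.0 * np.pi))
    return SpectrumCurve(
        wavelength_nm=wl, intensity=y, shift_applied=shift, sigma=sigma,
        meta=meta or {},
    )


def states_to_curve(states: ExcitonStates, kind: str = "cd", **kw) -> SpectrumCurve:
    """Convenience: broadened CD (R sticks) or absorption (f sticks)."""
    vals = states.R if kind == "cd" else states.f
    if vals is None:
        raise ValueError(f"states carry no {'R' if kind == 'cd' else 'f'} values")
    curve = stick_to_curve(zip(states.energies, vals), **kw)
    curve.meta["kind"] = kind
    return curve


def average_curves(curves) -> SpectrumCurve:
    """Pointwise arithmetic mean of curves on identical grids."""
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    wl0 = curves[0].wavelength_nm
    for c in curves[1:]:
        if c.wavelength_nm.shape != wl0.shape or np.max(np.abs(c.wavelength_nm - wl0)) > 1e-9:
            raise ValueError("grid mismatch among curves")
    y = np.mean([c.intensity for c in curves], axis=0)
    return SpectrumCurve(
        wavelength_nm=wl0.copy(), intensity=y,
        shift_applied=curves[0].shift_applied, sigma=curves[0].sigma,
        meta={"averaged_over": len(curves),
              "sources": [c.meta.get("source", "") for c in curves]},
    )


def _lowest_energy_peak(curve: SpectrumCurve) -> tuple[int, float]:
    """Index and value of the longest-wavelength local extremum of |I|."""
    y = np.abs(curve.intensity)
    if np.max(y) < 1e-300:
        raise ValueError("flat curve: no peak to normalize to")
    interior = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 1e-3 * y.max())
    cand = np.where(interior)[0] + 1
    if cand.size == 0:
        cand = np.array([int(np.argmax(y))])
    # grid runs short -> long wavelength; the last candidate is lowest energy
    k = int(cand[np.argmax(curve.wavelength_nm[cand])])
    return k, float(curve.intensity[k])


def normalize_to_peak(
    curve: SpectrumCurve,
    reference=1.0,
    which_peak: str = "lowest_energy",
    scale: float | None = None,
) -> SpectrumCurve:
    """Scale a curve so a chosen extremum matches a reference value.

    ``reference`` may be a scalar target or another curve (whose own peak
    value is the target).  Passing ``scale`` instead applies a stored
    factor, so sibling curves can reuse one normalization without each
    being forced to peak 1.
    """
    if which_peak != "lowest_energy":
        raise ValueError("only 'lowest_energy' peak selection is implemented")
    if scale is None:
        _, own = _lowest_energy_peak(curve)
        if isinstance(reference, SpectrumCurve):
            _, target = _lowest_energy_peak(reference)
        else:
            target = float(reference)
        scale = abs(target) / abs(own)
    out = replace(
        curve,
        intensity=curve.intensity * scale,
        normalization={"scale": float(scale), "reference": which_peak},
        meta=dict(curve.meta),
    )
    return out
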