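"""Composition analysis of excitonic states.

Decomposes eigenstates into per-site LE coefficients and per-pair CT
weights, reports the low-energy band (energies, rotational and oscillator
strengths, CT percentage, dominant sites), and pairs structural stacking
descriptors with state compositions across a structure series, linking the
spectra to the tetrad stacking geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diabatization import StateLabel
from .hamiltonian import ExcitonHamiltonian
from .spectra import ExcitonStates
from .structure import OverlapReport

__all__ = [
    "StateComposition",
    "state_composition",
    "band_report",
    "correlate_overlap_vs_composition",
]


@dataclass
class StateComposition:
    """LE/CT decomposition of one excitonic state."""

    state_index: int
    energy_ev: float
    le_coefficients: dict[tuple[int, str], float]   # (site, alpha) -> signed C
    ct_weights: dict[tuple[int, int], float]        # ordered (donor, acceptor) -> sum_g C^2
    ct_percent: float
    R: float | None = None
    f: float | None = None

    @property
    def le_weight(self) -> float:
        return float(sum(c * c for c in self.le_coefficients.values()))

    @property
    def ct_weight(self) -> float:
        return float(sum(self.ct_weights.values()))

    def dominant_le(self) -> tuple[int, str]:
        return max(self.le_coefficients, key=lambda k: abs(self.le_coefficients[k]))

    def dominant_ct_pair(self) -> tuple[int, int] | None:
        if not self.ct_weights:
            return None
        return max(self.ct_weights, key=self.ct_weights.get)

    def to_dict(self) -> dict:
        return {
            "state": self.state_index,
            "energy_ev": self.energy_ev,
            "le_coefficients": {f"{s}:{a}": c for (s, a), c in self.le_coefficients.items()},
            "ct_weights": {f"{d}->{a}": w for (d, a), w in self.ct_weights.items()},
            "ct_percent": self.ct_percent,
            "R": self.R,
            "f": self.f,
        }


def state_composition(
    states: ExcitonStates, ham: ExcitonHamiltonian, k: int
) -> StateComposition:
    """Partition state k's coefficients by basis label; CT percent is 100x
    the total squared weight on the CT block."""
    if not 0 <= k < states.n_states:
        raise IndexError(f"state index {k} out of range (0..{states.n_states - 1})")
    C = states.coefficients[:, k]
    le: dict[tuple[int, str], float] = {}
    ct: dict[tuple[int, int], float] = {}
    for i, label in enumerate(ham.basis.labels):
        if label.kind == "LE":
            le[(label.site, label.alpha)] = float(C[i])
        else:
            key = (label.donor, label.acceptor)
            ct[key] = ct.get(key, 0.0) + float(C[i] ** 2)
    ct_total = sum(ct.values())
    return StateComposition(
        state_index=k,
        energy_ev=float(states.energies[k]),
        le_coefficients=le,
        ct_weights=ct,
        ct_percent=100.0 * ct_total,
        R=float(states.R[k]) if states.R is not None else None,
        f=float(states.f[k]) if states.f is not None else None,
    )


def band_report(
    states: ExcitonStates, ham: ExcitonHamiltonian, n_states: int | None = None
) -> pd.DataFrame:
    """Per-state table over the lowest states (default: the LE-band count,
    n_sites x n_loc): energy, R, f, CT percent, dominant LE label."""
    if n_states is None:
        n_states = ham.basis.n_le
    if n_states > states.n_states:
        raise ValueError("fewer states than requested")
    rows = []
    for k in range(n_states):
        comp = state_composition(states, ham, k)
        site, alpha = comp.dominant_le()
        rows.append(
            {
                "state": k + 1,
                "energy_ev": comp.energy_ev,
                "R": comp.R,
                "f": comp.f,
                "ct_percent": comp.ct_percent,
                "dominant_site": site,
                "dominant_le": alpha,
                "dominant_coeff": comp.le_coefficients[(site, alpha)],
            }
        )
    return pd.DataFrame(rows)


def correlate_overlap_vs_composition(
    overlaps: dict[str, OverlapReport],
    compositions: dict[str, dict[int, StateComposition]],
) -> pd.DataFrame:
    """Pair interface overlap totals with state CT/LE weights per structure.

    ``overlaps`` and ``compositions`` are keyed by structure id; the output
    has one row per structure id (sorted, order-independent of the input)
    with the interface totals and, for each selected state, the total CT
    weight and the dominant stacked pair's CT weight.
    """
    if set(overlaps) != set(compositions):
        raise ValueError(
            f"mismatched structure ids: {sorted(set(overlaps) ^ set(compositions))}"
        )
    rows = []
    for sid in sorted(overlaps):
        rep = overlaps[sid]
        row: dict = {"structure_id": sid}
        for (a, b), tot in sorted(rep.interface_totals.items()):
            row[f"overlap_{a}_{b}"] = tot
        for k, comp in sorted(compositions[sid].items()):
            row[f"state{k + 1}_ct_percent"] = comp.ct_percent
            pair = comp.dominant_ct_pair()
            row[f"state{k + 1}_top_ct_pair"] = f"{pair[0]}->{pair[1]}" if pair else ""
            row[f"state{k + 1}_top_ct_weight"] = (
                comp.ct_weights[pair] if pair else 0.0
            )
            dom = comp.dominant_le()
            row[f"state{k + 1}_dominant_le"] = f"{dom[0]}:{dom[1]}"
        rows.append(row)
    return pd.DataFrame(rows)


def write_compositions(comps: dict[int, StateComposition], path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k + 1): c.to_dict() for k, c in sorted(comps.items())}, fh, indent=1)
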