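"""Parametrization interchange format (JSON).

A parametrization file carries, per supramolecular complex (SC), exactly
the data the diabatization needs and nothing wavefunction-shaped: the
reference-state labels, the overlap matrix S (row-major, one row per
reference state), the adiabatic energies (eV) and the adiabatic electric
(gauge-flagged) and magnetic transition dipoles (a.u.).  The machine-
readable schema ships in ``docs/parametrization_schema.json``.
"""

from __future__ import annotations

import json

import numpy as np

from .diabatization import AdiabaticSet, ReferenceOverlap, StateLabel

__all__ = ["save_parametrization", "load_parametrization"]


def _label_to_json(l: StateLabel) -> dict:
    if l.kind == "LE":
        return {"kind": "LE", "site": l.site, "state": l.alpha}
    return {"kind": "CT", "donor": l.donor, "acceptor": l.acceptor,
            "orbital_pair": l.gamma}


def _label_from_json(d: dict) -> StateLabel:
    if d["kind"] == "LE":
        return StateLabel("LE", site=int(d["site"]), alpha=str(d["state"]))
    return StateLabel("CT", donor=int(d["donor"]), acceptor=int(d["acceptor"]),
                      gamma=int(d["orbital_pair"]))


def save_parametrization(path, sc_data: dict) -> None:
    """Write SCs to JSON.  ``sc_data`` maps sc_id -> (overlap, adiabatic)."""
    blocks = []
    for sc_id, (overlap, adiabatic) in sc_data.items():
        blocks.append(
            {
                "sc_id": str(sc_id),
                "labels": [_label_to_json(l) for l in overlap.labels],
                "n_adiabatic": adiabatic.n_adiabatic,
                "S": np.asarray(overlap.S).tolist(),
                "energies_eV": adiabatic.energies.tolist(),
                "elec_tdip_au": adiabatic.elec_tdip.tolist(),
                "elec_gauge": adiabatic.elec_gauge,
                "mag_tdip_au": adiabatic.mag_tdip.tolist(),
            }
        )
    with open(path, "w") as fh:
        json.dump({"format": "frdex-parametrization-1", "scs": blocks}, fh)


def load_parametrization(path) -> dict:
    """Read SCs from JSON; returns {sc_id: (ReferenceOverlap, AdiabaticSet)}."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("format") != "frdex-parametrization-1":
        raise ValueError(f"{path}: not a frdex parametrization file")
    out = {}
    for blk in data["scs"]:
        labels = [_label_from_json(d) for d in blk["labels"]]
        overlap = ReferenceOverlap(labels=labels, S=np.array(blk["S"], float))
        adiabatic = AdiabaticSet(
            sc_id=blk["sc_id"],
            energies=np.array(blk["energies_eV"], float),
            elec_tdip=np.array(blk["elec_tdip_au"], float),
            mag_tdip=np.array(blk["mag_tdip_au"], float),
            elec_gauge=blk.get("elec_gauge", "velocity"),
        )
        out[blk["sc_id"]] = (overlap, adiabatic)
    return out
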