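"""Orchestration of the per-structure analysis and report serialization.

A single call runs ligand extraction, hydrogen placement, ring perception,
pi-contact and hydrogen-bond detection, and pocket-volume estimation, and
returns a versioned, JSON-serialisable report with all parameters echoed.
Identical inputs and configuration produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .binding import BindingCurve, BindingFit, ItcTitration, fit_itc, fit_mst
from .geometry import DomainMotion, domain_motion
from .interactions import (
    HBond,
    PiContact,
    PiCriteria,
    detect_hbonds,
    detect_pi_contacts,
    find_aromatic_rings,
    place_ligand_hydrogens,
)
from .pocket import PocketParams, PocketResult, pocket_volume
from .structure_io import Structure, extract_ligand, read_structure

__all__ = [
    "AnalysisReport",
    "analyze_structure",
    "compare_states",
    "fit_binding_mst",
    "fit_binding_itc",
    "report_to_json",
    "pi_contacts_to_tsv",
    "hbonds_to_tsv",
    "load_binding_table",
    "load_itc_table",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisReport:
    """Aggregated binding-site findings for one structure + ligand."""

    structure_id: str
    ligand_selector: dict[str, Any]
    pi_contacts: list[PiContact]
    hbonds: list[HBond]
    pocket: PocketResult | None
    criteria: PiCriteria
    pocket_params: PocketParams | None
    hbond_cutoff: float
    warnings: list[str] = field(default_factory=list)
    schema_version: int = REPORT_SCHEMA_VERSION


def analyze_structure(
    structure: Structure | str | Path,
    ligand_residue: str,
    chain_id: str | None = None,
    residue_number: int | None = None,
    criteria: PiCriteria | None = None,
    pocket_params: PocketParams | None = None,
    hbond_cutoff: float = 3.5,
    run_pocket: bool = True,
) -> AnalysisReport:
    """Run the full per-structure binding-site analysis.

    Pipeline: extract the P-ligand, model its P-H hydrogens, perceive
    aromatic rings near the ligand, apply the pi criterion, collect the
    ligand hydrogen-bond network, and (optionally) measure the enclosed
    pocket volume. Deterministic for fixed inputs and configuration.
    """
    if not isinstance(structure, Structure):
        structure = read_structure(structure)
    criteria = criteria or PiCriteria()
    warnings: list[str] = []

    lig = extract_ligand(structure, ligand_residue, chain_id, residue_number)
    lig = place_ligand_hydrogens(lig)
    rings, skipped = find_aromatic_rings(structure, near=lig.centroid(), radius=10.0)
    warnings.extend(f"ring skipped: {s}" for s in skipped)

    if lig.hydrogens:
        contacts = detect_pi_contacts(lig, rings, criteria)
    else:
        contacts = []
        warnings.append("ligand carries no P-H hydrogens; pi criterion not applicable")
    hbonds = detect_hbonds(lig, structure, cutoff=hbond_cutoff)

    pocket = None
    if run_pocket:
        pocket_params = pocket_params or PocketParams()
        pocket = pocket_volume(structure, lig, pocket_params)
        warnings.extend(f"pocket: {f}" for f in pocket.flags)

    return AnalysisReport(
        structure_id=structure.id,
        ligand_selector={
            "residue_name": ligand_residue,
            "chain_id": chain_id,
            "residue_number": residue_number,
        },
        pi_contacts=contacts,
        hbonds=hbonds,
        pocket=pocket,
        criteria=criteria,
        pocket_params=pocket_params if run_pocket else None,
        hbond_cutoff=hbond_cutoff,
        warnings=warnings,
    )


def compare_states(
    open_structure: Structure | str | Path,
    closed_structure: Structure | str | Path,
    lobe1: list[tuple[int, int]],
    lobe2: list[tuple[int, int]],
    chain_open: str | None = None,
    chain_closed: str | None = None,
) -> DomainMotion:
    """Two-state domain-motion analysis (delegates to geometry)."""
    if not isinstance(open_structure, Structure):
        open_structure = read_structure(open_structure)
    if not isinstance(closed_structure, Structure):
        closed_structure = read_structure(closed_structure)
    return domain_motion(
        open_structure, closed_structure, lobe1, lobe2, chain_open, chain_closed
    )


def fit_binding_mst(curves: list[BindingCurve]) -> BindingFit:
    """MST replicate fit (delegates to binding)."""
    return fit_mst(curves)


def fit_binding_itc(titration: ItcTitration):
    """Single-site ITC fit (delegates to binding)."""
    return fit_itc(titration)


def load_binding_table(path: str | Path, protein_conc: float) -> list[BindingCurve]:
    """Read an MST table: columns replicate, ligand_conc, unit, signal.

    Delimited text (comma or whitespace); unit is one of M, mM, uM, nM.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"replicate", "ligand_conc", "unit", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"binding table missing columns: {sorted(missing)}")
    scale = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}
    conc = df["ligand_conc"].astype(float) * df["unit"].map(scale).astype(float)
    curves = []
    for rep, grp in df.assign(conc_M=conc).groupby("replicate"):
        g = grp.sort_values("conc_M", ascending=False)
        curves.append(
            BindingCurve(
                ligand_conc=g["conc_M"].to_numpy(),
                signal=g["signal"].to_numpy(),
                replicate_id=int(rep),
                protein_conc=protein_conc,
            )
        )
    return curves


def load_itc_table(
    path: str | Path,
    cell_protein_conc: float,
    syringe_ligand_conc: float,
    cell_volume: float,
    skip_first: bool = True,
) -> ItcTitration:
    """Read an ITC table: columns injection_volume (ul), heat (uJ)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"injection_volume", "heat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ITC table missing columns: {sorted(missing)}")
    return ItcTitration(
        cell_protein_conc=cell_protein_conc,
        syringe_ligand_conc=syringe_ligand_conc,
        cell_volume=cell_volume,
        injection_volumes=df["injection_volume"].to_numpy(float),
        heats=df["heat"].to_numpy(float),
        skip_first=skip_first,
    )


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return [float(f"{float(x):.9g}") for x in obj.ravel()]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.9g}")  # 9 significant digits, stable
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (frozenset, set)):
        return sorted(_jsonable(x) for x in obj)
    if isinstance(obj, tuple):
        return [_jsonable(x) for x in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_jsonable(x) for x in obj]
    return obj


def report_to_json(report: Any, path: str | Path | None = None) -> str:
    """Serialize a report (any package dataclass) to canonical JSON.

    Keys are sorted and floats rounded to 6 decimals so identical inputs
    give byte-identical output; the tool version and a config hash are
    embedded for provenance.
    """
    body = _jsonable(report)
    envelope = {
        "tool": "phosbind",
        "version": __version__,
        "report": body,
    }
    envelope["config_hash"] = hashlib.sha256(
        json.dumps(body, sort_keys=True).encode()
    ).hexdigest()[:16]
    text = json.dumps(envelope, sort_keys=True, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def pi_contacts_to_tsv(contacts: list[PiContact]) -> str:
    """One row per contact: donor, ring residue, d, offset, theta."""
    lines = ["donor\tring_residue\tring_label\tplane_distance_A\tcentroid_offset_A\tapproach_angle_deg"]
    for c in contacts:
        d = c.donor_atom
        lines.append(
            f"{d.element}:{d.residue_name}{d.residue_number}({d.chain_id})\t"
            f"{c.ring_residue}\t{c.ring.ring_label}\t"
            f"{c.plane_distance:.3f}\t{c.centroid_offset:.3f}\t{c.approach_angle:.1f}"
        )
    return "\n".join(lines) + "\n"


def hbonds_to_tsv(hbonds: list[HBond]) -> str:
    """One row per hydrogen bond: ligand oxygen, partner, distance."""
    lines = ["ligand_atom\tpartner_atom\tpartner_residue\tdistance_A"]
    for b in hbonds:
        lines.append(
            f"{b.donor.name}\t{b.acceptor.name}\t{b.partner_residue}\t{b.distance:.3f}"
        )
    return "\n".join(lines) + "\n"
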