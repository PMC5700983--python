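"""Van der Waals radii (Bondi set), the single source of truth for all modules."""

#: Bondi van der Waals radii in Angstroms. Elements absent from the table
#: fall back to :data:`DEFAULT_VDW`.
BONDI_VDW = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for an element symbol (case-insensitive)."""
    return BONDI_VDW.get(element.upper(), DEFAULT_VDW)
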