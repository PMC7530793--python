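"""Multiplex panel definitions: markers, compartments, fluorophore pairings.

MP1 is a six-plex T/B-cell panel (CD3, CD4, CD8, CD20, CK, DAPI) in which
CD3 co-expresses with CD4 and CD8 in the *same* cellular compartment (the
T-cell membrane).  MP2 is a five-plex panel (CD4, CD68, FOXP3, CK, DAPI)
whose co-expressing pair (CD4/FOXP3, regulatory T cells) sits in *different*
compartments (membrane vs nucleus).  That design difference is what makes
MP1, but not MP2, sensitive to detection order and dense-region artefacts.
"""

from __future__ import annotations

from .errors import ConfigurationError

MP1 = "MP1"
MP2 = "MP2"

PANEL_MARKERS = {
    MP1: ["DAPI", "CK", "CD3", "CD20", "CD4", "CD8"],
    MP2: ["DAPI", "CK", "CD68", "CD4", "FOXP3"],
}

#: Compartment in which each marker is expressed and measured.
MARKER_COMPARTMENT = {
    "DAPI": "nucleus",
    "CK": "membrane",
    "CD3": "membrane",
    "CD4": "membrane",
    "CD8": "membrane",
    "CD20": "membrane",
    "CD68": "membrane",
    "FOXP3": "nucleus",
}

#: Final optimised Opal-antibody pairings (spectrally distant MOTiF dyes).
PANEL_FLUOROPHORES = {
    MP1: {
        "DAPI": "DAPI",
        "CK": "Opal480",
        "CD3": "Opal520",
        "CD20": "Opal570",
        "CD4": "Opal620",
        "CD8": "Opal690",
    },
    MP2: {
        "DAPI": "DAPI",
        "CK": "Opal480",
        "CD68": "Opal520",
        "FOXP3": "Opal570",
        "CD4": "Opal620",
    },
}


def check_panel(panel: str) -> str:
    if panel not in PANEL_MARKERS:
        raise ConfigurationError(f"unknown panel {panel!r}; expected one of {list(PANEL_MARKERS)}")
    return panel


def panel_markers(panel: str) -> list[str]:
    return list(PANEL_MARKERS[check_panel(panel)])


def panel_fluorophores(panel: str) -> dict[str, str]:
    return dict(PANEL_FLUOROPHORES[check_panel(panel)])


def default_exposures(channels: list[str], base_ms: float = 50.0, dapi_ms: float = 20.0) -> dict[str, float]:
    """Per-channel exposure times in ms (nuclear counterstain is bright)."""
    return {c: (dapi_ms if c == "DAPI" else base_ms) for c in channels}
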