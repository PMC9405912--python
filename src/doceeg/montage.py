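"""10–20 montage geometry: Laplacian neighbor map and connectivity ROIs.

The adjacency table is a versioned design choice (the nearest-neighbor
graph of the standard 10–20 layout); the ROI pair sets implement the five
regions used for connectivity summaries: left/right frontoparietal
(intrahemispheric) and frontal/central/posterior interhemispheric.
Midline electrodes Fz/Cz/Pz are excluded from the ROIs.
"""
from __future__ import annotations

import itertools

from .core import CHANNELS_1020, ConfigurationError, canonical_channel_name

ADJACENCY_VERSION = "10-20-nn-v1"

#: Nearest-neighbor adjacency on the 10–20 layout (symmetric).
ADJACENCY: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7"),
    "Fp2": ("Fp1", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("F3", "F4", "Cz"),
    "F4": ("Fp2", "F8", "Fz", "C4"),
    "F8": ("Fp2", "F4", "T4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4"),
    "P4": ("C4", "T6", "Pz", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "O2"),
    "O2": ("T6", "P4", "O1"),
}

#: ROI definitions as cross-products of electrode sets. Each ROI value is
#: the mean connectivity over its electrode pairs.
ROI_ELECTRODES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "left_frontoparietal": (("Fp1", "F3", "F7"), ("P3", "T5")),
    "right_frontoparietal": (("Fp2", "F4", "F8"), ("P4", "T6")),
    "frontal_inter": (("Fp1", "F3", "F7"), ("Fp2", "F4", "F8")),
    "central_inter": (("T3", "C3"), ("C4", "T4")),
    "posterior_inter": (("P3", "T5", "O1"), ("P4", "T6", "O2")),
}

ROI_NAMES = tuple(ROI_ELECTRODES)


def roi_pairs(definition: dict | None = None) -> dict[str, tuple[tuple[str, str], ...]]:
    """Expand ROI electrode sets into explicit electrode pairs."""
    definition = definition or ROI_ELECTRODES
    out = {}
    for roi, (set_a, set_b) in definition.items():
        pairs = tuple(
            (canonical_channel_name(a), canonical_channel_name(b))
            for a, b in itertools.product(set_a, set_b)
            if a != b
        )
        if not pairs:
            raise ConfigurationError(f"ROI {roi!r} has an empty pair set")
        out[roi] = pairs
    return out


def validate_adjacency(adjacency: dict[str, tuple[str, ...]] | None = None) -> None:
    """Check that an adjacency map covers all 19 channels and is symmetric."""
    adjacency = adjacency or ADJACENCY
    missing = set(CHANNELS_1020) - set(adjacency)
    if missing:
        raise ConfigurationError(f"adjacency is missing channels {sorted(missing)}")
    for ch, nbrs in adjacency.items():
        for n in nbrs:
            if ch not in adjacency[n]:
                raise ConfigurationError(f"adjacency not symmetric: {ch}->{n}")
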