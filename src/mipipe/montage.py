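"""Canonical 19-channel 10-20 montage.

The montage fixes channel order for every array in the package, partitions
the scalp into left / right / medial sets, and maps a motor-imagery task
side to the contralateral sensorimotor channel (left-hand MI -> C4,
right-hand MI -> C3).  Older tempo-parietal labels (T3/T4/T5/T6) are
canonical; the modern spellings (T7/T8/P7/P8) are accepted on input and
normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

#: canonical channel order used by every trials x channels x samples array
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

LEFT_SET = frozenset({"Fp1", "F7", "F3", "T3", "C3", "T5", "P3", "O1"})
RIGHT_SET = frozenset({"Fp2", "F8", "F4", "T4", "C4", "T6", "P4", "O2"})
MEDIAL_SET = frozenset({"Fz", "Cz", "Pz"})

#: modern 10-10 spellings mapped back to the older labels used here
LABEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: left/right mirror pairs (midline channels map to themselves)
_MIRROR = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "T3": "T4", "C3": "C4",
    "T5": "T6", "P3": "P4", "O1": "O2",
    "Fz": "Fz", "Cz": "Cz", "Pz": "Pz",
}
_MIRROR.update({v: k for k, v in list(_MIRROR.items()) if k != v})

#: schematic 2-D scalp coordinates (unit head, Cz at origin); used by the
#: simulator's spatial ERP weighting, not for plotting
POSITIONS_2D = {
    "Fp1": (-0.3, 0.8), "Fp2": (0.3, 0.8),
    "F7": (-0.8, 0.4), "F3": (-0.4, 0.4), "Fz": (0.0, 0.4),
    "F4": (0.4, 0.4), "F8": (0.8, 0.4),
    "T3": (-0.8, 0.0), "C3": (-0.4, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.4, 0.0), "T4": (0.8, 0.0),
    "T5": (-0.8, -0.4), "P3": (-0.4, -0.4), "Pz": (0.0, -0.4),
    "P4": (0.4, -0.4), "T6": (0.8, -0.4),
    "O1": (-0.3, -0.8), "O2": (0.3, -0.8),
}


def normalize_label(label: str) -> str:
    """Map a raw channel label onto the canonical montage spelling.

    Strips common reference suffixes (``-REF``, ``-A1`` ...), matches
    case-insensitively and resolves T7/T8/P7/P8 aliases.  Raises
    ``ConfigurationError`` for labels outside the montage.
    """
    cleaned = label.strip()
    if cleaned.lower().startswith("eeg"):  # e.g. "EEG C3-REF"
        cleaned = cleaned[3:].lstrip(" -_")
    for sep in ("-", " "):
        if sep in cleaned:
            cleaned = cleaned.split(sep)[0]
    by_lower = {c.lower(): c for c in CHANNELS_1020}
    by_lower.update({a.lower(): c for a, c in LABEL_ALIASES.items()})
    key = cleaned.strip().lower()
    if key not in by_lower:
        raise ConfigurationError(f"unknown 10-20 channel label: {label!r}")
    return by_lower[key]


@dataclass(frozen=True)
class Montage:
    """Ordered 10-20 channel list with hemisphere partition."""

    channels: tuple[str, ...] = CHANNELS_1020
    left_set: frozenset[str] = LEFT_SET
    right_set: frozenset[str] = RIGHT_SET
    medial_set: frozenset[str] = MEDIAL_SET
    contralateral_map: dict = field(
        default_factory=lambda: {"left": "C4", "right": "C3"}
    )

    def __post_init__(self) -> None:
        union = self.left_set | self.right_set | self.medial_set
        if union != set(self.channels) or (
            len(self.left_set) + len(self.right_set) + len(self.medial_set)
            != len(self.channels)
        ):
            raise ConfigurationError(
                "left/right/medial sets must partition the montage channels"
            )
        for task, ch in self.contralateral_map.items():
            if _MIRROR.get(ch) != self.contralateral_map[
                "left" if task == "right" else "right"
            ]:
                raise ConfigurationError(
                    "contralateral_map entries must be mirror channels"
                )

    def index(self, label: str) -> int:
        return self.channels.index(normalize_label(label))

    def mirror(self, label: str) -> str:
        return _MIRROR[normalize_label(label)]

    def contralateral(self, task: str) -> str:
        """Channel contralateral to the imagined hand ('left' or 'right')."""
        try:
            return self.contralateral_map[task]
        except KeyError:
            raise ConfigurationError(f"no contralateral channel for task {task!r}")

    def ipsilateral(self, task: str) -> str:
        return self.mirror(self.contralateral(task))

    def indices(self, labels) -> list[int]:
        return [self.index(lb) for lb in labels]


def standard_montage() -> Montage:
    """The package-wide default 19-channel montage."""
    return Montage()
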