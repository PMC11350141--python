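"""Frontal fNIRS montage: optodes, channels, and the LDLPFC channel set.

The default montage is the 48-channel frontal layout used throughout the
package: 16 sources and 16 detectors anchored to 10-20 scalp positions,
every source-detector pair separated by 3.0 cm.  Only the three left
dorsolateral prefrontal cortex (LDLPFC) channels are anatomically
meaningful to the analyses (F3-F5, F3-F1, F3-FC3); the remaining labels
follow a documented frontal 10-20 convention.  Analyses depend only on
channel labels and the LDLPFC set, never on geometry; the nominal 2-D
positions exist for display purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage", "LDLPFC_LABELS"]

#: The three LDLPFC channels named in the analysis.
LDLPFC_LABELS = ("F3-F5", "F3-F1", "F3-FC3")

# Frontal 10-20 optode grid: 16 source positions and 16 detector positions.
# F3 (and its right homologue F4) act as sources for the DLPFC channels.
_SOURCES = [
    "F3", "F4", "Fz", "AFz", "AF3", "AF4", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "Fp1", "Fp2", "F9", "F10",
]
_DETECTORS = [
    "F5", "F1", "FC3", "F6", "F2", "FC4", "AF7", "AF8",
    "Fpz", "FT7", "FT8", "C1", "C2", "F11", "F12", "FCz",
]

# 48 source-detector pairs, three per source.  The first three channels are
# the LDLPFC set; the rest tile the frontal cortex.
_PAIRING = [
    ("F3", "F5"), ("F3", "F1"), ("F3", "FC3"),
    ("F4", "F6"), ("F4", "F2"), ("F4", "FC4"),
    ("Fz", "F1"), ("Fz", "F2"), ("Fz", "FCz"),
    ("AFz", "Fpz"), ("AFz", "F1"), ("AFz", "F2"),
    ("AF3", "AF7"), ("AF3", "F5"), ("AF3", "Fpz"),
    ("AF4", "AF8"), ("AF4", "F6"), ("AF4", "Fpz"),
    ("F7", "AF7"), ("F7", "F5"), ("F7", "FT7"),
    ("F8", "AF8"), ("F8", "F6"), ("F8", "FT8"),
    ("FC1", "F1"), ("FC1", "FCz"), ("FC1", "C1"),
    ("FC2", "F2"), ("FC2", "FCz"), ("FC2", "C2"),
    ("FC5", "FC3"), ("FC5", "F5"), ("FC5", "FT7"),
    ("FC6", "FC4"), ("FC6", "F6"), ("FC6", "FT8"),
    ("Fp1", "Fpz"), ("Fp1", "AF7"), ("Fp1", "F11"),
    ("Fp2", "Fpz"), ("Fp2", "AF8"), ("Fp2", "F12"),
    ("F9", "FT7"), ("F9", "F11"), ("F9", "AF7"),
    ("F10", "FT8"), ("F10", "F12"), ("F10", "AF8"),
]


@dataclass(frozen=True)
class Montage:
    """Source-detector channel layout for a frontal fNIRS recording."""

    sources: tuple[str, ...]
    detectors: tuple[str, ...]
    channels: tuple[tuple[str, str, str], ...]  # (source, detector, label)
    separation_cm: tuple[float, ...]
    ldlpfc_labels: tuple[str, ...] = LDLPFC_LABELS
    positions: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        labels = [c[2] for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if len(self.separation_cm) != len(self.channels):
            raise ValueError("one separation per channel required")
        if any(s <= 0 for s in self.separation_cm):
            raise ValueError("separations must be positive")
        missing = set(self.ldlpfc_labels) - set(labels)
        if missing:
            raise ValueError(f"LDLPFC labels absent from montage: {sorted(missing)}")

    @property
    def labels(self) -> list[str]:
        return [c[2] for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def ldlpfc_indices(self) -> list[int]:
        lab = self.labels
        return [lab.index(name) for name in self.ldlpfc_labels]

    def subset(self, labels: list[str]) -> "Montage":
        """Montage restricted to ``labels`` (order preserved); the LDLPFC set
        is kept only if fully contained."""
        keep = [c for c in self.channels if c[2] in set(labels)]
        idx = {c[2]: i for i, c in enumerate(self.channels)}
        sep = tuple(self.separation_cm[idx[c[2]]] for c in keep)
        kept = {c[2] for c in keep}
        ldl = self.ldlpfc_labels if set(self.ldlpfc_labels) <= kept else tuple(
            l for l in self.ldlpfc_labels if l in kept
        )
        if not ldl:
            ldl = tuple(c[2] for c in keep[:1])  # degenerate; montage needs >=1
        return Montage(
            sources=self.sources,
            detectors=self.detectors,
            channels=tuple(keep),
            separation_cm=sep,
            ldlpfc_labels=ldl,
            positions={k: v for k, v in self.positions.items() if k in kept},
        )


def default_montage() -> Montage:
    """The 48-channel frontal montage with 3.0 cm separations.

    Deterministic: identical across calls.
    """
    channels = tuple((s, d, f"{s}-{d}") for s, d in _PAIRING)
    # nominal display positions on a unit disc, plotting only
    rng_free_angle = np.linspace(0.0, 2.0 * np.pi, len(channels), endpoint=False)
    positions = {
        f"{s}-{d}": (float(np.cos(a)), float(np.sin(a)))
        for (s, d), a in zip(_PAIRING, rng_free_angle)
    }
    return Montage(
        sources=tuple(_SOURCES),
        detectors=tuple(_DETECTORS),
        channels=channels,
        separation_cm=tuple(3.0 for _ in channels),
        ldlpfc_labels=LDLPFC_LABELS,
        positions=positions,
    )
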