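"""Microsatellite-instability typing from the five reference markers.

A tumor is typed from instability calls at D2S123, D5S346, D17S250, BAT25
and BAT26: MSI-H with instability at two or more markers, MSI-L at exactly
one, MSS at none.  The rule presumes all five markers were assayed, so an
incomplete vector is an error rather than being renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .synthetic import MSI_MARKERS

MSS = "MSS"
MSI_L = "MSI-L"
MSI_H = "MSI-H"


def classify_msi(marker_unstable: Sequence[bool]) -> str:
    """MSI class from the five boolean marker instability calls."""
    if len(marker_unstable) != 5:
        raise ValueError(
            f"expected instability calls for the 5 markers {MSI_MARKERS}, "
            f"got {len(marker_unstable)}"
        )
    n_unstable = sum(bool(m) for m in marker_unstable)
    if n_unstable >= 2:
        return MSI_H
    if n_unstable == 1:
        return MSI_L
    return MSS


@dataclass
class MSIProfile:
    sample_id: str
    marker_unstable: tuple[bool, ...]
    msi_class: str = ""

    def __post_init__(self) -> None:
        self.marker_unstable = tuple(bool(m) for m in self.marker_unstable)
        derived = classify_msi(self.marker_unstable)
        if self.msi_class and self.msi_class != derived:
            raise ValueError(
                f"{self.sample_id}: class {self.msi_class} inconsistent with markers"
            )
        self.msi_class = derived
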