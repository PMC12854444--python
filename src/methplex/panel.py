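"""Marker panel of the methylation-specific multiplex ddPCR assay.

The multiplex targets five methylation biomarkers plus the *ALB* reference
gene in one reaction.  Three markers carry methylation patterns conserved in
prostate tissue regardless of cancer status (prostate-conserved), two are
hypermethylated specifically in prostate cancer tissue (PCa-specific).
Separate QC targets (spike-in recovery, blood-cell contamination, fragment
length) ride along on the same droplet-count tables but are never part of
positivity calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CONSERVED_MARKERS: tuple[str, ...] = ("ACTRT2", "EVX1", "HOXD13")
SPECIFIC_MARKERS: tuple[str, ...] = ("DOCK2", "HAPLN3")
REFERENCE_TARGET: str = "ALB"
QC_TARGETS: tuple[str, ...] = ("CPP1", "PB", "ECM7_65", "ECM7_250")


@dataclass(frozen=True)
class Panel:
    """A marker panel: which targets are called, and how they are grouped."""

    conserved: tuple[str, ...] = CONSERVED_MARKERS
    specific: tuple[str, ...] = SPECIFIC_MARKERS
    reference: str = REFERENCE_TARGET
    qc_targets: tuple[str, ...] = field(default=QC_TARGETS)

    @property
    def markers(self) -> tuple[str, ...]:
        """All called biomarkers, conserved first."""
        return self.conserved + self.specific

    @property
    def all_targets(self) -> tuple[str, ...]:
        return self.markers + (self.reference,)

    def __post_init__(self) -> None:
        overlap = set(self.conserved) & set(self.specific)
        if overlap:
            raise ValueError(f"markers in both groups: {sorted(overlap)}")
        if self.reference in self.conserved + self.specific:
            raise ValueError("reference target cannot also be a marker")


DEFAULT_PANEL = Panel()
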