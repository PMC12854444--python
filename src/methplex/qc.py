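"""Sample- and plate-level quality-control rules.

Declarative pass/fail/warn gating mirroring the assay's acceptance rules:
wells need more than 15,000 accepted droplets; bisulfite conversion
recovery (converted ALB over non-converted ECM7 65 bp) must exceed 0.2;
spike-in (CPP1) recovery and ccfDNA fragmentation (ECM7 250/65 bp ratio)
are reported without a printed cutoff; plate controls (methylated,
unmethylated, whole-blood and no-template) must behave as expected for
every marker assay.  Both printed thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .panel import DEFAULT_PANEL, Panel
from .quantify import DropletWell

DROPLET_COUNT_MIN = 15_000          # accepted droplets must exceed this
BISULFITE_RATIO_MIN = 0.2           # converted ALB / non-converted ECM7_65
CPP1_EXPECTED_COPIES_PER_ML = 35_000

PASS, FAIL, WARN, NOT_EVALUABLE = "pass", "fail", "warn", "not-evaluable"

CONTROL_ROLES = ("methylated", "unmethylated", "whole_blood", "ntc")


@dataclass(frozen=True)
class QcRule:
    name: str
    quantity: str
    comparator: str                  # one of > >= < <=
    threshold: float
    severity: str = "fail"           # fail | warn | report-only

    def __post_init__(self) -> None:
        if self.comparator not in (">", ">=", "<", "<="):
            raise ValueError(f"bad comparator {self.comparator!r}")
        if self.severity not in ("fail", "warn", "report-only"):
            raise ValueError(f"bad severity {self.severity!r}")

    def holds(self, observed: float) -> bool:
        return {
            ">": observed > self.threshold,
            ">=": observed >= self.threshold,
            "<": observed < self.threshold,
            "<=": observed <= self.threshold,
        }[self.comparator]


@dataclass(frozen=True)
class QcVerdict:
    unit_id: str                     # sample, well or plate identifier
    rule: str
    observed: float | None
    verdict: str                     # pass | fail | warn | not-evaluable
    message: str = ""


def check_droplet_count(well: DropletWell) -> QcVerdict:
    """Accepted-droplet gate: strictly more than 15,000 droplets."""
    ok = well.accepted > DROPLET_COUNT_MIN
    return QcVerdict(
        well.well_id,
        "droplet_count",
        float(well.accepted),
        PASS if ok else FAIL,
        f"accepted droplets {well.accepted} "
        f"{'>' if ok else '<='} {DROPLET_COUNT_MIN}",
    )


def bisulfite_recovery(
    alb_converted_conc: float,
    ecm7_65_nonconverted_conc: float,
    sample_id: str = "",
) -> QcVerdict:
    """Conversion recovery = converted ALB conc / non-converted ECM7 65 conc.

    Strictly greater than 0.2 passes; an undefined ratio (no ECM7 65
    signal) is not evaluable.
    """
    if ecm7_65_nonconverted_conc < 0 or alb_converted_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if ecm7_65_nonconverted_conc == 0:
        return QcVerdict(
            sample_id, "bisulfite_recovery", None, NOT_EVALUABLE,
            "ECM7 65 concentration is zero; recovery ratio undefined",
        )
    ratio = alb_converted_conc / ecm7_65_nonconverted_conc
    ok = ratio > BISULFITE_RATIO_MIN
    return QcVerdict(
        sample_id, "bisulfite_recovery", ratio, PASS if ok else FAIL,
        f"recovery ratio {ratio:.3f} {'>' if ok else '<='} {BISULFITE_RATIO_MIN}",
    )


def spike_recovery(
    cpp1_copies_per_ml: float,
    expected: float = CPP1_EXPECTED_COPIES_PER_ML,
    sample_id: str = "",
    warn_floor: float | None = None,
) -> QcVerdict:
    """CPP1 process-control recovery fraction; report-only by default.

    No acceptance cutoff is defined for the spike-in; supplying
    ``warn_floor`` escalates recoveries below it to a warning.
    """
    if expected <= 0:
        raise ValueError("expected copies must be > 0")
    if cpp1_copies_per_ml < 0:
        raise ValueError("observed copies must be >= 0")
    recovery = cpp1_copies_per_ml / expected
    verdict = PASS
    msg = f"spike recovery {recovery:.3f} (report-only)"
    if warn_floor is not None and recovery < warn_floor:
        verdict = WARN
        msg = f"spike recovery {recovery:.3f} below floor {warn_floor}"
    return QcVerdict(sample_id, "spike_recovery", recovery, verdict, msg)


def fragmentation_profile(
    ecm7_65_conc: float, ecm7_250_conc: float, sample_id: str = ""
) -> QcVerdict:
    """Fragment-length ratio (250 bp / 65 bp); report-only."""
    if ecm7_65_conc < 0 or ecm7_250_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if ecm7_65_conc == 0:
        return QcVerdict(
            sample_id, "fragmentation_profile", None, NOT_EVALUABLE,
            "ECM7 65 concentration is zero; fragmentation ratio undefined",
        )
    ratio = ecm7_250_conc / ecm7_65_conc
    return QcVerdict(
        sample_id, "fragmentation_profile", ratio, PASS,
        f"250/65 bp ratio {ratio:.3f} (report-only)",
    )


def validate_plate_controls(
    control_wells: Mapping[str, Sequence[DropletWell]],
    panel: Panel = DEFAULT_PANEL,
    lob: Mapping[str, int] | None = None,
    plate_id: str = "plate",
) -> list[QcVerdict]:
    """Check the four per-plate control roles against every marker assay.

    Methylated control must be positive for all marker assays; the
    unmethylated, whole-blood and no-template controls must be negative for
    all markers; ALB must be positive in everything but the no-template
    control.  Positivity means more than the per-assay limit of blank when
    a LOB table is supplied, else at least one positive droplet.  A missing
    control role yields a single not-evaluable verdict for that role.
    """
    verdicts: list[QcVerdict] = []

    def threshold(target: str) -> int:
        return int(lob[target]) if lob is not None and target in lob else 0

    for role in CONTROL_ROLES:
        wells = control_wells.get(role)
        if not wells:
            verdicts.append(
                QcVerdict(plate_id, f"control_{role}", None, NOT_EVALUABLE,
                          f"control role {role!r} missing from plate")
            )
            continue
        by_target = {w.target: w for w in wells}
        for target in panel.markers:
            rule = f"control_{role}_{target}"
            well = by_target.get(target)
            if well is None:
                verdicts.append(
                    QcVerdict(plate_id, rule, None, NOT_EVALUABLE,
                              f"{role} control lacks a {target} well")
                )
                continue
            positive = well.positives > threshold(target)
            want_positive = role == "methylated"
            ok = positive == want_positive
            verdicts.append(
                QcVerdict(
                    plate_id, rule, float(well.positives),
                    PASS if ok else FAIL,
                    f"{role} control {target}: {well.positives} positive "
                    f"droplets, expected {'signal' if want_positive else 'none'}",
                )
            )
        # reference behaviour
        ref = by_target.get(panel.reference)
        rule = f"control_{role}_{panel.reference}"
        if ref is None:
            verdicts.append(
                QcVerdict(plate_id, rule, None, NOT_EVALUABLE,
                          f"{role} control lacks an {panel.reference} well")
            )
        else:
            positive = ref.positives > 0
            want_positive = role != "ntc"
            ok = positive == want_positive
            verdicts.append(
                QcVerdict(
                    plate_id, rule, float(ref.positives),
                    PASS if ok else FAIL,
                    f"{role} control {panel.reference}: {ref.positives} "
                    f"positive droplets",
                )
            )
    return verdicts


def failing_samples(verdicts: Iterable[QcVerdict]) -> dict[str, list[str]]:
    """Map unit id -> names of failed rules (for downstream exclusion)."""
    failed: dict[str, list[str]] = {}
    for v in verdicts:
        if v.verdict == FAIL:
            failed.setdefault(v.unit_id, []).append(v.rule)
    return failed
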