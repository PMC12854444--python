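"""Droplet-count quantification for digital PCR.

A ddPCR reaction partitions the template into ~20,000 nanoliter droplets.
Template molecules distribute approximately Poisson across droplets, so the
mean copies per droplet is recovered from the fraction of *negative*
droplets: lambda = -ln(1 - positives/accepted).  Concentration in copies per
microliter of reaction follows by dividing by the droplet volume.

This module also handles replicate pooling, the volume chain that maps a
reaction-level concentration back to copies per milliliter of plasma,
marker/reference ratios (the ctDNA fraction), dilution-series linearity, and
the lowest reliably detected quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: Default droplet volume in nanoliters (QX-class instrument convention).
DROPLET_VOLUME_NL: float = 0.85


@dataclass(frozen=True)
class DropletWell:
    """One well x one target: positive and accepted droplet counts."""

    well_id: str
    sample_id: str
    target: str
    positives: int
    accepted: int

    def __post_init__(self) -> None:
        if self.accepted < 0:
            raise ValueError(f"accepted droplets must be >= 0, got {self.accepted}")
        if not 0 <= self.positives <= self.accepted:
            raise ValueError(
                f"well {self.well_id!r} target {self.target!r}: positives "
                f"{self.positives} outside [0, accepted={self.accepted}]"
            )


@dataclass(frozen=True)
class QuantResult:
    """Poisson quantification of one well (or pooled replicate wells)."""

    target: str
    lam: float                      # mean copies per droplet
    conc_per_ul: float              # copies per microliter of reaction
    ci95: tuple[float, float]       # 95% CI on conc_per_ul
    saturated: bool = False
    positives: int = 0
    accepted: int = 0


@dataclass(frozen=True)
class VolumeChain:
    """Volumes of the sample-processing chain, plasma -> ddPCR well.

    Defaults follow the extraction/bisulfite workflow of the assay: ccfDNA
    from 4 ml plasma eluted in 60 ul buffer + 140 ul water (200 ul total),
    30 ul drawn for QC, the remaining 170 ul concentrated to 20 ul, bisulfite
    converted and eluted in 15 ul, of which 6 ul template enters a 24 ul
    reaction.  Concentration and bisulfite conversion are treated as lossless
    for the copy bookkeeping; the ``concentrate_out_ul`` volume therefore
    cancels and is kept for auditability only.
    """

    plasma_ml: float = 4.0
    elution_ul: float = 200.0
    qc_draw_ul: float = 30.0
    concentrate_in_ul: float = 170.0
    concentrate_out_ul: float = 20.0
    bisulfite_elution_ul: float = 15.0
    template_per_well_ul: float = 6.0
    reaction_ul: float = 24.0

    def __post_init__(self) -> None:
        for name in (
            "plasma_ml", "elution_ul", "qc_draw_ul", "concentrate_in_ul",
            "concentrate_out_ul", "bisulfite_elution_ul",
            "template_per_well_ul", "reaction_ul",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"volume {name} must be > 0")
        if self.qc_draw_ul >= self.elution_ul:
            raise ValueError("qc_draw_ul must be smaller than the eluate volume")

    @property
    def per_ml_factor(self) -> float:
        """Multiplier taking conc (copies/ul reaction) to copies/ml plasma."""
        copies_in_reaction_per_conc = self.reaction_ul
        per_ul_template = copies_in_reaction_per_conc / self.template_per_well_ul
        in_bisulfite_eluate = per_ul_template * self.bisulfite_elution_ul
        # all DNA in concentrate_in_ul carried forward; scale up to full eluate
        in_full_eluate = in_bisulfite_eluate * self.elution_ul / self.concentrate_in_ul
        return in_full_eluate / self.plasma_ml


@dataclass(frozen=True)
class MarkerRatio:
    """Marker concentration relative to the ALB reference."""

    marker: str
    ratio: float
    ctdna_fraction_pct: float
    saturated: bool = False


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class DetectionResult:
    """Lowest fully detected quantity in a dilution series."""

    copies: int | None
    fully_detected_expected: tuple[float, ...] = ()
    non_monotone: bool = False


def poisson_concentration(
    positives: int,
    accepted: int,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    target: str = "",
    alpha: float = 0.05,
) -> QuantResult:
    """Convert droplet counts to copies/ul via the Poisson partition model.

    The binomial CI on the positive fraction uses the Wilson interval (stable
    at zero positives) and is propagated through the monotone transform
    ``-ln(1-p)/V``.  A fully positive well cannot be quantified and is
    returned with ``saturated=True`` and infinite point estimate.
    """
    if accepted <= 0:
        raise ValueError("accepted droplets must be > 0 to quantify a well")
    if not 0 <= positives <= accepted:
        raise ValueError("positives must lie in [0, accepted]")
    vol_ul = droplet_volume_nl * 1e-3
    p_lo, p_hi = proportion_confint(positives, accepted, alpha=alpha, method="wilson")
    ci = (_lam(p_lo) / vol_ul, _lam(p_hi) / vol_ul)
    if positives == accepted:
        return QuantResult(target, math.inf, math.inf, ci, True, positives, accepted)
    lam = _lam(positives / accepted)
    return QuantResult(target, lam, lam / vol_ul, ci, False, positives, accepted)


def _lam(p: float) -> float:
    if p >= 1.0:
        return math.inf
    return -math.log1p(-p)


def merge_wells(wells: Sequence[DropletWell]) -> DropletWell:
    """Pool replicate wells of one sample+target by summing droplet counts.

    Summing counts is the maximum-likelihood pooling under the Poisson model
    (as opposed to averaging per-well concentrations).
    """
    if not wells:
        raise ValueError("cannot merge an empty collection of wells")
    targets = {w.target for w in wells}
    samples = {w.sample_id for w in wells}
    if len(targets) > 1:
        raise ValueError(f"cannot merge wells with mixed targets: {sorted(targets)}")
    if len(samples) > 1:
        raise ValueError(f"cannot merge wells from mixed samples: {sorted(samples)}")
    if len(wells) == 1:
        return wells[0]
    return DropletWell(
        well_id="+".join(w.well_id for w in wells),
        sample_id=wells[0].sample_id,
        target=wells[0].target,
        positives=sum(w.positives for w in wells),
        accepted=sum(w.accepted for w in wells),
    )


def copies_per_ml_plasma(conc_per_ul: float, chain: VolumeChain) -> float:
    """Map a reaction concentration back to copies per ml of input plasma.

    Pure deterministic arithmetic through the volume chain; linear in the
    input concentration.
    """
    if conc_per_ul < 0:
        raise ValueError("concentration must be >= 0")
    return conc_per_ul * chain.per_ml_factor


def marker_ratio(marker: QuantResult, reference: QuantResult) -> MarkerRatio:
    """Marker/reference concentration ratio; x100 gives the ctDNA fraction."""
    if reference.conc_per_ul == 0:
        raise ValueError(
            f"reference {reference.target!r} concentration is zero: "
            "marker ratio undefined"
        )
    saturated = marker.saturated or reference.saturated
    ratio = marker.conc_per_ul / reference.conc_per_ul
    return MarkerRatio(marker.target, ratio, 100.0 * ratio, saturated)


def linearity_fit(expected: Sequence[float], measured: Sequence[float]) -> LinearFit:
    """Ordinary least-squares fit of measured on expected copies.

    R^2 = 1 - SS_res/SS_tot, with the convention R^2 = 0 when the response
    has zero variance (a constant carries no explainable variation).
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size != y.size:
        raise ValueError("expected and measured must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a linearity fit")
    if np.ptp(x) == 0:
        raise ValueError("expected copies have zero variance; fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 0.0
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return LinearFit(float(slope), float(intercept), r2)


def lowest_detected_quantity(
    series: pd.DataFrame,
    lob: Mapping[str, int] | None = None,
) -> DetectionResult:
    """Lowest dilution point at which every assay detects in all replicates.

    ``series`` needs columns ``expected_copies``, ``target``, ``replicate``
    and ``positives``.  A well counts as detected when its positives exceed
    the per-assay limit of blank if one is supplied, else when it has at
    least one positive droplet (the pre-LOB convention of the technical
    validation).  The result is the expected copy number of the smallest
    fully detected point, rounded to the nearest integer genomic copy.
    Detection that drops out at one point but reappears at a lower one is
    reported with ``non_monotone=True``.
    """
    required = {"expected_copies", "target", "replicate", "positives"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series table lacks columns: {sorted(missing)}")
    if series.empty:
        raise ValueError("empty dilution series")

    def detected(row: pd.Series) -> bool:
        if lob is not None:
            return row["positives"] > int(lob[row["target"]])
        return row["positives"] >= 1

    flags = series.apply(detected, axis=1)
    per_point = flags.groupby(series["expected_copies"]).all().sort_index()
    full = tuple(float(e) for e, ok in per_point.items() if ok)
    if not full:
        return DetectionResult(None, (), False)
    lowest = min(full)
    # non-monotone: some point above the lowest fully-detected one failed
    non_monotone = any(
        (not ok) and e > lowest for e, ok in per_point.items()
    )
    return DetectionResult(int(round(lowest)), full, non_monotone)


def quantify_wells(
    wells: Iterable[DropletWell],
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
    chain: VolumeChain | None = None,
) -> pd.DataFrame:
    """Quantify a collection of wells, pooling replicates per sample+target.

    Returns a tidy table with one row per (sample, target):
    positives, accepted, lambda, conc_per_ul, ci_lo, ci_hi and, when a
    volume chain is given, copies_per_ml.
    """
    groups: dict[tuple[str, str], list[DropletWell]] = {}
    for w in wells:
        groups.setdefault((w.sample_id, w.target), []).append(w)
    rows = []
    for (sample, target), ws in sorted(groups.items()):
        merged = merge_wells(ws)
        q = poisson_concentration(
            merged.positives, merged.accepted, droplet_volume_nl, target=target
        )
        row = {
            "sample_id": sample,
            "target": target,
            "positives": merged.positives,
            "accepted": merged.accepted,
            "lambda": q.lam,
            "conc_per_ul": q.conc_per_ul,
            "ci_lo": q.ci95[0],
            "ci_hi": q.ci95[1],
            "saturated": q.saturated,
        }
        if chain is not None:
            row["copies_per_ml"] = (
                math.inf if q.saturated else copies_per_ml_plasma(q.conc_per_ul, chain)
            )
        rows.append(row)
    return pd.DataFrame(rows)
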