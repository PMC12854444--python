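"""Limit of blank, multiplex positivity calling and cohort summaries.

The limit of blank (LOB) of each assay is the highest positive-droplet
count expected from analyte-free plasma at a stated confidence level.  It
is estimated nonparametrically from a blank cohort: sort the per-sample
blank counts ascending and take the value at rank ceil(confidence x n)
(1-based), an integer droplet count by construction.  A validation cohort
confirms the LOB when at most (1 - confidence) of its blanks exceed it.

A sample's marker is called positive when its positive droplets are
*strictly greater* than the marker's LOB; the sample is ctDNA-positive
when any marker is.  Cohort sensitivity is reported with a truncated Wald
binomial interval (the printed convention for this assay class), with the
exact Clopper-Pearson interval available behind a method tag.  The
Clopper-Pearson bound for 19/20 is (75%, 100%), not the Wald (85%, 100%):
the two are deliberately not interchangeable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import DEFAULT_PANEL, Panel
from .quantify import (
    DROPLET_VOLUME_NL,
    DropletWell,
    LinearFit,
    linearity_fit,
    marker_ratio,
    merge_wells,
    poisson_concentration,
)

MIN_BLANKS_DEFAULT = 20


@dataclass(frozen=True)
class LobTable:
    """Per-assay limit of blank in positive droplets."""

    lob: dict[str, int]
    n_blanks: dict[str, int]
    confidence: float = 0.95
    method: str = "rank"             # "rank" or "clsi"

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")
        for marker, value in self.lob.items():
            if value < 0:
                raise ValueError(f"LOB for {marker} must be >= 0")

    def __getitem__(self, marker: str) -> int:
        return self.lob[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.lob


@dataclass(frozen=True)
class SampleCall:
    """Per-sample multiplex positivity call."""

    sample_id: str
    positives: dict[str, int]                 # per marker, pooled droplets
    calls: dict[str, bool]                    # per marker positive?
    ctdna_fraction_pct: dict[str, float | None]
    overall_positive: bool
    n_positive_markers: int
    positive_conserved: bool                  # >=1 prostate-conserved marker
    positive_specific: bool                   # >=1 PCa-specific marker


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_positive: int
    sensitivity_pct: float
    ci95: tuple[float, float]                 # truncated, percent scale
    ci95_reported: tuple[int, int]            # rounded to integer percent
    ci_method: str
    n_all_five: int
    n_conserved_any: int
    n_specific_any: int
    per_marker_positive: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str                               # "exact" or "normal"


def blank_counts_from_wells(
    wells: Iterable[DropletWell], panel: Panel = DEFAULT_PANEL
) -> dict[str, np.ndarray]:
    """Per-marker arrays of blank positive-droplet counts (one per sample)."""
    counts: dict[str, dict[str, int]] = {m: {} for m in panel.markers}
    for w in wells:
        if w.target in counts:
            counts[w.target][w.sample_id] = (
                counts[w.target].get(w.sample_id, 0) + w.positives
            )
        # reference / QC targets carry no blank information
    return {
        m: np.array([per_sample[s] for s in sorted(per_sample)], dtype=int)
        for m, per_sample in counts.items()
    }


def _lob_one(counts: np.ndarray, confidence: float, method: str) -> int:
    srt = np.sort(np.asarray(counts, dtype=float))
    n = srt.size
    if method == "rank":
        rank = math.ceil(confidence * n)       # 1-based
        rank = min(max(rank, 1), n)
        return int(srt[rank - 1])
    if method == "clsi":
        # interpolated position 0.5 + confidence*n; rounded to an integer
        # droplet count since interpolation between counts is ill-defined
        pos = 0.5 + confidence * n
        lo = int(math.floor(pos))
        frac = pos - lo
        if lo >= n:
            value = srt[-1]
        elif lo < 1:
            value = srt[0]
        else:
            value = srt[lo - 1] + frac * (srt[min(lo, n - 1)] - srt[lo - 1])
        return int(round(value))
    raise ValueError(f"unknown LOB method {method!r}")


def estimate_lob(
    blank_counts: Mapping[str, Sequence[int]],
    confidence: float = 0.95,
    method: str = "rank",
    min_blanks: int = MIN_BLANKS_DEFAULT,
) -> LobTable:
    """Nonparametric per-assay LOB from blank positive-droplet counts.

    Warns (but proceeds) when a marker has fewer than ``min_blanks``
    blanks; raises on an empty blank set.
    """
    lob: dict[str, int] = {}
    n_blanks: dict[str, int] = {}
    for marker, counts in blank_counts.items():
        arr = np.asarray(list(counts), dtype=int)
        if arr.size == 0:
            raise ValueError(f"no blank measurements for {marker}")
        if arr.min() < 0:
            raise ValueError("droplet counts must be >= 0")
        if arr.size < min_blanks:
            warnings.warn(
                f"only {arr.size} blanks for {marker} (< {min_blanks}); "
                "LOB estimate will be unstable"
            )
        lob[marker] = _lob_one(arr, confidence, method)
        n_blanks[marker] = int(arr.size)
    return LobTable(lob, n_blanks, confidence, method)


def validate_lob(
    lob: LobTable, validation_counts: Mapping[str, Sequence[int]]
) -> dict[str, bool]:
    """Confirm a LOB on an independent blank cohort.

    A marker is confirmed when the fraction of validation blanks strictly
    exceeding its LOB is at most 1 - confidence.
    """
    verdict: dict[str, bool] = {}
    for marker, counts in validation_counts.items():
        arr = np.asarray(list(counts), dtype=int)
        if arr.size == 0:
            raise ValueError(f"no validation blanks for {marker}")
        frac = float((arr > lob[marker]).mean())
        verdict[marker] = frac <= (1.0 - lob.confidence)
    return verdict


def call_sample(
    wells: Sequence[DropletWell],
    lob: LobTable,
    panel: Panel = DEFAULT_PANEL,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
) -> SampleCall:
    """Call multiplex positivity for one sample.

    Replicate wells per target are pooled; a marker is positive when its
    pooled positive droplets strictly exceed the marker's LOB.  ctDNA
    fractions (marker/ALB concentration x 100) are None when the reference
    well is absent or empty.
    """
    samples = {w.sample_id for w in wells}
    if len(samples) != 1:
        raise ValueError(f"wells span multiple samples: {sorted(samples)}")
    sample_id = samples.pop()
    by_target: dict[str, list[DropletWell]] = {}
    for w in wells:
        by_target.setdefault(w.target, []).append(w)
    missing = [m for m in panel.markers if m not in by_target]
    if missing:
        raise ValueError(f"sample {sample_id}: missing marker wells {missing}")

    merged = {t: merge_wells(ws) for t, ws in by_target.items()}
    ref_quant = None
    if panel.reference in merged:
        ref_well = merged[panel.reference]
        ref_quant = poisson_concentration(
            ref_well.positives, ref_well.accepted, droplet_volume_nl,
            target=panel.reference,
        )

    positives: dict[str, int] = {}
    calls: dict[str, bool] = {}
    fractions: dict[str, float | None] = {}
    for marker in panel.markers:
        well = merged[marker]
        positives[marker] = well.positives
        calls[marker] = well.positives > lob[marker]
        if ref_quant is None or ref_quant.conc_per_ul == 0:
            fractions[marker] = None
        else:
            q = poisson_concentration(
                well.positives, well.accepted, droplet_volume_nl, target=marker
            )
            fractions[marker] = marker_ratio(q, ref_quant).ctdna_fraction_pct

    n_pos = sum(calls.values())
    return SampleCall(
        sample_id=sample_id,
        positives=positives,
        calls=calls,
        ctdna_fraction_pct=fractions,
        overall_positive=n_pos >= 1,
        n_positive_markers=n_pos,
        positive_conserved=any(calls[m] for m in panel.conserved),
        positive_specific=any(calls[m] for m in panel.specific),
    )


def wald_interval(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    """Truncated Wald binomial CI on the percent scale."""
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half)))


def clopper_pearson_interval(
    k: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact Clopper-Pearson binomial CI on the percent scale."""
    ci = stats.binomtest(k, n).proportion_ci(
        confidence_level=confidence, method="exact"
    )
    return (100.0 * ci.low, 100.0 * ci.high)


def summarize_cohort(
    calls: Sequence[SampleCall],
    panel: Panel = DEFAULT_PANEL,
    ci_method: str = "wald",
) -> CohortSummary:
    """Cohort sensitivity with binomial CI and marker-type breakdowns."""
    if not calls:
        raise ValueError("no sample calls to summarize")
    n = len(calls)
    n_pos = sum(c.overall_positive for c in calls)
    if ci_method == "wald":
        ci = wald_interval(n_pos, n)
    elif ci_method == "clopper-pearson":
        ci = clopper_pearson_interval(n_pos, n)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    n_markers = len(panel.markers)
    return CohortSummary(
        n=n,
        n_positive=n_pos,
        sensitivity_pct=100.0 * n_pos / n,
        ci95=ci,
        ci95_reported=(int(round(ci[0])), int(round(ci[1]))),
        ci_method=ci_method,
        n_all_five=sum(c.n_positive_markers == n_markers for c in calls),
        n_conserved_any=sum(c.positive_conserved for c in calls),
        n_specific_any=sum(c.positive_specific for c in calls),
        per_marker_positive={
            m: sum(c.calls[m] for c in calls) for m in panel.markers
        },
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a, from midranks of the pooled sample."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[: a.size].sum())
    return r1 - a.size * (a.size + 1) / 2.0


def group_difference_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max: int = 8,
) -> MannWhitneyResult:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test with midrank ties.

    Exact enumeration of all group assignments when the smaller group has
    at most ``exact_max`` observations (p = fraction of assignments whose U
    deviates from its null mean at least as much as observed); otherwise
    the normal approximation with tie-corrected variance.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    u_obs = _u_statistic(a, b)
    mean_u = n1 * n2 / 2.0

    if min(n1, n2) <= exact_max:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        dev_obs = abs(u_obs - mean_u)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - offset
            if abs(u - mean_u) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return MannWhitneyResult(u_obs, count / total, "exact")

    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u == 0:
        return MannWhitneyResult(u_obs, 1.0, "normal")
    z = (u_obs - mean_u) / math.sqrt(var_u)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(u_obs, min(1.0, p), "normal")


def duplex_multiplex_agreement(
    duplex_conc: Sequence[float], multiplex_conc: Sequence[float]
) -> LinearFit:
    """Least-squares agreement of multiplex on duplex concentrations."""
    return linearity_fit(duplex_conc, multiplex_conc)
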