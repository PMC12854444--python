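"""Synthetic inputs with known ground truth.

Two families of generators:

* **Beta matrices** emulating the 450K discovery input: a probes x samples
  matrix of beta values drawn from Beta distributions parameterized by
  (mean, concentration), with a handful of planted differentially
  methylated CpG islands (hyper- or hypomethylated in PRAD relative to
  REST) against an uninformative background.  Default sample sizes follow
  the discovery cohort of the assay: 553 prostate and 828 non-prostate
  samples.

* **Droplet wells** for the ddPCR stages.  The forward model is the one the
  Poisson quantification inverts: each template molecule (after
  per-molecule dropout) lands uniformly in one of ``total_droplets``
  droplets; false positives arise binomially over the unoccupied droplets.
  Cohort generators cover blank plasma (limit-of-blank estimation),
  dilution series (technical sensitivity and linearity), and mCRPC-like
  plasma cohorts (clinical sensitivity), each with ground truth.

Determinism: every cohort derives per-well substreams from its config seed
via ``numpy`` SeedSequence spawning, so outputs are byte-identical for a
fixed seed and independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import PRAD, REST, BetaMatrix
from .panel import DEFAULT_PANEL, Panel
from .quantify import DropletWell, VolumeChain

#: Blank-plasma ccfDNA median, copies per ml (test cohort of the assay).
BLANK_CCFDNA_COPIES_PER_ML: float = 841.0
#: mCRPC plasma ccfDNA median, copies per ml.
MCRPC_CCFDNA_COPIES_PER_ML: float = 2201.0

#: Default per-assay per-droplet false-positive rates for blank cohorts.
#: Chosen so mean blank counts per well ({0.8, 0.2, 0.3, 0.02, 0.2} at
#: 20,000 droplets) mirror the relative blank levels of the five assays
#: (ACTRT2 blankest-noisiest, DOCK2 essentially silent) while keeping the
#: rank-based LOB estimator at n=40 away from Poisson-quantile boundaries.
DEFAULT_BLANK_FP_RATES: dict[str, float] = {
    "ACTRT2": 4.0e-5,
    "EVX1": 1.0e-5,
    "HOXD13": 1.5e-5,
    "DOCK2": 1.0e-6,
    "HAPLN3": 1.0e-5,
}

DistSpec = float | int | tuple | Callable


@dataclass(frozen=True)
class BetaSimConfig:
    """Parameters of the synthetic discovery matrix.

    ``hyper_means`` gives the (PRAD, REST) Beta means for probes planted in
    hypermethylated islands; ``hypo_means`` the reverse pattern.
    ``concentration`` is the Beta precision (a+b): larger = tighter around
    the mean.  ``missing_rate`` is the probability that a *background*
    probe carries missing values; planted probes stay complete so the
    planted ground truth remains discoverable after complete-probe
    filtering.
    """

    n_prad: int = 553
    n_rest: int = 828
    n_probes: int = 20_000
    n_planted_islands: int = 9
    probes_per_island: int = 2
    hyper_means: tuple[float, float] = (0.9, 0.1)
    hypo_means: tuple[float, float] = (0.1, 0.9)
    background_mean: float = 0.5
    concentration: float = 50.0
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_prad", "n_rest", "n_probes", "n_planted_islands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.probes_per_island < 2:
            raise ValueError(
                "probes_per_island must be >= 2: the island selection rule "
                "requires more than one DMC per island"
            )
        if self.n_planted_islands * self.probes_per_island > self.n_probes:
            raise ValueError("planted probes exceed n_probes")
        for m in (*self.hyper_means, *self.hypo_means, self.background_mean):
            if not 0 < m < 1:
                raise ValueError("Beta means must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class WellSimConfig:
    """Instrument-level parameters of the droplet forward model."""

    total_droplets: int = 20_000
    droplet_volume_nl: float = 0.85
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be > 0")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be > 0")
        for r in (self.fp_rate, self.fn_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must lie in [0, 1)")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    planted_dmc_probe_ids: frozenset[str] = frozenset()
    planted_island_ids: frozenset[str] = frozenset()
    island_direction: dict[str, str] = field(default_factory=dict)
    true_copies: dict[str, dict[str, float]] = field(default_factory=dict)
    true_fractions: dict[str, float] = field(default_factory=dict)


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def generate_beta_matrix(
    config: BetaSimConfig,
) -> tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Synthesize a labeled beta matrix, probe annotation and ground truth.

    Planted islands alternate hyper/hypo direction.  The annotation (probe
    -> chrom/start/end/island_id, 0-based half-open) assigns planted probes
    to shared multi-probe islands; background probes alternate between
    singleton islands and no island at all.
    """
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_prad + config.n_rest
    n_planted = config.n_planted_islands * config.probes_per_island
    sample_ids = [f"PRAD_{i:04d}" for i in range(config.n_prad)] + [
        f"REST_{i:04d}" for i in range(config.n_rest)
    ]
    labels = pd.Series(
        [PRAD] * config.n_prad + [REST] * config.n_rest, index=sample_ids
    )
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]

    values = np.empty((config.n_probes, n_samples))
    a_bg, b_bg = _beta_params(config.background_mean, config.concentration)
    values[:] = rng.beta(a_bg, b_bg, size=(config.n_probes, n_samples))

    planted_probes: list[str] = []
    island_ids: list[str] = []
    island_direction: dict[str, str] = {}
    ann_rows = []
    for k in range(config.n_planted_islands):
        island = f"CGI_{k:04d}"
        island_ids.append(island)
        direction = "hyper" if k % 2 == 0 else "hypo"
        island_direction[island] = direction
        mean_prad, mean_rest = (
            config.hyper_means if direction == "hyper" else config.hypo_means
        )
        a_p, b_p = _beta_params(mean_prad, config.concentration)
        a_r, b_r = _beta_params(mean_rest, config.concentration)
        for j in range(config.probes_per_island):
            idx = k * config.probes_per_island + j
            probe = probe_ids[idx]
            planted_probes.append(probe)
            values[idx, : config.n_prad] = rng.beta(a_p, b_p, size=config.n_prad)
            values[idx, config.n_prad :] = rng.beta(a_r, b_r, size=config.n_rest)
            start = 10_000 * (k + 1) + 50 * j
            ann_rows.append(("chr1", start, start + 2, island, probe))

    for idx in range(n_planted, config.n_probes):
        start = 1_000_000 + 200 * idx
        # alternate singleton islands and island-free probes
        island = f"CGI_BG_{idx:06d}" if idx % 2 == 0 else None
        ann_rows.append(("chr2", start, start + 2, island, probe_ids[idx]))

    # probe-level missingness, background probes only
    if config.missing_rate > 0 and config.n_probes > n_planted:
        bg_idx = np.arange(n_planted, config.n_probes)
        hit = bg_idx[rng.random(bg_idx.size) < config.missing_rate]
        for idx in hit:
            k_cells = 1 + rng.binomial(n_samples - 1, 0.05)
            cols = rng.choice(n_samples, size=k_cells, replace=False)
            values[idx, cols] = np.nan

    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    annotation = pd.DataFrame(
        ann_rows, columns=["chrom", "start", "end", "island_id", "probe_id"]
    ).set_index("probe_id")
    truth = GroundTruth(
        planted_dmc_probe_ids=frozenset(planted_probes),
        planted_island_ids=frozenset(island_ids),
        island_direction=island_direction,
    )
    return BetaMatrix(frame, labels), annotation, truth


def simulate_well(
    true_copies: int,
    config: WellSimConfig,
    rng: np.random.Generator | None = None,
    well_id: str = "A01",
    sample_id: str = "sample",
    target: str = "target",
) -> DropletWell:
    """Forward-simulate one well.

    Each molecule surviving per-molecule dropout (``fn_rate``) is assigned
    uniformly to a droplet; false positives are drawn binomially at
    ``fp_rate`` over the unoccupied droplets only, so a positive droplet is
    never double-counted.
    """
    if true_copies < 0:
        raise ValueError("true_copies must be >= 0")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.total_droplets
    surviving = (
        int(rng.binomial(true_copies, 1.0 - config.fn_rate))
        if config.fn_rate > 0
        else int(true_copies)
    )
    occupied = (
        int(np.unique(rng.integers(0, n, size=surviving)).size) if surviving else 0
    )
    false_pos = (
        int(rng.binomial(n - occupied, config.fp_rate)) if config.fp_rate > 0 else 0
    )
    return DropletWell(well_id, sample_id, target, occupied + false_pos, n)


def default_blank_alb_copies(chain: VolumeChain | None = None) -> int:
    """Per-well ALB copies implied by the blank-plasma ccfDNA median.

    Maps the median blank ccfDNA load (copies/ml) through the default
    volume chain to template copies in one reaction.
    """
    chain = chain or VolumeChain()
    conc = BLANK_CCFDNA_COPIES_PER_ML / chain.per_ml_factor
    return int(round(conc * chain.reaction_ul))


def simulate_blank_cohort(
    n_samples: int,
    per_assay_fp: Mapping[str, float],
    config: WellSimConfig,
    alb_copies: int | None = None,
    spike: tuple[int, str, int] | None = None,
    panel: Panel = DEFAULT_PANEL,
    sample_prefix: str = "blank",
) -> list[DropletWell]:
    """Blank-plasma cohort: zero marker copies, assay-specific false positives.

    One well per sample per target.  ``spike`` = (sample index, target,
    copies) optionally plants a single high-signal outlier well, the
    pattern seen in real blank cohorts.  ALB carries the ccfDNA load
    (default derived from the blank-plasma median via the volume chain).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    unknown = set(per_assay_fp) - set(panel.markers)
    if unknown:
        raise ValueError(f"fp rates for unknown markers: {sorted(unknown)}")
    if alb_copies is None:
        alb_copies = default_blank_alb_copies()
    targets = panel.markers + (panel.reference,)
    streams = np.random.SeedSequence(config.seed).spawn(n_samples * len(targets))
    wells = []
    for i in range(n_samples):
        sample = f"{sample_prefix}{i:03d}"
        for t_idx, target in enumerate(targets):
            rng = np.random.default_rng(streams[i * len(targets) + t_idx])
            if target == panel.reference:
                copies = int(rng.poisson(alb_copies))
                cfg = replace(config, fp_rate=0.0)
            else:
                copies = 0
                cfg = replace(config, fp_rate=float(per_assay_fp.get(target, 0.0)))
            if spike is not None and spike[0] == i and spike[1] == target:
                copies = int(spike[2])
            wells.append(
                simulate_well(
                    copies, cfg, rng,
                    well_id=f"{sample_prefix[0].upper()}{i:03d}_{target}",
                    sample_id=sample, target=target,
                )
            )
    return wells


def simulate_dilution_series(
    start_copies: int,
    config: WellSimConfig,
    points: int = 7,
    factor: float = 3.0,
    background_copies: int = 1500,
    replicates: int = 3,
    panel: Panel = DEFAULT_PANEL,
) -> tuple[list[DropletWell], pd.DataFrame]:
    """Dilution series of marker template in a reference background.

    Point ``k`` carries expected marker copies ``start_copies / factor**k``
    for every marker assay (actual copies Poisson around the expectation);
    the background contributes reference (ALB) copies only.  Returns the
    wells plus a table mapping each well to its point and expected copies.
    """
    if start_copies <= 0:
        raise ValueError("start_copies must be > 0")
    if points < 1 or replicates < 1:
        raise ValueError("points and replicates must be >= 1")
    targets = panel.markers + (panel.reference,)
    streams = np.random.SeedSequence(config.seed).spawn(
        points * len(targets) * replicates
    )
    wells, rows = [], []
    s = 0
    for k in range(points):
        expected = start_copies / factor**k
        sample = f"dil{k:02d}"
        for target in targets:
            for r in range(replicates):
                rng = np.random.default_rng(streams[s]); s += 1
                mean = background_copies if target == panel.reference else expected
                copies = int(rng.poisson(mean))
                w = simulate_well(
                    copies, config, rng,
                    well_id=f"D{k:02d}{target}r{r}", sample_id=sample, target=target,
                )
                wells.append(w)
                if target != panel.reference:
                    rows.append(
                        {
                            "point": k,
                            "expected_copies": expected,
                            "target": target,
                            "replicate": r,
                            "well_id": w.well_id,
                            "positives": w.positives,
                            "accepted": w.accepted,
                        }
                    )
    return wells, pd.DataFrame(rows)


def _draw(dist: DistSpec, rng: np.random.Generator) -> float:
    """Draw one value from a distribution spec.

    Accepts a constant, ``("lognormal", median, sigma)``,
    ``("uniform", lo, hi)``, or a callable ``f(rng) -> float``.
    """
    if isinstance(dist, (int, float)):
        return float(dist)
    if callable(dist):
        return float(dist(rng))
    kind = dist[0]
    if kind == "lognormal":
        _, median, sigma = dist
        return float(rng.lognormal(math.log(median), sigma))
    if kind == "uniform":
        _, lo, hi = dist
        return float(rng.uniform(lo, hi))
    raise ValueError(f"unknown distribution spec {dist!r}")


def simulate_mcrpc_cohort(
    n_samples: int,
    config: WellSimConfig,
    ctdna_fraction_dist: DistSpec = ("lognormal", 0.10, 1.0),
    total_copies_dist: DistSpec = ("lognormal", 1500.0, 1.0),
    marker_dropout: float | Mapping[str, float] = 0.05,
    panel: Panel = DEFAULT_PANEL,
    sample_prefix: str = "mCRPC",
) -> tuple[list[DropletWell], GroundTruth]:
    """mCRPC-like plasma cohort with known ctDNA fractions.

    Per sample: total ccfDNA copies and a ctDNA fraction are drawn; every
    marker carries ``fraction x total`` expected copies, independently
    zeroed with probability ``marker_dropout`` (biological heterogeneity of
    individual markers); ALB carries the total.  Defaults put the median
    template load at ~1500 copies per well (the mCRPC ccfDNA median mapped
    through the 2 ml volume chain), median fraction at 10%, and 5% marker
    dropout.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(n_samples)
    wells: list[DropletWell] = []
    truth = GroundTruth()
    for i in range(n_samples):
        rng = np.random.default_rng(streams[i])
        sample = f"{sample_prefix}{i + 1:02d}"
        total = _draw(total_copies_dist, rng)
        fraction = min(_draw(ctdna_fraction_dist, rng), 1.0)
        truth.true_fractions[sample] = fraction
        truth.true_copies[sample] = {}
        for target in panel.markers + (panel.reference,):
            if target == panel.reference:
                mean = total
            else:
                drop = (
                    marker_dropout.get(target, 0.0)
                    if isinstance(marker_dropout, Mapping)
                    else marker_dropout
                )
                mean = 0.0 if rng.random() < drop else fraction * total
            truth.true_copies[sample][target] = mean
            copies = int(rng.poisson(mean)) if mean > 0 else 0
            wells.append(
                simulate_well(
                    copies, config, rng,
                    well_id=f"P{i:02d}_{target}", sample_id=sample, target=target,
                )
            )
    return wells, truth
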