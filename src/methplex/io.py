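"""File formats and run configuration.

Well tables are comma-separated with header
``well,sample_id,target,positives,accepted_droplets`` (instrument-export
convention); beta matrices and annotations are tab-separated; genomic
coordinates are 0-based half-open; LOB tables and cohort summaries are
JSON.  Decimal separator is always '.' regardless of locale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .discovery import BetaMatrix, RfeConfig
from .lob import LobTable, SampleCall
from .panel import DEFAULT_PANEL, Panel
from .quantify import DropletWell, VolumeChain
from .simulate import DEFAULT_BLANK_FP_RATES, WellSimConfig

WELL_COLUMNS = ["well", "sample_id", "target", "positives", "accepted_droplets"]


def read_well_table(path: str | Path) -> list[DropletWell]:
    """Read a droplet-count CSV into typed wells.

    Malformed rows are rejected with their line number (header = line 1);
    a well with more positives than accepted droplets is a hard error.  An
    empty table returns an empty list with a warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing_cols = set(WELL_COLUMNS) - set(frame.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    if frame.empty:
        warnings.warn(f"{path}: well table is empty")
        return []
    wells = []
    for i, row in frame.iterrows():
        line = i + 2  # header occupies line 1
        try:
            positives = int(row["positives"])
            accepted = int(row["accepted_droplets"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {line}: non-integer droplet count") from exc
        try:
            wells.append(
                DropletWell(
                    str(row["well"]), str(row["sample_id"]), str(row["target"]),
                    positives, accepted,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path} line {line}: {exc}") from exc
    return wells


def write_well_table(wells: Iterable[DropletWell], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "well": w.well_id,
                "sample_id": w.sample_id,
                "target": w.target,
                "positives": w.positives,
                "accepted_droplets": w.accepted,
            }
            for w in wells
        ],
        columns=WELL_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_beta_matrix(path: str | Path, labels_path: str | Path) -> BetaMatrix:
    """Read a probes-x-samples beta TSV plus a sample->group label TSV.

    Empty cells and 'NA' parse as missing.  Every matrix sample must carry
    a label; labels for absent samples are tolerated with a warning.
    """
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicated probe ids {list(dups[:5])}")
    labels_frame = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(labels_frame.columns):
        raise ValueError(f"{labels_path}: need columns sample_id, group")
    labels = labels_frame.set_index("sample_id")["group"]
    extra = set(labels.index) - set(values.columns)
    if extra:
        warnings.warn(
            f"{labels_path}: labels for {len(extra)} samples absent from the matrix"
        )
        labels = labels.drop(index=sorted(extra))
    unlabeled = set(values.columns) - set(labels.index)
    if unlabeled:
        raise ValueError(f"{path}: samples without labels: {sorted(unlabeled)[:5]}")
    return BetaMatrix(values.astype(float), labels)


def write_beta_matrix(
    matrix: BetaMatrix, path: str | Path, labels_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
    lab = matrix.labels.rename("group").rename_axis("sample_id").reset_index()
    lab.to_csv(labels_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """BED-like probe annotation: chrom, start, end, island_id, probe_id."""
    frame = pd.read_csv(
        path, sep="\t",
        names=["chrom", "start", "end", "island_id", "probe_id"],
        dtype={"chrom": str, "island_id": str, "probe_id": str},
        comment="#",
    )
    frame["island_id"] = frame["island_id"].replace(".", None)
    if frame["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated probe ids in annotation")
    return frame.set_index("probe_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()[["chrom", "start", "end", "island_id", "probe_id"]]
    out["island_id"] = out["island_id"].fillna(".")
    out.to_csv(path, sep="\t", header=False, index=False)


def write_lob(lob: LobTable, path: str | Path) -> None:
    payload = {
        "lob": lob.lob,
        "n_blanks": lob.n_blanks,
        "confidence": lob.confidence,
        "method": lob.method,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_lob(path: str | Path) -> LobTable:
    payload = json.loads(Path(path).read_text())
    return LobTable(
        {k: int(v) for k, v in payload["lob"].items()},
        {k: int(v) for k, v in payload.get("n_blanks", {}).items()},
        float(payload.get("confidence", 0.95)),
        str(payload.get("method", "rank")),
    )


def calls_to_frame(calls: Sequence[SampleCall], panel: Panel = DEFAULT_PANEL) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict = {"sample_id": c.sample_id}
        for m in panel.markers:
            row[f"{m}_positives"] = c.positives[m]
            row[f"{m}_call"] = c.calls[m]
            frac = c.ctdna_fraction_pct[m]
            row[f"{m}_fraction_pct"] = np.nan if frac is None else frac
        row["overall_positive"] = c.overall_positive
        row["n_positive_markers"] = c.n_positive_markers
        row["positive_conserved"] = c.positive_conserved
        row["positive_specific"] = c.positive_specific
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_calls(frame: pd.DataFrame, panel: Panel = DEFAULT_PANEL) -> list[SampleCall]:
    calls = []
    for _, row in frame.iterrows():
        positives = {m: int(row[f"{m}_positives"]) for m in panel.markers}
        marker_calls = {m: bool(row[f"{m}_call"]) for m in panel.markers}
        fractions = {
            m: (None if pd.isna(row[f"{m}_fraction_pct"]) else float(row[f"{m}_fraction_pct"]))
            for m in panel.markers
        }
        calls.append(
            SampleCall(
                sample_id=str(row["sample_id"]),
                positives=positives,
                calls=marker_calls,
                ctdna_fraction_pct=fractions,
                overall_positive=bool(row["overall_positive"]),
                n_positive_markers=int(row["n_positive_markers"]),
                positive_conserved=bool(row["positive_conserved"]),
                positive_specific=bool(row["positive_specific"]),
            )
        )
    return calls


def write_calls(calls: Sequence[SampleCall], path: str | Path,
                panel: Panel = DEFAULT_PANEL) -> None:
    calls_to_frame(calls, panel).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path, panel: Panel = DEFAULT_PANEL) -> list[SampleCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t"), panel)


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs; YAML round-trips."""

    seed: int = 0
    out_dir: str = "methplex_run"
    total_droplets: int = 20_000
    droplet_volume_nl: float = 0.85
    lob_confidence: float = 0.95
    lob_method: str = "rank"
    ci_method: str = "wald"
    n_blanks: int = 40
    n_patients: int = 20
    marker_dropout: float = 0.05
    blank_fp_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BLANK_FP_RATES)
    )
    volume_chain: dict[str, float] = field(default_factory=dict)
    rfe: dict = field(default_factory=dict)
    qc_overrides: dict = field(default_factory=dict)

    def well_config(self, seed_offset: int = 0) -> WellSimConfig:
        return WellSimConfig(
            total_droplets=self.total_droplets,
            droplet_volume_nl=self.droplet_volume_nl,
            seed=self.seed + seed_offset,
        )

    def chain(self) -> VolumeChain:
        return VolumeChain(**self.volume_chain)

    def rfe_config(self) -> RfeConfig:
        return RfeConfig(seed=self.seed, **self.rfe)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
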