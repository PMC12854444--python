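"""End-to-end orchestration: simulate -> qc -> lob -> call -> report.

Stages run in dependency order; every artifact is hashed into a manifest so
a rerun from the same seed can be verified byte-for-byte.  Samples failing
a severity=fail QC rule are excluded from cohort statistics and the
exclusion is logged by rule name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from .io import (
    RunConfig,
    read_calls,
    read_lob,
    read_well_table,
    write_calls,
    write_lob,
    write_well_table,
)
from .lob import blank_counts_from_wells, call_sample, estimate_lob, summarize_cohort, validate_lob
from .panel import DEFAULT_PANEL
from .qc import check_droplet_count, failing_samples
from .simulate import simulate_blank_cohort, simulate_mcrpc_cohort
from .viz import fraction_stack_plot, lob_dot_plot

log = logging.getLogger("methplex")

STAGES = ("simulate", "lob", "call", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, stages: Sequence[str] | None = None, plots: bool = True
) -> dict[str, str]:
    """Execute the requested stages; returns {artifact: sha256} manifest."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(
            f"unknown stage(s) {sorted(unknown)}; valid stages: {list(STAGES)}"
        )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = DEFAULT_PANEL
    artifacts: list[Path] = []

    if "simulate" in stages:
        blanks = simulate_blank_cohort(
            config.n_blanks, config.blank_fp_rates, config.well_config(0),
            panel=panel, sample_prefix="blankT",
        )
        validation = simulate_blank_cohort(
            config.n_blanks, config.blank_fp_rates, config.well_config(1),
            panel=panel, sample_prefix="blankV",
        )
        patients, _truth = simulate_mcrpc_cohort(
            config.n_patients, config.well_config(2),
            marker_dropout=config.marker_dropout, panel=panel,
        )
        write_well_table(blanks, out / "blank_test_wells.csv")
        write_well_table(validation, out / "blank_validation_wells.csv")
        write_well_table(patients, out / "patient_wells.csv")
        artifacts += [
            out / "blank_test_wells.csv",
            out / "blank_validation_wells.csv",
            out / "patient_wells.csv",
        ]
        log.info("simulate: %d blanks x2, %d patients", config.n_blanks,
                 config.n_patients)

    if "lob" in stages:
        blanks = read_well_table(out / "blank_test_wells.csv")
        validation = read_well_table(out / "blank_validation_wells.csv")
        table = estimate_lob(
            blank_counts_from_wells(blanks, panel),
            confidence=config.lob_confidence, method=config.lob_method,
        )
        confirmed = validate_lob(table, blank_counts_from_wells(validation, panel))
        write_lob(table, out / "lob.json")
        (out / "lob_validation.json").write_text(
            json.dumps(confirmed, indent=2, sort_keys=True) + "\n"
        )
        artifacts += [out / "lob.json", out / "lob_validation.json"]
        log.info("lob: %s (validation %s)", table.lob, confirmed)

    if "call" in stages:
        patients = read_well_table(out / "patient_wells.csv")
        table = read_lob(out / "lob.json")
        # droplet-count QC gate; failing samples are excluded and logged
        verdicts = [check_droplet_count(w) for w in patients]
        failed_wells = failing_samples(verdicts)
        bad_samples = {
            w.sample_id for w in patients if w.well_id in failed_wells
        }
        for sample in sorted(bad_samples):
            rules = sorted(
                {r for w in patients if w.sample_id == sample
                 for r in failed_wells.get(w.well_id, [])}
            )
            log.warning("excluding sample %s: failed QC rules %s", sample, rules)
        by_sample: dict[str, list] = {}
        for w in patients:
            if w.sample_id not in bad_samples:
                by_sample.setdefault(w.sample_id, []).append(w)
        calls = [
            call_sample(ws, table, panel, config.droplet_volume_nl)
            for _, ws in sorted(by_sample.items())
        ]
        write_calls(calls, out / "calls.tsv", panel)
        artifacts.append(out / "calls.tsv")
        log.info("call: %d samples, %d positive", len(calls),
                 sum(c.overall_positive for c in calls))

    if "report" in stages:
        calls = read_calls(out / "calls.tsv", panel)
        summary = summarize_cohort(calls, panel, ci_method=config.ci_method)
        payload = {
            "n": summary.n,
            "n_positive": summary.n_positive,
            "sensitivity_pct": summary.sensitivity_pct,
            "ci95_pct": list(summary.ci95),
            "ci95_reported_pct": list(summary.ci95_reported),
            "ci_method": summary.ci_method,
            "n_all_five": summary.n_all_five,
            "n_conserved_any": summary.n_conserved_any,
            "n_specific_any": summary.n_specific_any,
            "per_marker_positive": summary.per_marker_positive,
        }
        (out / "cohort_summary.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        artifacts.append(out / "cohort_summary.json")
        if plots:
            fraction_stack_plot(calls, out / "ctdna_fractions.png", panel)
            if (out / "blank_test_wells.csv").exists() and (out / "lob.json").exists():
                blanks = read_well_table(out / "blank_test_wells.csv")
                lob_dot_plot(
                    blank_counts_from_wells(blanks, panel),
                    read_lob(out / "lob.json"),
                    out / "blank_dotplot.png", panel,
                )
        log.info("report: sensitivity %.1f%% CI %s", summary.sensitivity_pct,
                 summary.ci95_reported)

    manifest = {p.name: _sha256(p) for p in artifacts}
    config_text = json.dumps(config.to_dict(), sort_keys=True)
    run_log = {
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "manifest": manifest,
    }
    (out / "manifest.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n"
    )
    return manifest
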