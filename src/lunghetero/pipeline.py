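"""End-to-end orchestration: generate -> ct-quant -> oemri-quant -> stats.

One seed governs the whole run; per-subject seeds are derived from it, so a
re-run with the same config produces a bit-identical output bundle (cohort
CSVs, per-subject result JSON, stats report, run log — the log carries no
timestamps for exactly this reason).
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import ct as ct_quant
from . import io as lio
from . import oemri as oemri_quant
from . import stats as cohort_stats
from .config import RunConfig, save_config
from .synth import generate_cohort, generate_ct_phantom, generate_oemri_phantom

__all__ = ["run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "ct-quant", "oemri-quant", "stats")

CT_CANDIDATES = ["age", "bmi", "lav_pct", "sd_lav"]
MRI_CANDIDATES = ["age", "bmi", "mrer", "sd_rer"]
OUTCOMES = ["fev1", "dlco", "pao2"]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


class _RunLog:
    """Deterministic run log: ordered lines, no timestamps."""

    def __init__(self) -> None:
        self.lines: list[str] = []

    def __call__(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = ALL_STAGES) -> Path:
    """Run the requested stages; returns the output directory.

    Stage hand-off is file-based: each stage reads what the previous one
    wrote, so individual stages can be re-run on existing outputs. Failures
    inside a per-subject loop are re-raised naming the subject.
    """
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)} (valid: {ALL_STAGES})")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logbuf = _RunLog()
    save_config(config, out / "run_config.yaml")

    if "synth" in stages:
        _stage_synth(config, out, logbuf)
    if "ct-quant" in stages:
        _stage_ct(config, out, logbuf)
    if "oemri-quant" in stages:
        _stage_oemri(config, out, logbuf)
    if "stats" in stages:
        _stage_stats(config, out, logbuf)

    logbuf.write(out / "run_log.txt")
    return out


def _subject_dirs(out: Path) -> list[Path]:
    root = out / "subjects"
    if not root.exists():
        raise FileNotFoundError(f"no subjects directory in {out}; run the synth stage first")
    return sorted(p for p in root.iterdir() if p.is_dir())


def _stage_synth(config: RunConfig, out: Path, logbuf) -> None:
    cohort_cfg = replace(config.cohort, seed=config.seed)
    table, specs, ground = generate_cohort(cohort_cfg, config.ct, config.oemri)
    lio.write_table(table, out / "cohort_true.csv")
    ground.covariate_means.to_csv(out / "ground_truth.csv", index=False, float_format="%.15g")
    logbuf(f"synth: generated cohort of {len(specs)} subjects (seed {config.seed})")
    for spec in specs:
        sdir = out / "subjects" / spec.subject_id
        try:
            volume, gt = generate_ct_phantom(spec.ct_config)
            lio.write_volume(volume, sdir / "ct.nii")
            series = generate_oemri_phantom(spec.oemri_config, gt)
            lio.write_series(series, sdir / "oemri")
        except Exception as exc:
            raise RuntimeError(f"synth stage failed for subject {spec.subject_id}") from exc
        logbuf(
            f"synth: {spec.subject_id} ({spec.group}) "
            f"true LAV fraction {gt.lav_fraction_whole:.4f}"
        )


def _stage_ct(config: RunConfig, out: Path, logbuf) -> None:
    for sdir in _subject_dirs(out):
        sid = sdir.name
        try:
            volume = lio.read_volume(sdir / "ct.nii")
            result = ct_quant.analyze_volume(
                volume,
                threshold_hu=config.lav_threshold_hu,
                n_partitions=config.ct_partitions,
            )
            _dump_json(result.to_dict(), sdir / "lav.json")
            pd.DataFrame(
                {
                    "partition": np.arange(result.n_partitions),
                    "lav_percent": result.all_partition_lav_percent,
                    "kept": [k in result.kept for k in range(result.n_partitions)],
                }
            ).to_csv(sdir / "lav_partitions.csv", index=False, float_format="%.15g")
        except Exception as exc:
            raise RuntimeError(f"ct-quant stage failed for subject {sid}") from exc
        logbuf(
            f"ct-quant: {sid} LAV% {result.lav_percent_whole:.3f} "
            f"SD-LAV {result.sd_lav:.3f} shift {result.calibration_shift:+.2f} HU"
        )


def _stage_oemri(config: RunConfig, out: Path, logbuf) -> None:
    for sdir in _subject_dirs(out):
        sid = sdir.name
        try:
            series = lio.read_series(sdir / "oemri")
            result = oemri_quant.analyze_series(
                series,
                window_fraction=config.window_fraction,
                n_partitions=config.oemri_partitions,
            )
            _dump_json(result.to_dict(), sdir / "rer.json")
        except Exception as exc:
            raise RuntimeError(f"oemri-quant stage failed for subject {sid}") from exc
        logbuf(f"oemri-quant: {sid} MRER {result.mrer:.3f} SD-RER {result.sd_rer:.3f}")


def _stage_stats(config: RunConfig, out: Path, logbuf) -> None:
    table = lio.read_table(out / "cohort_true.csv")
    measured = table.copy()
    for sdir in _subject_dirs(out):
        sid = sdir.name
        row = measured["subject_id"] == sid
        lav = json.loads((sdir / "lav.json").read_text())
        rer = json.loads((sdir / "rer.json").read_text())
        measured.loc[row, "lav_pct"] = lav["lav_percent_whole"]
        measured.loc[row, "sd_lav"] = lav["sd_lav"]
        measured.loc[row, "mrer"] = rer["mrer"]
        measured.loc[row, "sd_rer"] = rer["sd_rer"]
    lio.write_table(measured, out / "cohort_measured.csv")

    copd = measured[measured["group"] == "COPD"]
    report: dict = {"n_copd": int(len(copd)), "n_control": int((measured["group"] == "control").sum())}
    report["group_comparison_mrer"] = cohort_stats.compare_groups(measured, "mrer").to_dict()
    correlations = []
    for xvar in ("lav_pct", "sd_lav", "mrer", "sd_rer"):
        for yvar in OUTCOMES:
            correlations.append(cohort_stats.correlate(copd, xvar, yvar).to_dict())
    correlations.append(cohort_stats.correlate(copd, "lav_pct", "mrer").to_dict())
    correlations.append(cohort_stats.correlate(copd, "sd_lav", "sd_rer").to_dict())
    report["correlations"] = correlations
    report["stepwise_ct"] = {
        o: cohort_stats.stepwise_regression(copd, o, CT_CANDIDATES).to_dict() for o in OUTCOMES
    }
    report["stepwise_mri"] = {
        o: cohort_stats.stepwise_regression(copd, o, MRI_CANDIDATES).to_dict() for o in OUTCOMES
    }
    _dump_json(report, out / "stats_report.json")
    _write_markdown_report(report, out / "stats_report.md")
    gc = report["group_comparison_mrer"]
    logbuf(
        "stats: MRER COPD vs control "
        f"{gc['summaries']['COPD']['mean']:.2f} vs {gc['summaries']['control']['mean']:.2f} "
        f"({gc['test_used']}, p={gc['pvalue']:.3g})"
    )


def _write_markdown_report(report: dict, path: Path) -> None:
    lines = ["# Cohort statistics", ""]
    gc = report["group_comparison_mrer"]
    lines += [
        "## Group comparison: MRER",
        "",
        "| group | n | median (q25, q75) | mean +/- SD |",
        "|---|---|---|---|",
    ]
    for g, s in gc["summaries"].items():
        lines.append(
            f"| {g} | {s['n']} | {s['median']:.2f} ({s['q25']:.2f}, {s['q75']:.2f}) "
            f"| {s['mean']:.2f} +/- {s['sd']:.2f} |"
        )
    lines += ["", f"Test: {gc['test_used']}, p = {gc['pvalue']:.3g}", ""]
    lines += ["## Bivariate correlations (COPD subjects)", "",
              "| x | y | r | p | method |", "|---|---|---|---|---|"]
    for c in report["correlations"]:
        lines.append(f"| {c['x']} | {c['y']} | {c['r']:.3f} | {c['pvalue']:.3g} | {c['method']} |")
    for label, key in (("CT indices", "stepwise_ct"), ("OEMRI indices", "stepwise_mri")):
        lines += ["", f"## Stepwise regression ({label})", ""]
        for outcome, rep in report[key].items():
            lines += [f"### outcome: {outcome}", "",
                      "| variable | std beta | p |", "|---|---|---|"]
            for var in rep["candidates"]:
                if var in rep["selected"]:
                    sel = rep["selected"][var]
                    lines.append(f"| {var} | {sel['beta']:.3f} | {sel['pvalue']:.3g} |")
                else:
                    p = rep["unselected"][var]["pvalue"]
                    lines.append(f"| {var} | - | {p:.3g} |")
            lines += ["", f"cumulative R^2 = {rep['r_squared']:.3f}", ""]
    path.write_text("\n".join(lines) + "\n")
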