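"""End-to-end orchestration: parse → dedup → cohort → descriptives →
stratified signals → reports.

A run consumes either a directory of FAERS ASCII tables or a synthetic
generator configuration, and produces CSV tables plus a JSON manifest
recording the report count surviving each stage (total parsed, after
deduplication, COVID-19 cohort, target and comparator group sizes) —
the identification flow of the study, in machine-readable form.

Outputs are staged in a temporary directory and moved into place only
when every stage succeeds, so a failed run leaves no partial output.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from . import io as faers_io
from .cohort import TARGET, CohortSpec, build_cohort
from .dedup import deduplicate
from .descriptives import characteristics, sex_ratio, top_events
from .records import TableKind
from .signals import (
    StratumSpec,
    default_strata,
    run_stratified,
    soc_long_table,
)
from .synthetic import SyntheticConfig, generate, toy_pt_to_soc


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    """Paths and key numbers of one completed run."""

    output_dir: Path
    manifest: Dict


def _load_tables(input_dir: Path):
    tables = {}
    issues = {}
    for kind in TableKind:
        matches = sorted(p for p in input_dir.iterdir()
                         if p.is_file()
                         and p.name.upper().startswith(kind.value))
        if not matches:
            raise FileNotFoundError(
                f"no {kind.value} table found in {input_dir}")
        records: List = []
        table_issues: List = []
        for path in matches:
            recs, probs = faers_io.read_table(path, kind)
            records.extend(recs)
            table_issues.extend(probs)
        tables[kind] = records
        issues[kind] = table_issues
    return tables, issues


def run(input_dir=None,
        synthetic_config: Optional[SyntheticConfig] = None,
        cohort_spec: Optional[CohortSpec] = None,
        strata: Optional[Sequence[StratumSpec]] = None,
        pt_to_soc: Optional[Mapping[str, str]] = None,
        denominator: str = "pairs",
        out_dir=None,
        top_k: int = 15) -> PipelineResult:
    """Execute the full pipeline and write CSV tables plus a manifest.

    Exactly one of ``input_dir`` (existing FAERS ASCII tables) or
    ``synthetic_config`` (generate them first) must be given.  When
    running on synthetic data the toy vocabulary's PT → SOC mapping is
    used unless one is supplied.
    """
    if (input_dir is None) == (synthetic_config is None):
        raise ValueError(
            "exactly one of input_dir / synthetic_config is required")
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)

    staging = Path(tempfile.mkdtemp(prefix="pvror-run-"))
    manifest: Dict = {"stages": {}, "denominator": denominator}
    try:
        stage = "generate"
        if synthetic_config is not None:
            data_dir = staging / "synthetic_input"
            generate(synthetic_config, data_dir)
            manifest["seed"] = synthetic_config.seed
            if pt_to_soc is None:
                pt_to_soc = toy_pt_to_soc(synthetic_config.vocabulary)
        else:
            data_dir = Path(input_dir)

        stage = "parse"
        tables, issues = _load_tables(data_dir)
        manifest["stages"]["parsed_reports"] = len(tables[TableKind.DEMO])
        manifest["parse_issues"] = {
            kind.value: len(issue_list)
            for kind, issue_list in issues.items()}

        stage = "dedup"
        reports = deduplicate(tables[TableKind.DEMO])
        manifest["stages"]["after_dedup"] = len(reports)

        stage = "cohort"
        spec = cohort_spec or CohortSpec()
        cohort = build_cohort(reports, tables[TableKind.DRUG],
                              tables[TableKind.REAC],
                              tables[TableKind.INDI],
                              tables[TableKind.OUTC], spec)
        n_target = sum(1 for c in cohort if c.group == TARGET)
        manifest["stages"]["covid_cohort"] = len(cohort)
        manifest["stages"]["target_group"] = n_target
        manifest["stages"]["comparator_group"] = len(cohort) - n_target
        if not cohort:
            raise ValueError("cohort is empty after indication filtering")

        stage = "descriptives"
        characteristics(cohort).to_csv(
            staging / "characteristics.csv", index=False)
        for group, tag in ((TARGET, "target"), ("COMPARATOR", "comparator")):
            top_events(cohort, group, k=top_k).to_csv(
                staging / f"top_events_{tag}.csv", index=False)
            top_events(cohort, group, k=top_k, weight="fatal-only").to_csv(
                staging / f"top_fatal_events_{tag}.csv", index=False)
        ratio = sex_ratio(cohort, TARGET)
        manifest["sex_ratio_target"] = ratio

        stage = "signals"
        stratified = run_stratified(cohort, strata or default_strata(),
                                    pt_to_soc=pt_to_soc,
                                    denominator=denominator)
        manifest["signal_counts"] = {}
        for name, frame in stratified.items():
            frame.to_csv(staging / f"signals_{name}.csv", index=False)
            manifest["signal_counts"][name] = int(frame["is_signal"].sum())
        soc_long_table(stratified).to_csv(
            staging / "soc_signal_counts_long.csv", index=False)

        stage = "reports"
        (staging / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    except Exception as exc:
        shutil.rmtree(staging, ignore_errors=True)
        raise PipelineError(stage, exc) from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    for path in sorted(staging.iterdir()):
        destination = out_dir / path.name
        if destination.exists():
            if destination.is_dir():
                shutil.rmtree(destination)
            else:
                destination.unlink()
        shutil.move(str(path), destination)
    staging.rmdir()
    return PipelineResult(output_dir=out_dir, manifest=manifest)


def load_config(path) -> Dict:
    """Read a YAML run configuration (see the CLI module)."""
    return yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}


def synthetic_config_from_dict(data: Mapping) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from plain YAML/JSON data,
    accepting only known field names."""
    kwargs = dict(data)
    if "planted_effects" in kwargs:
        kwargs["planted_effects"] = {
            str(pt): float(theta)
            for pt, theta in kwargs["planted_effects"].items()}
    for key in ("age_probs", "sex_probs", "occupation_probs",
                "country_probs", "outcome_probs", "dosage_probs"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "vocabulary" in kwargs:
        kwargs["vocabulary"] = tuple(
            (str(pt), str(soc), float(p))
            for pt, soc, p in kwargs["vocabulary"])
    return SyntheticConfig(**kwargs)
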