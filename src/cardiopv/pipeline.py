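"""End-to-end orchestration: ingest -> clean -> cohorts -> disproportionality -> outcomes.

One :func:`run` call reads a batch of quarterly tables plus the two
dictionaries, applies the three cleaning stages, and writes six artifacts to
the output directory:

- ``cohort_summary.tsv``   baseline tabulation of cardiovascular cases
- ``overall_disprop.tsv``  overall cardiovascular analysis per exposure group
- ``smq_disprop.tsv``      per-SMQ analyses
- ``pt_signals.tsv``       per-PT analyses with both signal criteria
- ``outcome_profiles.tsv`` outcome severity, overall and per SMQ stratum
- ``indication_restricted.tsv``  the same disproportionality analyses among
  cases with malignant-tumour indications
- ``manifest.json``        config hash, package version and stage-by-stage
  record counts (in = kept + dropped at every stage)

Any stage failure aborts the run, removes partial outputs, and re-raises
with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort import (
    CANCER_INDICATION_TERMS,
    build_cohorts,
    classify_exposure,
    cohort_summary,
    deduplicate,
    filter_suspect,
    restrict_to_indications,
)
from .disprop import Comparator, CountingUnit, analyze_all, round_results
from .faers_io import Dialect, read_drug_archive, read_reports, read_smq_map
from .model import ExposureGroup
from .outcomes import outcome_table

log = logging.getLogger(__name__)

ARTIFACTS = (
    "cohort_summary.tsv",
    "overall_disprop.tsv",
    "smq_disprop.tsv",
    "pt_signals.tsv",
    "outcome_profiles.tsv",
    "indication_restricted.tsv",
    "manifest.json",
)


class RunConfig(BaseModel):
    """Configuration of one pipeline run (also loadable from YAML/JSON)."""

    input_dir: Path
    drug_archive: Path
    smq_map: Path
    output_dir: Path
    delimiter: str = "$"
    comparator: Comparator = Comparator.NEITHER
    counting_unit: CountingUnit = CountingUnit.PER_PT
    indication_terms: tuple[str, ...] = CANCER_INDICATION_TERMS
    display_precision: int = Field(default=3, ge=0, le=10)
    seed: int = 0  # reserved for resampling extensions; the analysis itself is deterministic

    @classmethod
    def from_file(cls, path: Path | str) -> "RunConfig":
        import yaml

        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


@dataclass
class RunResult:
    output_dir: Path
    manifest: dict

    def path(self, artifact: str) -> Path:
        return self.output_dir / artifact


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis; see the module docstring for outputs."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        def save(df: pd.DataFrame, name: str) -> None:
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)

        stage = "ingest"
        dialect = Dialect().with_delimiter(config.delimiter)
        rs = read_reports(config.input_dir, dialect)
        archive = read_drug_archive(config.drug_archive)
        smq_map = read_smq_map(config.smq_map)
        n_in = rs.n_reports

        stage = "deduplicate"
        rs_dedup = deduplicate(rs)
        stage = "filter_suspect"
        rs_suspect = filter_suspect(rs_dedup)
        stage = "classify_exposure"
        cohort = classify_exposure(rs_suspect, archive)
        counts = build_cohorts(cohort, smq_map)

        stage = "cohort_summary"
        save(cohort_summary(cohort, smq_map), "cohort_summary.tsv")

        stage = "disproportionality"
        results = analyze_all(
            cohort, smq_map, comparator=config.comparator, unit=config.counting_unit
        )
        results = round_results(results, config.display_precision)
        save(results[results["level"] == "overall"], "overall_disprop.tsv")
        save(results[results["level"] == "smq"], "smq_disprop.tsv")
        save(results[results["level"] == "pt"], "pt_signals.tsv")

        stage = "outcomes"
        save(outcome_table(cohort, smq_map), "outcome_profiles.tsv")

        stage = "indication_restricted"
        restricted = restrict_to_indications(cohort, config.indication_terms)
        res_r = analyze_all(
            restricted, smq_map, comparator=config.comparator, unit=config.counting_unit
        )
        save(round_results(res_r, config.display_precision), "indication_restricted.tsv")

        stage = "manifest"
        pt_level = results[results["level"] == "pt"]
        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": json.loads(config.model_dump_json()),
            "counts": {
                "reports_in": n_in,
                "dropped_duplicates": n_in - rs_dedup.n_reports,
                "after_dedup": rs_dedup.n_reports,
                "dropped_no_suspect": rs_dedup.n_reports - rs_suspect.n_reports,
                "after_suspect_filter": rs_suspect.n_reports,
                "cases_by_group": {g.value: n for g, n in cohort.group_sizes().items()},
                "cv_cases_by_group": {g.value: n for g, n in counts.n_cases.items()},
                "cv_reports_by_group": {g.value: n for g, n in counts.n_reports.items()},
                "restricted_cases": restricted.n_cases,
            },
            "pt_signal_counts": {
                "by_ic": {
                    g.value: int(pt_level.loc[pt_level["group"] == g.value, "signal_by_ic"].sum())
                    for g in ExposureGroup
                    if g != ExposureGroup.NEITHER
                },
                "by_ror": {
                    g.value: int(pt_level.loc[pt_level["group"] == g.value, "signal_by_ror"].sum())
                    for g in ExposureGroup
                    if g != ExposureGroup.NEITHER
                },
            },
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(path)
        log.info("pipeline complete: %d artifacts in %s", len(written), outdir)
        return RunResult(output_dir=outdir, manifest=manifest)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
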