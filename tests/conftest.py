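"""Shared fixtures: a small generated batch with its ground-truth ledger."""

from __future__ import annotations

import pytest

from cardiopv import faers_io
from cardiopv.cohort import classify_exposure, deduplicate, filter_suspect
from cardiopv.model import ExposureGroup
from cardiopv.synthetic import default_config, generate


SMALL_N = {
    ExposureGroup.ICI_ALONE: 150,
    ExposureGroup.AGI_ALONE: 200,
    ExposureGroup.COMBINATION: 60,
    ExposureGroup.NEITHER: 800,
}


@pytest.fixture(scope="session")
def small_config():
    return default_config(seed=42, n_cases=dict(SMALL_N))


@pytest.fixture(scope="session")
def batch(small_config, tmp_path_factory):
    """Generated batch directory plus its ground truth."""
    outdir = tmp_path_factory.mktemp("batch")
    truth = generate(small_config, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def report_set(batch):
    outdir, _ = batch
    return faers_io.read_reports(outdir)


@pytest.fixture(scope="session")
def archive(batch):
    outdir, _ = batch
    return faers_io.read_drug_archive(outdir / "drug_archive.tsv")


@pytest.fixture(scope="session")
def smq_map(batch):
    outdir, _ = batch
    return faers_io.read_smq_map(outdir / "smq_map.tsv")


@pytest.fixture(scope="session")
def clean_cohort(report_set, archive):
    return classify_exposure(filter_suspect(deduplicate(report_set)), archive)
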