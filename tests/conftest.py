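"""Shared fixtures: the default synthetic study, generated once per session."""

from __future__ import annotations

import pytest

from secrc.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default planted-truth dataset (seed 42) plus its manifest."""
    root = tmp_path_factory.mktemp("dataset")
    manifest = generate_dataset(SyntheticConfig(), root)
    return root, manifest


@pytest.fixture(scope="session")
def pipeline_results(default_dataset, tmp_path_factory):
    """Full pipeline run over the default dataset."""
    from secrc.pipeline import PipelineConfig, run_all

    root, manifest = default_dataset
    out = tmp_path_factory.mktemp("results")
    summary = run_all(PipelineConfig(dataset_dir=str(root)), out)
    return out, summary, manifest
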