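"""Shared fixtures: one synthetic bundle + one pipeline run per session."""

from __future__ import annotations

import pytest

from atavipan.report import run_all
from atavipan.synth import SynthConfig, generate_all, write_bundle


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=0)


@pytest.fixture(scope="session")
def bundle(default_config):
    """In-memory synthetic bundle under the default study conditions."""
    return generate_all(default_config)


@pytest.fixture(scope="session")
def bundle_dir(default_config, tmp_path_factory):
    """On-disk bundle with manifest, shared across integration tests."""
    out = tmp_path_factory.mktemp("bundle")
    return write_bundle(default_config, out)


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """One full pipeline run on the default synthetic manifest."""
    out = tmp_path_factory.mktemp("run_main")
    return run_all(bundle_dir, out), out
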