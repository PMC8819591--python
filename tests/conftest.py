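"""Shared fixtures: the default synthetic benchmark and one full pipeline run.

The expensive end-to-end artifacts are session-scoped so the acceptance
tests and the module tests that inspect pipeline output share a single
computation.
"""

from __future__ import annotations

import pytest

from raacdip import GeneratorConfig, PipelineConfig, generate, run_pipeline


@pytest.fixture(scope="session")
def dataset7():
    """The default synthetic two-class benchmark (seed 7)."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline7(dataset7):
    """One full pipeline run on the default benchmark (seed 7)."""
    return run_pipeline(dataset7.records, PipelineConfig(seed=7))
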