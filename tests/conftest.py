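"""Shared fixtures: synthetic families at the default study conditions.

The heavy end-to-end objects (generated family, full pipeline report) are
session-scoped so the many tests that inspect them pay the cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mipkit.report import PipelineConfig, run_pipeline
from mipkit.seqio import read_gff3
from mipkit.synth import SynthConfig, evolve_family, paperlike_config, synthetic_gff

END_TO_END_SEED = 1


@pytest.fixture(scope="session")
def small_family():
    """A reduced family (4 members/subfamily) for fast unit tests."""
    return evolve_family(
        SynthConfig(members_per_subfamily=4, near_duplicate_count=2, rng_seed=7)
    )


@pytest.fixture(scope="session")
def paperlike_family():
    """The full default study conditions: 5 subfamilies x 10 members,
    2 references each, 5 planted near-duplicate pairs."""
    return evolve_family(paperlike_config(END_TO_END_SEED))


@pytest.fixture(scope="session")
def paperlike_report(paperlike_family):
    """Full pipeline output on the paperlike family (100 bootstrap reps)."""
    fam = paperlike_family
    gff_text, gff_truth = synthetic_gff(fam.config, seed=END_TO_END_SEED)
    rep = run_pipeline(
        fam.records, fam.references, fam.anchor,
        anchor_record=fam.anchor_record,
        gff_features=read_gff3(gff_text),
        config=PipelineConfig(bootstrap_reps=100),
        seed=END_TO_END_SEED,
    )
    return rep, gff_truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
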