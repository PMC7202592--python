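"""Shared fixtures: configs and a scaled-down planted cohort."""

from __future__ import annotations

from dataclasses import replace

import pytest

import metbc


@pytest.fixture(scope="session")
def paper_config():
    return metbc.default_config_from_paper()


@pytest.fixture(scope="session")
def small_cohort(paper_config):
    """Planted cohort at roughly one-fifth of the study's group sizes."""
    config = replace(paper_config, n_local=900, n_lymph=270, n_met=1000,
                     n_ambiguous=140)
    cohort, truth = metbc.simulate_cohort(config, seed=11)
    return cohort, truth, config


@pytest.fixture
def tiny_cohort():
    """Four hand-enumerable samples with known calls."""
    samples = [
        metbc.SampleRecord("s1", "breast", er_status="positive"),
        metbc.SampleRecord("s2", "liver", er_status="negative"),
        metbc.SampleRecord("s3", "lymph node", er_status="positive",
                           her2_amplified=True),
        metbc.SampleRecord("s4", "bone"),
    ]
    calls = [
        metbc.AlterationCall("s1", "TP53", "short_variant",
                             functional_status="known", vaf=0.4),
        metbc.AlterationCall("s1", "ESR1", "short_variant",
                             protein_change="D538G",
                             functional_status="known", vaf=0.2),
        metbc.AlterationCall("s2", "ESR1", "short_variant",
                             protein_change="Y537S",
                             functional_status="VUS", vaf=0.3),
        metbc.AlterationCall("s2", "MYC", "amplification"),
        metbc.AlterationCall("s3", "PTEN", "deletion"),
    ]
    panel = ["TP53", "ESR1", "MYC", "PTEN", "GATA3"]
    return metbc.Cohort.from_records(samples, calls, panel)
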