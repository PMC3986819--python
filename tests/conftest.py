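"""Shared fixtures: seeded simulated datasets generated at test time."""

from __future__ import annotations

import pytest

from neophase import cli_report as cr
from neophase import simdata as sd


@pytest.fixture(scope="session")
def small_bundle() -> sd.SimBundle:
    """20-gene dataset exercising lesions and divergence (seed 42)."""
    cfg = sd.SimConfig(n_genes=20, mean_cds_codons=200, seed=42)
    return sd.simulate_gene_set(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_bundle) -> cr.PipelineInputs:
    return cr._bundle_inputs(small_bundle)


@pytest.fixture(scope="session")
def small_result(small_inputs) -> cr.PipelineResult:
    return cr.run_pipeline(small_inputs)


@pytest.fixture(scope="session")
def small_evaluation(small_result, small_bundle) -> cr.TruthEvaluation:
    return cr.evaluate_against_truth(small_result, small_bundle.truth)


@pytest.fixture(scope="session")
def screen_bundle() -> sd.SimBundle:
    """Dataset enriched for deletion/silencing fates (screen tests)."""
    cfg = sd.SimConfig(
        n_genes=30,
        mean_cds_codons=150,
        frac_ptc=0.0,
        frac_frameshift=0.0,
        frac_neoY_silenced=0.2,
        frac_neoY_deleted=0.2,
        frac_neoX_deleted=0.15,
        seed=7,
    )
    return sd.simulate_gene_set(cfg)


@pytest.fixture(scope="session")
def screen_result(screen_bundle) -> cr.PipelineResult:
    return cr.run_pipeline(cr._bundle_inputs(screen_bundle))
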