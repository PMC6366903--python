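from types import SimpleNamespace

import hypothesis
import pytest

from suppscreen.effect import annotate_calls
from suppscreen.refmodel import CodonTable
from suppscreen.simscreen import SimConfig, simulate_screen
from suppscreen.snvcall import ThresholdConfig, call_experiment, pass_set
from suppscreen.triage import TriageConfig, triage_screen

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def table() -> CodonTable:
    return CodonTable.standard()


@pytest.fixture(scope="session")
def small_screen():
    """A fast, fully featured screen: 6 strains, 2 controls, 25 kb genome."""
    cfg = SimConfig(seed=20, n_suppressor_strains=6, n_other_genes=60,
                    genome_length=25_000, ancestral_variant_count=10)
    return simulate_screen(cfg)


@pytest.fixture(scope="session")
def default_screen():
    """The full default-condition screen (95 strains, ~0.5 Mb genome, 200×)
    run once through the whole pipeline."""
    cfg = SimConfig(seed=101)
    fx = simulate_screen(cfg)
    thresholds = ThresholdConfig.preset("batch95")
    calls = call_experiment(fx.counts, fx.design, thresholds)
    annotated = annotate_calls(pass_set(calls), fx.genome, fx.orfs)
    config = TriageConfig(gene_sets=fx.gene_sets)
    reports = triage_screen(annotated, config, samples=fx.design.suppressors)
    return SimpleNamespace(fixture=fx, thresholds=thresholds, calls=calls,
                           annotated=annotated, reports=reports)
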