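"""Shared fixtures: a small simulated study bundle, generated once per session."""

import pytest

import pathfuse as pf

# small but complete study: every stage has work to do, runs in seconds;
# effects are strong so planted pathways are unambiguous at this scale
SMALL_CONFIG = dict(
    seed=11,
    n_cases=300,
    n_controls=300,
    n_genes=120,
    n_pathways=40,
    pathway_size_range=(8, 30),
    n_enriched_pathways=3,
    n_expr_cases=20,
    n_expr_controls=20,
    maf_range=(0.05, 0.4),
    n_panel=300,
    genotype_odds_ratio=2.0,
    de_effect_size=2.0,
    causal_gene_fraction=0.15,
    de_gene_fraction=0.15,
    enrichment_fraction=0.8,
)


@pytest.fixture(scope="session")
def small_bundle():
    return pf.simulate_all(pf.SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    pf.write_fixture_bundle(str(outdir), small_bundle)
    return outdir


@pytest.fixture(scope="session")
def null_bundle():
    """Global null: no genotype effect, no differential expression."""
    cfg = pf.SimulationConfig(
        **{**SMALL_CONFIG, "genotype_odds_ratio": 1.0, "de_effect_size": 0.0}
    )
    return pf.simulate_all(cfg)
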