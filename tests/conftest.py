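"""Shared fixtures: one default synthetic study, generated once per session."""

import pytest

from postgwas.config import SimConfig
from postgwas.synthio import (build_layout, gen_gene_models, gen_genotypes, gen_motifs,
                              gen_phenotypes, gen_tracks, reference_sequence)


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def layout(cfg):
    return build_layout(cfg)


@pytest.fixture(scope="session")
def refseq(cfg, layout):
    return reference_sequence(cfg, layout)


@pytest.fixture(scope="session")
def panel(cfg, layout, refseq):
    return gen_genotypes(cfg, layout, refseq)


@pytest.fixture(scope="session")
def models(cfg, layout):
    return gen_gene_models(cfg, layout)


@pytest.fixture(scope="session")
def tracks(cfg, layout):
    return gen_tracks(cfg, layout)


@pytest.fixture(scope="session")
def pwms(cfg, layout):
    return gen_motifs(cfg, layout)


@pytest.fixture(scope="session")
def pheno(cfg, panel, layout):
    return gen_phenotypes(cfg, panel, layout)


@pytest.fixture(scope="session")
def result(cfg):
    from postgwas import pipeline

    return pipeline.run(cfg, n_perm=100)
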