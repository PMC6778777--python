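"""Shared fixtures: small seeded study designs reused across the suite."""

import dataclasses

import pytest

import ddradsex as dx


def small_config(**overrides) -> dx.RunConfig:
    """A desk-scale study design: 4F + 4M, 40 autosomal + 3 W loci, deep
    error-free coverage so planted-truth assertions are exact."""
    cfg = dx.RunConfig(
        genome=dx.GenomeSpec(n_autosomal_loci=60, n_w_specific_loci=3, snp_rate=0.002),
        sim=dx.SimConfig(mean_depth_per_locus=25.0),
        n_females=4,
        n_males=4,
        error_rate=0.0,
        seed=123,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.sim.seed = cfg.seed
    return cfg


@pytest.fixture(scope="session")
def ef_discovery() -> dx.DiscoveryResult:
    """One complete error-free discovery run (simulate -> cascade), shared."""
    return dx.discover(small_config())


@pytest.fixture(scope="session")
def ef_config() -> dx.RunConfig:
    return small_config()
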