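from __future__ import annotations

import pytest

from pansym.records import GeneRecord
from pansym.synthdata import SimConfig, simulate_clade


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast five-strain + outgroup clade used across tests."""
    cfg = SimConfig(
        n_core_families=40,
        n_fls_accessory=10,
        strain_specific_counts=(3, 3, 3, 2, 1),
        n_single_copy_core=12,
        protein_length=60,
        duplication_rate=0.0,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def low_rate_config(seed: int = 7, **overrides) -> SimConfig:
    """Small clade with mild divergence everywhere (rates <= 0.1/branch)."""
    cfg = small_config(seed=seed, **overrides)
    cfg = cfg.resolved()
    cfg.branch_subst_rates = {k: 0.02 for k in cfg.branch_subst_rates}
    return cfg


@pytest.fixture(scope="session")
def small_clade():
    return simulate_clade(small_config())


@pytest.fixture(scope="session")
def low_rate_clade():
    return simulate_clade(low_rate_config())


def make_gene(strain="S1", gene_id="g1", start=1, end=30, strand="+",
              cog=None, sequence="MKVLAAAAAA", contig="chr1") -> GeneRecord:
    return GeneRecord(strain=strain, gene_id=gene_id, contig=contig,
                      start=start, end=end, strand=strand, cog=cog,
                      sequence=sequence)
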