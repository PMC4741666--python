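"""Shared fixtures: a small hand-built two-exon gene and a generated one."""

from __future__ import annotations

import numpy as np
import pytest

from splicetriage.config import PipelineConfig
from splicetriage.genome_variant import GeneModel
from splicetriage.synthetic_data import SimulationConfig, generate_gene

# A strong intron: consensus-grade donor start and polypyrimidine/AG end.
STRONG_INTRON = "GTAAGT" + "CAACTCGACTCGAACTCGAC" + "TTTTTTTTTTTTTTTTCCAG"

UTR5 = "GGTACCAGTACC"  # 12 nt
# 30 codons incl. stop; laid out so specific codons drive the examples:
# codon 10 AGC (Ser), codon 15 GAA (Glu), codon 20 GAG (Glu), stop TGA.
CODONS = (
    ["ATG"]                                     # 1  Met
    + ["GCT", "CTG", "AAA", "GAT", "TGC", "CCT", "GTT", "ACT"]  # 2-9
    + ["AGC"]                                   # 10 Ser
    + ["CAT", "TGG", "CGT", "TAC"]              # 11-14
    + ["GAA"]                                   # 15 Glu
    + ["ATT", "CCA", "GGT", "TTG"]              # 16-19
    + ["GAG"]                                   # 20 Glu
    + ["AAC", "GAC", "TTC", "ATC", "AAG", "CTC", "GTG", "TGT", "ACA"]  # 21-29
    + ["TGA"]                                   # stop
)
# 3' UTR carries an in-frame TAA five codons downstream for stop-loss extension
UTR3 = "GGATCCGGATCCGGGTAAGGCACC"


def build_toy_model() -> GeneModel:
    mature = UTR5 + "".join(CODONS) + UTR3
    # split inside the CDS: exon 1 ends after c.45 (codon 15)
    cut = len(UTR5) + 45
    exon1, exon2 = mature[:cut], mature[cut:]
    pre = exon1 + STRONG_INTRON + exon2
    model = GeneModel(
        gene_id="TOY",
        pre_mrna=pre,
        exons=[(0, cut), (cut + len(STRONG_INTRON), len(pre))],
        cds_start=len(UTR5) + 1,
        cds_end=len(UTR5) + 90,
        protein_length=29,
        special_regions=[("NLS", 24, 27)],
    )
    model.validate()
    return model


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    return build_toy_model()


@pytest.fixture(scope="session")
def syn_model() -> GeneModel:
    cfg = SimulationConfig(seed=11, n_variants=10)
    return generate_gene(cfg, np.random.default_rng(cfg.seed))


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
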