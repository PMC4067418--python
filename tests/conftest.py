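"""Shared fixtures: tiny simulation worlds with known planted truth."""

import numpy as np
import pandas as pd
import pytest

from eqtlmap import simulate
from eqtlmap.datatypes import ExpressionMatrix, GeneModel, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genotypes(dosages, chrom="1", start_pos=1000, spacing=1000):
    """GenotypeMatrix from a plain (n_snps, n_samples) array."""
    d = np.asarray(dosages, dtype=float)
    snps = pd.DataFrame(
        {
            "snp": [f"rs{i+1}" for i in range(d.shape[0])],
            "chrom": chrom,
            "pos": [start_pos + i * spacing for i in range(d.shape[0])],
        }
    )
    samples = [f"S{j+1:04d}" for j in range(d.shape[1])]
    return GenotypeMatrix(d, snps, samples)


def make_expression(values, probe_prefix="P", stage="adjusted", chrom="1"):
    v = np.asarray(values, dtype=float)
    probes = pd.DataFrame(
        {
            "probe": [f"{probe_prefix}{i+1}" for i in range(v.shape[0])],
            "gene_id": [f"G{i+1}" for i in range(v.shape[0])],
            "symbol": [f"GENE{i+1}" for i in range(v.shape[0])],
            "rna_class": "mRNA",
            "chrom": chrom,
            "start": 10_000,
            "end": 20_000,
            "strand": "+",
        }
    )
    samples = [f"S{j+1:04d}" for j in range(v.shape[1])]
    return ExpressionMatrix(v, probes, samples, stage=stage)


def simple_gene(chrom="1", start=10_000, end=20_000, strand="+", gene_id="G1", symbol="GENE1"):
    return GeneModel(gene_id, symbol, chrom, start, end, strand)


@pytest.fixture
def trio_world():
    """One chromosome, three genes, one strong planted cis effect."""
    genes = [
        simulate.GeneSpec(f"G{i+1}", f"GENE{i+1}", "mRNA", "1", 100_000 + i * 1_200_000,
                          120_000 + i * 1_200_000, "+")
        for i in range(3)
    ]
    blocks = [
        simulate.LdBlockSpec("1", f"rs{i+1}", 90_000 + i * 1_200_000, 0.3)
        for i in range(3)
    ]
    plan = simulate.SimulationPlan(
        n_samples=300,
        chromosomes=[("1", 4_000_000)],
        ld_blocks=blocks,
        genes=genes,
        cis_effects=[simulate.EffectSpec("rs1", "G1_p1", 0.8)],
        noise_sd=0.5,
        baseline_sd=0.0,
        seed=7,
    )
    return plan
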