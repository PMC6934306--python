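"""Shared fixtures: small seeded synthetic studies."""

from types import SimpleNamespace

import numpy as np
import pytest

import heterokaryon as hk


def make_study(**overrides):
    defaults = dict(genome_length=40_000, n_genes=10, gene_length=1500,
                    n_snps=80, ratio_p=0.5, wg_depth=30.0, rna_depth=50.0,
                    error_rate=0.005, expression_mode="uniform", seed=11)
    defaults.update(overrides)
    cfg = hk.SimulationConfig(**defaults)
    genome, genes, repeat_iv = hk.simulate_genome(cfg)
    truth = hk.plant_heterokaryon_snps(genome, genes, repeat_iv, cfg)
    return SimpleNamespace(cfg=cfg, genome=genome, genes=genes,
                           repeats=repeat_iv, truth=truth)


@pytest.fixture(scope="session")
def het_study():
    """A 40 kb heterokaryon (p = 0.5) with 80 planted SNPs (2/kb)."""
    return make_study()


@pytest.fixture(scope="session")
def het_wg(het_study):
    return hk.simulate_wg_reads(het_study.truth, het_study.cfg)


@pytest.fixture(scope="session")
def het_sites(het_study, het_wg, tmp_path_factory):
    sam = tmp_path_factory.mktemp("wg") / "wg.sam"
    het_wg.write_sam(sam)
    counts = hk.pileup_allele_counts(sam, het_study.genome)
    return hk.classify_pileup(counts["contig_1"], "contig_1",
                              error_rate=het_study.cfg.error_rate)


def dup_genome_with_fragment(seed=3, copies=2):
    """Random genome carrying an exact duplicated cassette that digests
    into one EcoRI-MseI fragment per copy (planted by construction)."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", np.uint8)

    def rand(n):
        seq = bases[rng.integers(0, 4, n)].tobytes().decode()
        while "GAATTC" in seq or "TTAA" in seq:
            seq = seq.replace("GAATTC", "GAATAC").replace("TTAA", "TCAA")
        return seq

    # the leading TTAA keeps the filler upstream of each cassette from
    # forming its own >= 50 bp MseI-EcoRI fragment
    cassette = "TTAA" + rand(30) + "GAATTC" + rand(200) + "TTAA"
    parts = []
    for _ in range(copies):
        parts.append(rand(3000) + cassette)
    parts.append(rand(3000))
    genome = {"contig_1": "".join(parts)}
    return genome, cassette
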