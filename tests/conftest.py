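"""Shared fixtures: hand-built gene models and a small simulated panel."""

import numpy as np
import pytest

from irkit import quantify
from irkit import simulate as sim
from irkit.annotation import GeneModel, GenomeAnnotation, TranscriptModel


def make_gene(
    gene_id="G1",
    chrom="chr1",
    strand="+",
    exons=((0, 100), (200, 300), (400, 500)),
    cds=None,
    utr3=None,
    tx_id=None,
):
    tx = TranscriptModel(
        id=tx_id or f"{gene_id}.t1",
        exons=[tuple(e) for e in exons],
        cds=[tuple(c) for c in cds] if cds else [],
        utr3=[tuple(u) for u in utr3] if utr3 else [],
    )
    g = GeneModel(id=gene_id, chrom=chrom, strand=strand)
    g.transcripts[tx.id] = tx
    return g


def make_annotation(*genes):
    ann = GenomeAnnotation()
    for g in genes:
        ann.genes[g.id] = g
        ann.chrom_lengths[g.chrom] = max(ann.chrom_lengths.get(g.chrom, 0), g.end)
    return ann


@pytest.fixture(scope="session")
def small_sim():
    """80-gene simulated species with coverage/junction evidence and calls."""
    cfg = sim.SimConfig(n_genes=80, rng_seed=11)
    ann, genome, truth = sim.generate_annotation_and_genome(cfg)
    cov, jx = sim.simulate_alignment_evidence(ann, truth, cfg)
    fpkm = sim.estimate_fpkm_from_coverage(ann, cov, cfg.coverage_per_fpkm)
    calls, gene_irs = quantify.quantify_annotation(ann, cov, jx, fpkm=fpkm)
    retained = {
        i for g in gene_irs.values() for i in g.retained_intron_ids
    }
    return {
        "cfg": cfg,
        "ann": ann,
        "genome": genome,
        "truth": truth,
        "cov": cov,
        "jx": jx,
        "calls": calls,
        "gene_irs": gene_irs,
        "retained_ids": retained,
        "introns": ann.all_introns(representative_only=True),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
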