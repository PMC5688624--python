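"""3' UTR lengths, miRNA seed-site scanning, and 6-mer word enrichment.

A seed site is a 3' UTR subsequence that is the exact reverse complement
of miRNA positions 2-8 (a 7-mer; G:U wobble excluded). Word enrichment
follows the Sylamer framework: per 6-mer, the upper-tail cumulative
hypergeometric probability of the number of foreground sequences
containing the word, given its background prevalence, Bonferroni-corrected
over all 4^6 words (E-value).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .maxent import revcomp

POLYA_SIGNAL = "AATAAA"


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    gene_id: str
    position: int  # nt offset of the site in the UTR
    in_intron: bool = False


@dataclass
class WordEnrichment:
    word: str
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p: float
    e_value: float
    is_polya_signal: bool = False


def seed_word(mirna_seq: str) -> str:
    """UTR site sequence matched by miRNA offset positions 2-8."""
    dna = mirna_seq.upper().replace("U", "T")
    if len(dna) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    return revcomp(dna[1:8])


def utr3_length_per_gene(ann, include_retained_introns=None) -> dict[str, int | None]:
    """Per gene, the longest annotated spliced 3' UTR across transcripts.

    3'-UTR introns are excluded from the length unless their ids appear in
    ``include_retained_introns``, in which case their genomic length is
    added (the retained-intron-inclusive UTR).
    """
    from .annotation import derive_introns

    out: dict[str, int | None] = {}
    for gid, gene in ann.genes.items():
        best = None
        for tx in gene.transcripts.values():
            if not tx.utr3:
                continue
            length = sum(e - s for s, e in tx.utr3)
            if include_retained_introns:
                for intr in derive_introns(tx, gene.strand, gene.chrom, gid):
                    if intr.id in include_retained_introns and _inside_utr3(
                        intr, tx, gene.strand
                    ):
                        length += intr.length
            best = length if best is None else max(best, length)
        out[gid] = best
    return out


def _inside_utr3(intron, tx, strand) -> bool:
    if not tx.utr3:
        return False
    lo = min(s for s, _ in tx.utr3)
    hi = max(e for _, e in tx.utr3)
    return lo <= intron.start and intron.end <= hi


def spliced_utr3_seq(tx, strand, chrom_seq: str) -> str:
    """3' UTR sequence in transcript orientation, introns spliced out."""
    parts = [chrom_seq[s:e] for s, e in sorted(tx.utr3)]
    seq = "".join(parts)
    return seq if strand == "+" else revcomp(seq)


def scan_seed_sites(utr_seq: str, mirnas: dict[str, str], gene_id: str = ".",
                    energy_fn=None, energy_threshold: float = -14.0):
    """All perfect seed matches of each miRNA in a UTR sequence.

    ``energy_fn(mirna_seq, utr_context) -> kcal/mol`` is an optional duplex
    energy hook; sites above ``energy_threshold`` are dropped when the hook
    is supplied (disabled by default).
    """
    utr = utr_seq.upper().replace("U", "T")
    matches = []
    for mid, mseq in sorted(mirnas.items()):
        word = seed_word(mseq)
        start = 0
        while True:
            p = utr.find(word, start)
            if p < 0:
                break
            start = p + 1
            if energy_fn is not None:
                ctx = utr[max(0, p - 15) : p + 22]
                if energy_fn(mseq, ctx) > energy_threshold:
                    continue
            matches.append(SeedMatch(mirna_id=mid, gene_id=gene_id, position=p))
    return matches


def site_count_comparison(counts_ir, counts_other):
    """Median site counts per group, percent increase, Wilcoxon rank p."""
    a = np.asarray(list(counts_ir), float)
    b = np.asarray(list(counts_other), float)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    return {
        "median_ir": med_a,
        "median_other": med_b,
        "percent_increase": (med_a - med_b) / med_b * 100 if med_b else float("inf"),
        "wilcoxon_p": float(stats.ranksums(a, b).pvalue),
    }


def all_words(k: int = 6):
    return ["".join(w) for w in product("ACGT", repeat=k)]


def word_enrichment(fg_utrs, bg_utrs, k: int = 6) -> list[WordEnrichment]:
    """Per-word presence/absence enrichment of foreground vs background UTRs.

    p = upper-tail cumulative hypergeometric P(X >= fg_with) for X drawn
    from (bg_total, bg_with, fg_total); E-value = min(1, p * 4^k). The
    foreground must be a subset of the background sequence set. Sorted by
    E-value, the canonical polyadenylation signal flagged.
    """
    fg = [s.upper().replace("U", "T") for s in fg_utrs]
    bg = [s.upper().replace("U", "T") for s in bg_utrs]
    if not fg:
        raise ValueError("empty foreground set")
    n_words = 4**k

    def presence(seqs):
        counts: dict[str, int] = {}
        for s in seqs:
            seen = {s[i : i + k] for i in range(len(s) - k + 1)}
            for w in seen:
                if "N" not in w:
                    counts[w] = counts.get(w, 0) + 1
        return counts

    fg_counts = presence(fg)
    bg_counts = presence(bg)
    out = []
    for word, bg_with in bg_counts.items():
        fg_with = fg_counts.get(word, 0)
        # P(X >= fg_with), X ~ Hypergeom(M=len(bg), n=bg_with, N=len(fg))
        p = float(stats.hypergeom.sf(fg_with - 1, len(bg), bg_with, len(fg)))
        out.append(
            WordEnrichment(
                word=word,
                fg_with=fg_with,
                fg_total=len(fg),
                bg_with=bg_with,
                bg_total=len(bg),
                p=p,
                e_value=min(1.0, p * n_words),
                is_polya_signal=(k == 6 and word == POLYA_SIGNAL),
            )
        )
    out.sort(key=lambda w: (w.e_value, w.p, w.word))
    return out


def significant_words(enrichments, e_threshold: float = 0.01,
                      exclude_polya: bool = True):
    sig = [w for w in enrichments if w.e_value < e_threshold]
    if exclude_polya:
        sig = [w for w in sig if not w.is_polya_signal]
    return sig


def intron_site_density(retained_seqs, non_retained_seqs, mirnas):
    """Seed sites per kb in retained vs non-retained intron sequences."""
    def density(seqs):
        total_kb = sum(len(s) for s in seqs) / 1000.0
        n = sum(len(scan_seed_sites(s, mirnas)) for s in seqs)
        return n / total_kb if total_kb else float("nan"), n

    d_ret, n_ret = density(retained_seqs)
    d_other, n_other = density(non_retained_seqs)
    per_seq_ret = [
        len(scan_seed_sites(s, mirnas)) / (len(s) / 1000.0)
        for s in retained_seqs
        if len(s)
    ]
    per_seq_other = [
        len(scan_seed_sites(s, mirnas)) / (len(s) / 1000.0)
        for s in non_retained_seqs
        if len(s)
    ]
    p = float(stats.ranksums(per_seq_ret, per_seq_other).pvalue) if (
        per_seq_ret and per_seq_other
    ) else float("nan")
    return {
        "density_retained": d_ret,
        "density_other": d_other,
        "n_sites_retained": n_ret,
        "n_sites_other": n_other,
        "rank_p": p,
    }
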