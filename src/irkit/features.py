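"""Retained- vs non-retained-intron characteristics.

Length, GC content, intron phase, premature-termination-codon (PTC)
density in the host reading frame, relative position within the
transcript, and the intron-length / IR-ratio trend. Group differences use
two-sided rank tests; the length fold difference FD is the ratio of mean
non-retained to mean retained intron length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

STOPS = ("TAA", "TAG", "TGA")


@dataclass
class IntronFeatures:
    intron_id: str
    length: int
    gc: float
    phase: int | None
    ptc_density: float | None  # in-frame stops per kb
    rel_position: float
    is_retained: bool


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases; ambiguity codes are excluded."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def ptc_density(intron_seq: str, upstream_phase: int | None) -> float | None:
    """In-frame stop codons per kb, in the frame continued from the exon.

    ``upstream_phase`` is the number of bases of the interrupted codon
    already emitted upstream, so translation of the intron starts at offset
    (3 - phase) mod 3. None phase (non-coding context) gives None.
    """
    if upstream_phase is None:
        return None
    if upstream_phase not in (0, 1, 2):
        raise ValueError(f"phase must be 0, 1 or 2, got {upstream_phase}")
    seq = intron_seq.upper()
    offset = (3 - upstream_phase) % 3
    n_stops = sum(
        1 for i in range(offset, len(seq) - 2, 3) if seq[i : i + 3] in STOPS
    )
    return n_stops / (len(seq) / 1000.0)


def compare_feature(values_retained, values_other, test: str = "mann_whitney"):
    """Two-sided rank test + fold difference between groups.

    FD = mean(other) / mean(retained) — above 1 when the retained group is
    smaller, matching the convention for intron length.
    """
    a = np.asarray(values_retained, float)
    b = np.asarray(values_other, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    elif test == "wilcoxon":
        p = float(stats.ranksums(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "p_value": p,
        "median_retained": float(np.median(a)),
        "median_other": float(np.median(b)),
        "mean_retained": float(a.mean()),
        "mean_other": float(b.mean()),
        "fold_difference": float(b.mean() / a.mean()) if a.mean() else float("inf"),
    }


def length_ir_trend(
    ir_ratios, lengths, n_bins: int = 10, n_boot: int = 200, seed: int = 0
):
    """Binned-median description of the intron length / IR-ratio relation.

    Equal-count bins over the IR ratio; per bin the median log10 length
    plus a seeded 95% bootstrap band. Returns a dict of arrays.
    """
    r = np.asarray(ir_ratios, float)
    ln = np.log10(np.asarray(lengths, float))
    if r.size < n_bins:
        raise ValueError("need at least n_bins introns")
    order = np.argsort(r, kind="stable")
    r, ln = r[order], ln[order]
    edges = np.linspace(0, r.size, n_bins + 1).astype(int)
    rng = np.random.default_rng(seed)
    centers, med, lo, hi = [], [], [], []
    for a, b in zip(edges, edges[1:]):
        chunk = ln[a:b]
        centers.append(float(np.median(r[a:b])))
        med.append(float(np.median(chunk)))
        boots = np.median(
            rng.choice(chunk, size=(n_boot, chunk.size), replace=True), axis=1
        )
        lo.append(float(np.quantile(boots, 0.025)))
        hi.append(float(np.quantile(boots, 0.975)))
    return {
        "ir_ratio": np.array(centers),
        "median_log10_length": np.array(med),
        "band_low": np.array(lo),
        "band_high": np.array(hi),
    }


def phase_distribution(phases_retained, phases_other):
    """Phase proportions over {0,1,2} per group + chi-square comparison."""
    out = {}
    counts = {}
    for label, phases in (("retained", phases_retained), ("other", phases_other)):
        arr = np.asarray([p for p in phases if p is not None], dtype=int)
        c = np.bincount(arr, minlength=3)[:3].astype(float)
        counts[label] = c
        out[label] = c / c.sum() if c.sum() else c
    obs = np.vstack([counts["retained"], counts["other"]])
    if (obs.sum(axis=0) > 0).all() and obs.sum() > 0:
        chi2, p, _, _ = stats.chi2_contingency(obs)
        out["chi2"] = float(chi2)
        out["p_value"] = float(p)
    return out


def relative_position_density(introns_or_positions, n_bins: int = 20):
    """Histogram density of relative intron positions over (0, 1]."""
    pos = np.asarray(
        [
            x.rel_position if hasattr(x, "rel_position") else float(x)
            for x in introns_or_positions
        ]
    )
    hist, edges = np.histogram(pos, bins=n_bins, range=(0, 1), density=True)
    return {"density": hist, "edges": edges, "positions": pos}


def position_shift_test(pos_retained, pos_other):
    """KS test for a 3' (rightward) shift of retained-intron positions."""
    a = np.asarray(list(pos_retained), float)
    b = np.asarray(list(pos_other), float)
    res = stats.ks_2samp(a, b)
    return {
        "ks_p": float(res.pvalue),
        "mean_shift": float(a.mean() - b.mean()),
    }


def feature_table(introns, chrom_seqs, retained_ids):
    """Per-intron feature rows (list of IntronFeatures)."""
    rows = []
    for intr in introns:
        seq = chrom_seqs[intr.chrom][intr.start : intr.end]
        if intr.strand == "-":
            from .maxent import revcomp

            seq = revcomp(seq)
        rows.append(
            IntronFeatures(
                intron_id=intr.id,
                length=intr.length,
                gc=gc_content(seq),
                phase=intr.phase,
                ptc_density=ptc_density(seq, intr.phase),
                rel_position=intr.rel_position,
                is_retained=intr.id in retained_ids,
            )
        )
    return rows
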