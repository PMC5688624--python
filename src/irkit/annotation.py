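"""Gene annotation model: GTF I/O, intron derivation, interval arithmetic.

Internal coordinates are 0-based half-open genomic intervals everywhere;
conversion to/from the GTF's 1-based inclusive convention happens only at
the file boundary. Introns are derived as the gaps between consecutive
exons of a transcript, indexed from the transcript's 5' end, and carry the
reading-frame phase of the interrupted codon when the transcript is coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class AnnotationStructureError(ValueError):
    """Raised for structurally invalid gene models (e.g. overlapping exons)."""


@dataclass(frozen=True)
class Intron:
    """A single intron of one transcript.

    ``index`` is the 1-based ordinal counted from the transcript's 5' end
    (reverse genomic order on the minus strand). ``phase`` is the number of
    bases of the interrupted codon already emitted upstream of the intron
    (Ensembl exon-phase convention), or None for non-coding transcripts and
    introns outside the CDS. ``is_utr3`` marks introns lying fully
    downstream of the stop codon in at least one transcript of the gene.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    index: int
    n_introns_in_transcript: int
    phase: int | None = None
    is_utr3: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationStructureError(
                f"intron {self.id}: end {self.end} <= start {self.start}"
            )
        if not (1 <= self.index <= self.n_introns_in_transcript):
            raise AnnotationStructureError(
                f"intron {self.id}: index {self.index} outside "
                f"1..{self.n_introns_in_transcript}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def rel_position(self) -> float:
        """Relative position in (0, 1]: index / total introns in transcript."""
        return self.index / self.n_introns_in_transcript


@dataclass
class TranscriptModel:
    id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def sort(self) -> None:
        self.exons.sort()
        self.cds.sort()
        self.utr3.sort()

    def validate(self) -> None:
        self.sort()
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationStructureError(
                    f"transcript {self.id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise AnnotationStructureError(
                    f"transcript {self.id}: CDS [{cs},{ce}) not contained in an exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    biotype: str = "protein_coding"

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts.values())

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts.values())

    @property
    def tss(self) -> int:
        """5'-most transcribed base (genomic coordinate of transcription start)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcript end site (3'-most transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    def representative_transcript(self) -> TranscriptModel:
        """Deterministic per-gene transcript for gene-level intron summaries.

        Most exons, ties broken by spliced length, then lexicographic ID.
        """
        return max(
            self.transcripts.values(),
            key=lambda t: (len(t.exons), t.spliced_length, _neg_lex(t.id)),
        )


class _neg_lex(str):
    # max() with lexicographically *smallest* ID as final tie-break
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


@dataclass
class GenomeAnnotation:
    genes: dict[str, GeneModel] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def transcripts(self):
        for g in self.genes.values():
            yield from g.transcripts.values()

    def all_introns(self, representative_only: bool = False) -> list[Intron]:
        """Introns of every transcript (or only representative transcripts),
        with 3'-UTR membership flags applied."""
        utr3_ids = flag_utr3_introns(self)
        out: list[Intron] = []
        for g in self.genes.values():
            txs = (
                [g.representative_transcript()]
                if representative_only
                else g.transcripts.values()
            )
            for tx in txs:
                for intr in derive_introns(tx, g.strand, g.chrom, g.id):
                    if intr.id in utr3_ids:
                        intr = Intron(**{**intr.__dict__, "is_utr3": True})
                    out.append(intr)
        return out


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect, 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Lines with unknown feature types are skipped (a count is logged);
    missing gene_id/transcript_id attributes raise with the line number.
    """
    ann = GenomeAnnotation()
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr = fields
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if feature not in (
                "gene",
                "transcript",
                "exon",
                "CDS",
                "three_prime_utr",
                "five_prime_utr",
                "stop_codon",
                "start_codon",
                "UTR",
            ):
                skipped += 1
                continue
            attrs = _parse_attributes(attr, lineno)
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            if feature == "gene":
                if gid not in ann.genes:
                    ann.genes[gid] = GeneModel(
                        id=gid,
                        chrom=chrom,
                        strand=strand,
                        biotype=attrs.get("gene_biotype", "protein_coding"),
                    )
                continue
            if "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: {feature} feature missing transcript_id"
                )
            tid = attrs["transcript_id"]
            gene = ann.genes.setdefault(
                gid,
                GeneModel(
                    id=gid,
                    chrom=chrom,
                    strand=strand,
                    biotype=attrs.get("gene_biotype", "protein_coding"),
                ),
            )
            tx = gene.transcripts.setdefault(tid, TranscriptModel(id=tid))
            if feature == "exon":
                tx.exons.append((start, end))
            elif feature == "CDS":
                tx.cds.append((start, end))
            elif feature in ("three_prime_utr", "UTR"):
                tx.utr3.append((start, end))
    if skipped:
        logger.info("parse_gtf: skipped %d lines with unhandled feature types", skipped)
    for tx in ann.transcripts():
        tx.validate()
    for gene in ann.genes.values():
        ann.chrom_lengths[gene.chrom] = max(
            ann.chrom_lengths.get(gene.chrom, 0), gene.end
        )
    return ann


def write_gtf(ann: GenomeAnnotation, path) -> None:
    """Write the annotation back out as Ensembl-dialect GTF (round-trip safe)."""
    with open(path, "w") as fh:
        for gid in sorted(ann.genes):
            g = ann.genes[gid]

            def row(feature, s, e, tid=None):
                attrs = f'gene_id "{gid}"; gene_biotype "{g.biotype}";'
                if tid is not None:
                    attrs = (
                        f'gene_id "{gid}"; transcript_id "{tid}"; '
                        f'gene_biotype "{g.biotype}";'
                    )
                fh.write(
                    f"{g.chrom}\tirkit\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            row("gene", g.start, g.end)
            for tid in sorted(g.transcripts):
                tx = g.transcripts[tid]
                row("transcript", tx.start, tx.end, tid)
                for s, e in tx.exons:
                    row("exon", s, e, tid)
                for s, e in tx.cds:
                    row("CDS", s, e, tid)
                for s, e in tx.utr3:
                    row("three_prime_utr", s, e, tid)


def introns_to_bed6(introns: list[Intron], ir_ratios: dict[str, float] | None = None):
    """BED6 rows for introns; score = IR ratio x 1000 when calls are supplied."""
    rows = []
    for intr in introns:
        score = 0
        if ir_ratios and intr.id in ir_ratios:
            score = int(round(ir_ratios[intr.id] * 1000))
        rows.append(
            (intr.chrom, intr.start, intr.end, intr.id, score, intr.strand)
        )
    return rows


# ---------------------------------------------------------------------------
# Intron derivation
# ---------------------------------------------------------------------------


def derive_introns(
    tx: TranscriptModel, strand: str, chrom: str = ".", gene_id: str = "."
) -> list[Intron]:
    """Introns of a transcript: the gaps between consecutive exons.

    Index counts from the transcript's 5' end; phase is the cumulative CDS
    length upstream of the intron mod 3, None outside the CDS or for
    non-coding transcripts.
    """
    tx.validate()
    exons = tx.exons
    if len(exons) < 2:
        return []
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    n = len(gaps)
    cds = sorted(tx.cds)
    cds_span = (cds[0][0], cds[-1][1]) if cds else None
    introns = []
    for i, (gs, ge) in enumerate(gaps):
        index = i + 1 if strand == "+" else n - i
        phase: int | None = None
        # phase defined only for introns interrupting the CDS span
        if cds_span and cds_span[0] <= gs and ge <= cds_span[1]:
            if strand == "+":
                upstream = sum(min(e, gs) - s for s, e in cds if s < gs)
            else:
                upstream = sum(e - max(s, ge) for s, e in cds if e > ge)
            phase = upstream % 3
        introns.append(
            Intron(
                id=f"{tx.id}.i{index}",
                chrom=chrom,
                start=gs,
                end=ge,
                strand=strand,
                gene_id=gene_id,
                transcript_id=tx.id,
                index=index,
                n_introns_in_transcript=n,
                phase=phase,
            )
        )
    introns.sort(key=lambda x: x.index)
    return introns


def flag_utr3_introns(ann: GenomeAnnotation) -> set[str]:
    """IDs of introns lying fully 3' of the stop codon in >=1 transcript
    of their gene.

    An intron spanning the stop codon is not flagged. Genes without any
    annotated CDS yield no flags. The flag is assessed against every
    transcript of the gene that has a CDS, not just the intron's own.
    """
    flagged: set[str] = set()
    for g in ann.genes.values():
        stops: list[int] = []  # genomic boundary of the stop codon's 3' side
        for tx in g.transcripts.values():
            if not tx.cds:
                continue
            cds = sorted(tx.cds)
            stops.append(cds[-1][1] if g.strand == "+" else cds[0][0])
        if not stops:
            continue
        for tx in g.transcripts.values():
            for intr in derive_introns(tx, g.strand, g.chrom, g.id):
                if g.strand == "+":
                    ok = any(intr.start >= b for b in stops)
                else:
                    ok = any(intr.end <= b for b in stops)
                if ok:
                    flagged.add(intr.id)
    return flagged


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted non-overlapping list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_exonic_kbp(genes) -> float:
    """Total merged (union) exonic length over a collection of genes, in kbp.

    The union is taken within each gene across all of its transcripts'
    exons; per-gene totals are summed.
    """
    total = 0
    for g in genes:
        exons = [iv for tx in g.transcripts.values() for iv in tx.exons]
        total += sum(e - s for s, e in merge_intervals(exons))
    return total / 1000.0
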