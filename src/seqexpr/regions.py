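"""Derive the eight gene-associated region kinds and extract their sequences.

The model explains expression from the sequence composition of eight
regions per gene: three promoter segments around a chosen transcription
start site (distal upstream DU = -2000/-500, CORE = -500/+500, distal
downstream DD = +500/+2000 in transcription coordinates), the merged
5'UTR, CDS and 3'UTR, the constitutive introns (gene span minus all
annotated UTR/CDS sequence) and the downstream flanking region (DFR, the
1 kb immediately after the gene end).

Coordinates are 0-based half-open throughout.  Minus-strand sequences are
reverse-complemented so all features are computed on the sense strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .intervals import GenomicInterval, clip, merge, subtract, total_length
from .io import GtfRecord

logger = logging.getLogger(__name__)

REGION_KINDS = ("DU", "CORE", "DD", "UTR5", "CDS", "UTR3", "INTR", "DFR")

#: Promoter segments in transcription coordinates relative to the TSS.
PROMOTER_SPANS = {"DU": (-2000, -500), "CORE": (-500, 500), "DD": (500, 2000)}
DFR_LENGTH = 1000

TssChoice = Literal["first", "second", "third", "last"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    pass


@dataclass
class GeneModel:
    """One gene (or isoform) with the annotation needed to derive regions."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss_list: list[int]  # genomic positions, ordered 5'->3' in transcription direction
    utr5: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def transcription_end(self) -> int:
        """Genomic coordinate just past the last transcribed base (3' end)."""
        return self.end if self.strand == "+" else self.start


@dataclass
class RegionEntry:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    regions: dict[str, tuple[list[GenomicInterval], str]]
    missing: list[str] = field(default_factory=list)


@dataclass
class RegionCatalog:
    entries: dict[str, RegionEntry]
    skipped: list[str] = field(default_factory=list)

    def sequences(self, kind: str) -> dict[str, str]:
        return {gid: e.regions[kind][1] for gid, e in self.entries.items()}


# ---------------------------------------------------------------------------
# elementary operations


def select_tss(tss_list: Sequence[int], choice: TssChoice) -> int:
    """Pick a TSS from the transcription-ordered list, with fallback.

    ``second`` falls back to the first TSS when only one exists, ``third``
    to the second when only two exist; ``last`` is always the most
    downstream TSS.
    """
    if not tss_list:
        raise AnnotationError("gene has no TSS")
    if choice == "last":
        return tss_list[-1]
    rank = {"first": 0, "second": 1, "third": 2}
    if choice not in rank:
        raise ValueError(f"unknown TSS choice {choice!r}")
    return tss_list[min(rank[choice], len(tss_list) - 1)]


def _to_genomic(chrom: str, tss: int, strand: str, lo: int, hi: int) -> tuple[int, int]:
    """Map a transcription-coordinate window [lo, hi) to genomic coordinates."""
    if strand == "+":
        return tss + lo, tss + hi
    return tss - hi, tss - lo


def segment_promoter(
    chrom: str, tss: int, strand: str, chrom_length: int | None = None
) -> dict[str, GenomicInterval | None]:
    """Split the promoter into DU / CORE / DD around the TSS.

    On the minus strand the segments are mirrored so DU lies genomically
    downstream of the TSS.  Segments extending past the chromosome bounds
    are clipped (with a logged warning) rather than dropped.
    """
    out: dict[str, GenomicInterval | None] = {}
    bound = chrom_length if chrom_length is not None else 2**62
    for kind, (lo, hi) in PROMOTER_SPANS.items():
        gs, ge = _to_genomic(chrom, tss, strand, lo, hi)
        iv = clip(chrom, gs, ge, bound, strand)
        if iv is None or len(iv) < hi - lo:
            logger.warning(
                "promoter segment %s at %s:%d (%s) clipped to %s",
                kind, chrom, tss, strand, iv,
            )
        out[kind] = iv
    return out


def derive_dfr(
    gene: GeneModel, chrom_length: int | None = None
) -> GenomicInterval | None:
    """The 1 kb region immediately after the gene end (in transcription direction)."""
    bound = chrom_length if chrom_length is not None else 2**62
    if gene.strand == "+":
        iv = clip(gene.chrom, gene.end, gene.end + DFR_LENGTH, bound, gene.strand)
    else:
        iv = clip(gene.chrom, gene.start - DFR_LENGTH, gene.start, bound, gene.strand)
    if iv is None or len(iv) < DFR_LENGTH:
        logger.warning("DFR of %s clipped to %s", gene.gene_id, iv)
    return iv


def derive_introns(
    gene_span: GenomicInterval, exonic: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Constitutive introns: the gene span minus all annotated exonic sequence."""
    return subtract(gene_span, exonic)


def merge_and_concatenate(
    intervals: Sequence[GenomicInterval], genome: Mapping[str, str]
) -> tuple[list[GenomicInterval], str]:
    """Union overlapping/bookended intervals and concatenate their sequences.

    The concatenation follows transcription order: ascending genomic order
    on the plus strand, descending with reverse-complemented pieces on the
    minus strand.
    """
    merged = merge(list(intervals))
    if not merged:
        return [], ""
    chrom_seq = genome[merged[0].chrom]
    for iv in merged:
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside genome "
                f"(chromosome length {len(chrom_seq)})"
            )
    if merged[0].strand == "+":
        seq = "".join(chrom_seq[iv.start : iv.end] for iv in merged)
    else:
        seq = "".join(
            reverse_complement(chrom_seq[iv.start : iv.end]) for iv in reversed(merged)
        )
    return merged, seq


# ---------------------------------------------------------------------------
# annotation -> gene models


def gene_models_from_gtf(
    records: Sequence[GtfRecord], level: Literal["gene", "transcript"] = "gene"
) -> list[GeneModel]:
    """Assemble gene (or isoform) models from GTF records.

    Gene level merges UTR/CDS annotation over all transcripts of the gene
    and collects the distinct transcript starts as the TSS list.  Transcript
    level yields one model per transcript carrying only its own structure.
    """
    if level == "gene":
        return _models_grouped(records, key_attr="gene_id")
    return _models_grouped(records, key_attr="transcript_id")


def _models_grouped(records: Sequence[GtfRecord], key_attr: str) -> list[GeneModel]:
    groups: dict[str, list[GtfRecord]] = {}
    order: list[str] = []
    for rec in records:
        key = rec.attributes.get(key_attr)
        if key is None:
            continue
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    models = []
    for key in order:
        recs = groups[key]
        strand = recs[0].strand
        chrom = recs[0].chrom
        tx = [r for r in recs if r.feature == "transcript"]
        spans = tx if tx else recs
        start = min(r.start for r in spans)
        end = max(r.end for r in spans)
        tss = sorted({r.start if strand == "+" else r.end - 1 for r in (tx or spans)})
        if strand == "-":
            tss = tss[::-1]
        models.append(
            GeneModel(
                gene_id=key,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                tss_list=tss,
                utr5=[r.interval for r in recs if r.feature == "five_prime_utr"],
                cds=[r.interval for r in recs if r.feature == "CDS"],
                utr3=[r.interval for r in recs if r.feature == "three_prime_utr"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# catalog construction


def build_catalog(
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    tss_choice: TssChoice = "second",
) -> RegionCatalog:
    """Derive all eight regions and their sense-strand sequences per gene.

    Genes with no TSS are skipped (logged and reported).  Region kinds that
    come out empty (e.g. a gene whose exons tile the whole span has no
    introns) are kept with an empty sequence and flagged in ``missing``.
    """
    entries: dict[str, RegionEntry] = {}
    skipped: list[str] = []
    for gene in genes:
        if not gene.tss_list:
            logger.warning("gene %s has no TSS; skipped", gene.gene_id)
            skipped.append(gene.gene_id)
            continue
        chrom_len = len(genome[gene.chrom])
        tss = select_tss(gene.tss_list, tss_choice)
        regions: dict[str, tuple[list[GenomicInterval], str]] = {}

        promoter = segment_promoter(gene.chrom, tss, gene.strand, chrom_len)
        for kind in ("DU", "CORE", "DD"):
            iv = promoter[kind]
            regions[kind] = merge_and_concatenate([iv] if iv else [], genome)

        regions["UTR5"] = merge_and_concatenate(gene.utr5, genome)
        regions["CDS"] = merge_and_concatenate(gene.cds, genome)
        regions["UTR3"] = merge_and_concatenate(gene.utr3, genome)

        exonic = merge(gene.utr5 + gene.cds + gene.utr3)
        introns = derive_introns(gene.span, exonic)
        regions["INTR"] = merge_and_concatenate(introns, genome)

        dfr = derive_dfr(gene, chrom_len)
        regions["DFR"] = merge_and_concatenate([dfr] if dfr else [], genome)

        missing = [k for k in REGION_KINDS if not regions[k][1]]
        if missing:
            logger.warning("gene %s: empty regions %s", gene.gene_id, missing)
        entries[gene.gene_id] = RegionEntry(
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            strand=gene.strand,
            tss=tss,
            regions=regions,
            missing=missing,
        )
    return RegionCatalog(entries=entries, skipped=skipped)


def region_length_report(catalog: RegionCatalog) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = {
        gid: {kind: total_length(entry.regions[kind][0]) for kind in REGION_KINDS}
        for gid, entry in catalog.entries.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(REGION_KINDS)]
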