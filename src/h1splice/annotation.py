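"""Gene-model parsing and region-set construction.

Builds the internal-exon table and the promoter / internal-exon / intron /
junction region categories used throughout the pipeline.  Internal exons are
exons that are neither first nor last in any transcript annotating them;
overlapping exon variants are collapsed to the variant supported by the most
transcripts.  Junctions are the first and last 100 bp of each intron, and
those bases are excluded from the intron category.

Coordinates are 0-based half-open everywhere; GTF input (1-based closed) is
converted on read and BED output is written natively.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PROMOTER_SPAN = 2000
JUNCTION_SPAN = 100

CATEGORIES = ("promoter", "internal_exon", "intron", "junction")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_MITO_NAMES = {"chrM", "chrMT", "M", "MT"}
_PRIMARY_RE = re.compile(r"^(chr)?([0-9]{1,2}|X|Y)$")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; the message names the line number."""


def is_primary_chrom(name: str) -> bool:
    """True for primary-assembly chromosome names (chr1..chr22, chrX, chrY,
    with or without the ``chr`` prefix); mitochondrial and scaffold/patch
    names are rejected."""
    return name not in _MITO_NAMES and _PRIMARY_RE.match(name) is not None


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript as an ordered list of exon intervals.

    ``exons`` are (start, end) pairs in 0-based half-open genomic
    coordinates, sorted by start and non-overlapping; introns are the gaps
    between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) has end <= start"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def tss(self) -> int:
        """Transcription start: leftmost base for '+', rightmost for '-'
        (as a 0-based position just past the last base for '-')."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]


@dataclass(frozen=True)
class ExonRecord:
    """One internal exon (never a first or last exon of any transcript)."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_support: int
    ordinal: int
    length: int

    def __post_init__(self) -> None:
        if self.length != self.end - self.start or self.length < 1:
            raise ValueError("inconsistent exon length")
        if self.ordinal < 2:
            raise ValueError("internal exon ordinal must be >= 2")

    @property
    def exon_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping or bookended intervals, dropping empty ones."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, s, e in intervals:
        if e > s:
            by_chrom[chrom].append((s, e))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        cur_s = cur_e = None
        for s, e in sorted(by_chrom[chrom]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return merged


@dataclass(frozen=True)
class RegionSet:
    """A merged, non-overlapping set of intervals of one category."""

    category: str
    intervals: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_intervals(
        cls, category: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "RegionSet":
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return cls(category, tuple(merge_intervals(intervals)))

    @property
    def total_bases(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


def parse_gene_models(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Only exon features on primary-assembly chromosomes are retained;
    mitochondrial and scaffold chromosomes are dropped.  A transcript that
    carries no exon features (e.g. CDS-only) is excluded with a logged
    warning.  A malformed line raises :class:`GtfParseError` naming the line
    number.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    seen_any: set[str] = set()  # transcripts seen on retained chromosomes
    with open(gtf_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = (
                fields[:9]
            )
            if not is_primary_chrom(chrom):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            tx = attr.get("transcript_id")
            gene = attr.get("gene_id")
            if tx is None or gene is None:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: missing gene_id/transcript_id attribute"
                )
            seen_any.add(tx)
            if feature != "exon":
                continue
            try:
                start = int(start_s) - 1  # GTF is 1-based closed
                end = int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from exc
            if end <= start:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: end <= start after conversion"
                )
            if strand == "−":  # tolerate a typographic minus
                strand = "-"
            if strand not in "+-":
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: invalid strand {strand!r}"
                )
            exons[tx].append((start, end))
            meta[tx] = (gene, chrom, strand)
    for tx in sorted(seen_any - set(exons)):
        logger.warning("transcript %s has no exon features; excluded", tx)
    models = []
    for tx in sorted(exons):
        gene, chrom, strand = meta[tx]
        models.append(
            TranscriptModel(tx, gene, chrom, strand, tuple(sorted(exons[tx])))
        )
    return models


def build_internal_exon_table(
    models: Iterable[TranscriptModel],
) -> list[ExonRecord]:
    """Construct the non-overlapping internal-exon table.

    Each transcript's first and last exons are removed; among overlapping
    exon variants only the variant annotated in the most transcripts is
    retained, regardless of strand.  Support ties break toward the smaller
    start, then the smaller end.
    """
    # (chrom, start, end) -> list of (transcript_id, strand, gene_id, ordinal)
    occurrences: dict[tuple[str, int, int], list[tuple[str, str, str, int]]] = (
        defaultdict(list)
    )
    for m in models:
        n = len(m.exons)
        if n < 3:
            continue
        for j in range(1, n - 1):
            s, e = m.exons[j]
            ordinal = j + 1 if m.strand == "+" else n - j
            occurrences[(m.chrom, s, e)].append(
                (m.transcript_id, m.strand, m.gene_id, ordinal)
            )

    candidates = []
    for (chrom, s, e), occ in occurrences.items():
        support = len({tx for tx, _, _, _ in occ})
        rep = min(occ)  # deterministic representative: smallest transcript id
        candidates.append((chrom, s, e, support, rep))
    # max support first; ties -> smaller start, then smaller end
    candidates.sort(key=lambda c: (c[0], -c[3], c[1], c[2]))

    kept: list[ExonRecord] = []
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, s, e, support, (tx, strand, gene, ordinal) in candidates:
        if trees[chrom].overlap(s, e):
            continue
        trees[chrom].addi(s, e)
        kept.append(
            ExonRecord(chrom, s, e, strand, gene, support, ordinal, e - s)
        )
    kept.sort(key=lambda r: (r.chrom, r.start, r.end))
    return kept


def _intron_partition(
    intron: tuple[int, int],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split one intron into (junction intervals, intron-body intervals).

    Introns of at least 2 * JUNCTION_SPAN yield two 100 bp junctions and the
    remaining body; shorter introns are split at their midpoint into two
    junctions so every base stays in exactly one category.
    """
    s, e = intron
    length = e - s
    if length >= 2 * JUNCTION_SPAN:
        junctions = [(s, s + JUNCTION_SPAN), (e - JUNCTION_SPAN, e)]
        body = [(s + JUNCTION_SPAN, e - JUNCTION_SPAN)]
    else:
        mid = s + length // 2
        junctions = [(s, mid), (mid, e)]
        body = []
    return junctions, [iv for iv in body if iv[1] > iv[0]]


def derive_region_sets(
    models: Iterable[TranscriptModel],
    exons: Iterable[ExonRecord],
    genome_sizes: dict[str, int] | None = None,
) -> dict[str, RegionSet]:
    """Build the four region categories, each merged for overlaps.

    promoter: 2000 bp upstream of each TSS, oriented by strand and truncated
    at position 0 (and at the chromosome end when sizes are given);
    junction: first and last 100 bp of each intron; intron: intronic bases
    excluding junctions; internal_exon: the internal-exon table intervals.
    """
    promoters: list[tuple[str, int, int]] = []
    junctions: list[tuple[str, int, int]] = []
    intron_bodies: list[tuple[str, int, int]] = []
    for m in models:
        if m.strand == "+":
            tss = m.tss
            promoters.append((m.chrom, max(0, tss - PROMOTER_SPAN), tss))
        else:
            tss = m.tss
            end = tss + PROMOTER_SPAN
            if genome_sizes is not None and m.chrom in genome_sizes:
                end = min(end, genome_sizes[m.chrom])
            promoters.append((m.chrom, tss, end))
        for intron in m.introns:
            jns, body = _intron_partition(intron)
            junctions.extend((m.chrom, s, e) for s, e in jns)
            intron_bodies.extend((m.chrom, s, e) for s, e in body)
    exon_ivs = [(r.chrom, r.start, r.end) for r in exons]
    return {
        "promoter": RegionSet.from_intervals("promoter", promoters),
        "internal_exon": RegionSet.from_intervals("internal_exon", exon_ivs),
        "intron": RegionSet.from_intervals("intron", intron_bodies),
        "junction": RegionSet.from_intervals("junction", junctions),
    }


def gene_region_set(models: Iterable[TranscriptModel]) -> RegionSet:
    """Gene loci from 2000 bp upstream of the TSS to the transcript end,
    merged.  This is the sampling space of the randomization occupancy test.
    """
    ivs = []
    for m in models:
        s, e = m.exons[0][0], m.exons[-1][1]
        if m.strand == "+":
            s = max(0, s - PROMOTER_SPAN)
        else:
            e = e + PROMOTER_SPAN
        ivs.append((m.chrom, s, e))
    # "gene" is not one of the four analysis categories, so bypass from_intervals
    return RegionSet("gene", tuple(merge_intervals(ivs)))


def exon_trios(
    models: Iterable[TranscriptModel], exons: Iterable[ExonRecord]
) -> "pd.DataFrame":
    """For each internal exon, genomic coordinates of its flanking exons.

    The flanks come from the lexicographically smallest transcript that
    annotates the exon as internal.  Columns ``left_*``/``right_*`` are the
    genomically left and right neighbours (strand-agnostic), as used by
    junction-read counting.
    """
    import pandas as pd

    by_interval: dict[tuple[str, int, int], TranscriptModel] = {}
    for m in models:
        if len(m.exons) < 3:
            continue
        for j in range(1, len(m.exons) - 1):
            key = (m.chrom, *m.exons[j])
            cur = by_interval.get(key)
            if cur is None or m.transcript_id < cur.transcript_id:
                by_interval[key] = m
    rows = []
    for r in exons:
        m = by_interval.get((r.chrom, r.start, r.end))
        if m is None:
            continue
        j = m.exons.index((r.start, r.end))
        left, right = m.exons[j - 1], m.exons[j + 1]
        rows.append(
            {
                "exon_id": r.exon_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "gene_id": r.gene_id,
                "left_start": left[0],
                "left_end": left[1],
                "right_start": right[0],
                "right_end": right[1],
            }
        )
    return pd.DataFrame(rows)


def write_bed(region_set: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED6 (name = category, score = 0, strand = '.')."""
    with open(path, "w") as fh:
        for chrom, s, e in region_set.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{region_set.category}\t0\t.\n")


def write_exon_table(exons: Sequence[ExonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tgene_id\tordinal\tsupport\tlength\n")
        for r in exons:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.gene_id}\t"
                f"{r.ordinal}\t{r.transcript_support}\t{r.length}\n"
            )


def read_exon_table(path: str | Path) -> list[ExonRecord]:
    exons = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"{path}: missing exon-table header")
        for line in fh:
            chrom, start, end, strand, gene, ordinal, support, length = (
                line.rstrip("\n").split("\t")
            )
            exons.append(
                ExonRecord(
                    chrom,
                    int(start),
                    int(end),
                    strand,
                    gene,
                    int(support),
                    int(ordinal),
                    int(length),
                )
            )
    return exons
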