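"""Per-base occupancy tracks from aligned reads, plus GC and methylation tracks.

ChIP reads are shifted toward the middle of their originating fragment
(``floor((fragment - read) / 2)`` on the read strand), MNase reads are
extended to the nucleosome footprint, and depth is expressed in reads per
million mapped reads (RPM).  The final ChIP occupancy is the RPM difference
between the ChIP library and its input; negative values are retained so
meta-profiles can show depletion.

Reads are held in a pandas DataFrame with columns ``chrom, start, end,
strand`` (0-based half-open).  SAM/BAM input is read through pysam; a
4-column tab-separated text format is accepted as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]
UNITS = ("rpm", "rpm_difference", "binary", "proportion")


@dataclass
class SignalTrack:
    """Dense per-base values per chromosome with explicit units.

    ``data`` maps chromosome name to a float array covering the whole
    chromosome.  Missing values (e.g. non-CpG bases of a methylation track)
    are NaN and are excluded from meta-profile means.
    """

    data: dict[str, np.ndarray]
    units: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        self.data = {c: np.asarray(v, dtype=float) for c, v in self.data.items()}

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions beyond the chromosome are NaN."""
        arr = self.data[chrom]
        out = np.full(end - start, np.nan)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def to_bedgraph(self, path: str | Path) -> None:
        """Write non-NaN runs as 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                finite = np.isfinite(arr)
                # run boundaries wherever the value or finiteness changes
                change = np.empty(len(arr), dtype=bool)
                change[0] = True
                same = (arr[1:] == arr[:-1]) | (~finite[1:] & ~finite[:-1])
                change[1:] = ~same
                starts = np.flatnonzero(change)
                ends = np.append(starts[1:], len(arr))
                for s, e in zip(starts, ends):
                    if finite[s]:
                        fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:g}\n")


def from_bedgraph(
    path: str | Path,
    genome_sizes: Mapping[str, int],
    units: str,
    fill: float = 0.0,
) -> SignalTrack:
    """Load a bedGraph into a dense track; uncovered bases take ``fill``
    (use NaN for sparse tracks such as methylation)."""
    data = {c: np.full(n, fill, dtype=float) for c, n in genome_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, s, e, v = line.split()[:4]
            if chrom in data:
                data[chrom][int(s) : int(e)] = float(v)
    return SignalTrack(data, units, provenance=f"bedGraph:{path}")


def _as_reads(reads: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"reads frame missing columns {missing}")
    return reads


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read alignments from SAM/BAM (via pysam) or 4-column tab text."""
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                rows.append(
                    (
                        aln.reference_name,
                        aln.reference_start,
                        aln.reference_end,
                        "-" if aln.is_reverse else "+",
                    )
                )
        return pd.DataFrame(rows, columns=READ_COLUMNS)
    df = pd.read_csv(path, sep="\t", names=READ_COLUMNS, comment="#")
    return df


def write_alignments(reads: pd.DataFrame, path: str | Path) -> None:
    _as_reads(reads)[READ_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def fragment_midpoint_shift(read_length: int, mean_fragment: int) -> int:
    """Base-pair shift that moves a read onto its fragment midpoint.

    ``floor((mean_fragment - read_length) / 2)``, applied downstream on the
    read strand; e.g. 51 bp reads from 225 bp fragments shift 87 bp.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if mean_fragment < read_length:
        raise ValueError("mean_fragment must be >= read_length")
    return (mean_fragment - read_length) // 2


def shift_reads(
    reads: pd.DataFrame, shift: int, genome_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Translate reads by ``shift`` bp downstream on their strand.

    Plus-strand reads move +shift, minus-strand reads -shift; coordinates
    are clipped to chromosome bounds (total clipped bases logged) and reads
    clipped to zero length are dropped.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    df = _as_reads(reads).copy()
    sign = np.where(df["strand"].to_numpy() == "+", 1, -1)
    df["start"] = df["start"].to_numpy() + sign * shift
    df["end"] = df["end"].to_numpy() + sign * shift
    return _clip_to_genome(df, genome_sizes)


def extend_reads(
    reads: pd.DataFrame, target_length: int, genome_sizes: Mapping[str, int]
) -> pd.DataFrame:
    """Extend each read in its strand's 3' direction to ``target_length`` bp."""
    df = _as_reads(reads).copy()
    lengths = df["end"].to_numpy() - df["start"].to_numpy()
    if (lengths > target_length).any():
        raise ValueError("target_length is shorter than an input read")
    plus = df["strand"].to_numpy() == "+"
    df.loc[plus, "end"] = df.loc[plus, "start"] + target_length
    df.loc[~plus, "start"] = df.loc[~plus, "end"] - target_length
    return _clip_to_genome(df, genome_sizes)


def _clip_to_genome(
    df: pd.DataFrame, genome_sizes: Mapping[str, int]
) -> pd.DataFrame:
    sizes = df["chrom"].map(genome_sizes)
    if sizes.isna().any():
        bad = df.loc[sizes.isna(), "chrom"].unique()
        raise ValueError(f"reads on chromosomes absent from genome_sizes: {bad}")
    before = (df["end"] - df["start"]).sum()
    df["start"] = df["start"].clip(lower=0, upper=sizes)
    df["end"] = df["end"].clip(lower=0, upper=sizes)
    clipped = before - (df["end"] - df["start"]).sum()
    if clipped:
        logger.info("clipped %d read bases at chromosome bounds", clipped)
    keep = df["end"] > df["start"]
    if not keep.all():
        logger.info("dropped %d reads clipped to zero length", (~keep).sum())
    return df.loc[keep].reset_index(drop=True)


def coverage(
    reads: pd.DataFrame, genome_sizes: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Unnormalized per-base read coverage (number of reads spanning each base)."""
    df = _as_reads(reads)
    out = {}
    for chrom, size in genome_sizes.items():
        sub = df[df["chrom"] == chrom]
        diff = np.zeros(size + 1)
        np.add.at(diff, sub["start"].to_numpy(), 1.0)
        np.add.at(diff, sub["end"].to_numpy(), -1.0)
        out[chrom] = np.cumsum(diff[:-1])
    return out


def depth_rpm(
    reads: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    provenance: str = "",
) -> SignalTrack:
    """Reads-per-million depth: at each base, (# spanning reads) * 1e6 / library size."""
    n = len(_as_reads(reads))
    if n == 0:
        raise ValueError("cannot compute depth of an empty read set")
    cov = coverage(reads, genome_sizes)
    scale = 1e6 / n
    return SignalTrack(
        {c: v * scale for c, v in cov.items()}, "rpm", provenance=provenance
    )


def subtract_input(chip: SignalTrack, input_track: SignalTrack) -> SignalTrack:
    """ChIP minus input, elementwise in RPM; negative values are retained."""
    if chip.units != "rpm" or input_track.units != "rpm":
        raise ValueError("subtract_input expects two rpm tracks")
    if chip.chrom_sizes != input_track.chrom_sizes:
        raise ValueError("chromosome sets/sizes differ between chip and input")
    data = {c: chip.data[c] - input_track.data[c] for c in chip.data}
    prov = f"({chip.provenance}) - ({input_track.provenance})"
    return SignalTrack(data, "rpm_difference", provenance=prov)


def gc_track(fasta_path: str | Path) -> SignalTrack:
    """Binary track: 1 at G or C (case-insensitive), 0 at A/T and at N.

    N bases are counted and logged; they score 0 rather than missing, so GC
    meta-profiles remain simple proportions of called G/C.
    """
    from pyfaidx import Fasta

    data = {}
    n_total = 0
    with Fasta(str(fasta_path)) as fa:
        for name in fa.keys():
            seq = np.frombuffer(str(fa[name][:]).upper().encode(), dtype="S1")
            arr = ((seq == b"G") | (seq == b"C")).astype(float)
            n_total += int((seq == b"N").sum())
            data[name] = arr
    if n_total:
        logger.info("gc_track: %d N bases scored 0", n_total)
    return SignalTrack(data, "binary", provenance=f"gc:{fasta_path}")


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Per-CpG table: chrom, position, methylated_reads, total_reads[, proportion]."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "position", "methylated_reads", "total_reads"],
        usecols=[0, 1, 2, 3],
        comment="#",
    )
    validate_methylation_table(df)
    return df


def validate_methylation_table(table: pd.DataFrame) -> None:
    if (table["total_reads"] <= 0).any():
        raise ValueError("methylation table: total_reads must be positive")
    if (
        (table["methylated_reads"] < 0)
        | (table["methylated_reads"] > table["total_reads"])
    ).any():
        raise ValueError("methylation table: need 0 <= methylated <= total")
    if "proportion" in table.columns:
        prop = table["proportion"].to_numpy(float)
        if ((prop < 0) | (prop > 1)).any():
            raise ValueError("methylation table: proportion outside [0, 1]")
        expected = table["methylated_reads"] / table["total_reads"]
        if not np.allclose(prop, expected, atol=5e-3):
            raise ValueError("methylation table: proportion inconsistent with counts")


def methylation_track(
    table: pd.DataFrame, genome_sizes: Mapping[str, int]
) -> SignalTrack:
    """Per-CpG methylation proportions; non-CpG bases are NaN (missing)."""
    validate_methylation_table(table)
    data = {c: np.full(n, np.nan) for c, n in genome_sizes.items()}
    prop = (
        table["methylated_reads"].to_numpy(float)
        / table["total_reads"].to_numpy(float)
    )
    for chrom, pos, p in zip(table["chrom"], table["position"], prop):
        if chrom in data and 0 <= pos < len(data[chrom]):
            data[chrom][pos] = p
    return SignalTrack(data, "proportion", provenance="bisulfite proportions")
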