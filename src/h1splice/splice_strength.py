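"""Position-frequency splice-site strength scoring.

Donor (5'ss) and acceptor (3'ss) sequences are scored against per-position
nucleotide frequency tables on a 0-100 scale:

    score = 100 * (sum_i f_i(s_i) - sum_i min_i) / (sum_i max_i - sum_i min_i)

so the per-position consensus sequence scores exactly 100 and the
anti-consensus exactly 0.  Window spans follow the classical donor
3 exonic + 6 intronic and acceptor 14 intronic + 3 exonic convention.

Frequency tables are a required, pluggable input (TSV; see
``FrequencyTable.from_tsv``).  The defaults shipped here are synthetic
consensus tables matching the splice sites planted by the synthetic-data
generator — suitable for testing, not estimates from real splice sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DONOR_EXONIC_SPAN = 3
DONOR_INTRONIC_SPAN = 6
ACCEPTOR_INTRONIC_SPAN = 14
ACCEPTOR_EXONIC_SPAN = 3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FrequencyTable:
    """Per-position A/C/G/T frequencies for one splice-site type.

    ``freqs`` rows follow the site sequence 5'->3' (exon then intron for a
    donor; intron then exon for an acceptor); columns are A, C, G, T.
    """

    site_type: str  # 'donor' or 'acceptor'
    exonic_span: int
    intronic_span: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.site_type not in ("donor", "acceptor"):
            raise ValueError(f"site_type must be donor/acceptor, got {self.site_type!r}")
        if self.exonic_span <= 0 or self.intronic_span <= 0:
            raise ValueError("spans must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (self.width, 4):
            raise ValueError(
                f"frequency matrix must be ({self.width}, 4), got {f.shape}"
            )
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequencies at each position must sum to 1")
        if (f < 0).any():
            raise ValueError("negative frequency")
        object.__setattr__(self, "freqs", f)

    @property
    def width(self) -> int:
        return self.exonic_span + self.intronic_span

    def positions(self) -> list[int]:
        """Signed positions per row: negative on the exonic side, positive on
        the intronic side, counted from the splice junction outward."""
        if self.site_type == "donor":
            return list(range(-self.exonic_span, 0)) + list(
                range(1, self.intronic_span + 1)
            )
        return list(range(self.intronic_span, 0, -1)) + [
            -p for p in range(1, self.exonic_span + 1)
        ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_type\tposition\tfreq_A\tfreq_C\tfreq_G\tfreq_T\n")
            for pos, row in zip(self.positions(), self.freqs):
                fh.write(
                    f"{self.site_type}\t{pos}\t"
                    + "\t".join(f"{v:.6g}" for v in row)
                    + "\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrequencyTable":
        rows = []
        site_type = None
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["site_type", "position"]:
                raise ValueError(f"{path}: unexpected table header")
            for line in fh:
                st, pos, *fr = line.rstrip("\n").split("\t")
                site_type = st
                rows.append((int(pos), [float(v) for v in fr]))
        if site_type is None:
            raise ValueError(f"{path}: empty frequency table")
        exonic = sum(1 for p, _ in rows if p < 0)
        intronic = sum(1 for p, _ in rows if p > 0)
        # order rows back into sequence order from signed positions:
        # donor runs exon(-3..-1) then intron(+1..+6); acceptor runs
        # intron(+14..+1) then exon(-1..-3)
        if site_type == "donor":
            rows.sort(key=lambda r: r[0])
        else:
            rows.sort(key=lambda r: (r[0] < 0, -r[0]))
        return cls(site_type, exonic, intronic, np.array([f for _, f in rows]))


def score_site(sequence: str, table: FrequencyTable) -> float | None:
    """Shapiro-style 0-100 strength of one site sequence.

    Returns None (logged) for sequences containing N or other ambiguity
    codes; raises if the length does not match the table window.
    """
    seq = sequence.upper()
    if len(seq) != table.width:
        raise ValueError(
            f"sequence length {len(seq)} != table window {table.width}"
        )
    if any(c not in _BASE_INDEX for c in seq):
        logger.info("site %r contains ambiguity codes; not scored", sequence)
        return None
    idx = np.array([_BASE_INDEX[c] for c in seq])
    f = table.freqs[np.arange(table.width), idx].sum()
    lo = table.freqs.min(axis=1).sum()
    hi = table.freqs.max(axis=1).sum()
    if hi == lo:
        raise ValueError("degenerate frequency table: max == min at all positions")
    return float(100.0 * (f - lo) / (hi - lo))


def extract_site_sequences(exon, genome) -> tuple[str | None, str | None]:
    """(donor, acceptor) sequences for one internal exon.

    donor: last 3 exonic + first 6 intronic bases at the 5'ss;
    acceptor: last 14 intronic + first 3 exonic bases at the 3'ss.
    Minus-strand exons are read from the opposite genomic side and
    reverse-complemented.  A window that runs off the chromosome yields
    None for that site.

    ``genome`` may be a pyfaidx.Fasta or a plain mapping of chromosome name
    to sequence string.
    """
    seq = genome[exon.chrom]
    chrom_seq = str(seq[:]) if hasattr(seq, "__getitem__") and not isinstance(seq, str) else seq
    n = len(chrom_seq)

    def window(s: int, e: int) -> str | None:
        if s < 0 or e > n:
            return None
        return chrom_seq[s:e]

    if exon.strand == "+":
        donor = window(exon.end - DONOR_EXONIC_SPAN, exon.end + DONOR_INTRONIC_SPAN)
        acceptor = window(
            exon.start - ACCEPTOR_INTRONIC_SPAN, exon.start + ACCEPTOR_EXONIC_SPAN
        )
    else:
        d = window(exon.start - DONOR_INTRONIC_SPAN, exon.start + DONOR_EXONIC_SPAN)
        a = window(
            exon.end - ACCEPTOR_EXONIC_SPAN, exon.end + ACCEPTOR_INTRONIC_SPAN
        )
        donor = reverse_complement(d) if d is not None else None
        acceptor = reverse_complement(a) if a is not None else None
    return donor, acceptor


@dataclass(frozen=True)
class SpliceSiteScore:
    exon_id: str
    site_type: str
    score: float


def score_exons(
    exons: Sequence,
    genome,
    donor_table: "FrequencyTable | None" = None,
    acceptor_table: "FrequencyTable | None" = None,
) -> list[SpliceSiteScore]:
    """Donor and acceptor strengths for a set of internal exons.

    Sites that cannot be extracted (chromosome edge) or scored (ambiguity
    codes) are skipped.
    """
    donor_table = donor_table or default_donor_table()
    acceptor_table = acceptor_table or default_acceptor_table()
    out = []
    for exon in exons:
        donor, acceptor = extract_site_sequences(exon, genome)
        if donor is not None:
            s = score_site(donor, donor_table)
            if s is not None:
                out.append(SpliceSiteScore(exon.exon_id, "donor", s))
        if acceptor is not None:
            s = score_site(acceptor, acceptor_table)
            if s is not None:
                out.append(SpliceSiteScore(exon.exon_id, "acceptor", s))
    return out


# --- default synthetic consensus tables ------------------------------------
# These mirror the per-position sampling frequencies the synthetic-data
# generator uses when planting splice sites (GT..AG introns with a strong
# donor consensus and a pyrimidine-rich acceptor tract).  They are synthetic
# stand-ins for real frequency tables, shipped so the scorer is testable
# end-to-end without external data.

_DONOR_FREQS = [
    # exonic -3..-1
    [0.33, 0.37, 0.18, 0.12],
    [0.60, 0.13, 0.14, 0.13],
    [0.08, 0.04, 0.81, 0.07],
    # intronic +1..+6 (GT invariant)
    [0.00, 0.00, 1.00, 0.00],
    [0.00, 0.00, 0.00, 1.00],
    [0.58, 0.03, 0.35, 0.04],
    [0.71, 0.08, 0.12, 0.09],
    [0.07, 0.06, 0.84, 0.03],
    [0.17, 0.17, 0.19, 0.47],
]

_ACCEPTOR_FREQS = (
    # intronic +14..+5: pyrimidine tract
    [[0.10, 0.31, 0.12, 0.47]] * 4
    + [[0.08, 0.33, 0.10, 0.49]] * 4
    + [[0.06, 0.36, 0.08, 0.50]] * 2
    + [
        [0.24, 0.30, 0.21, 0.25],  # +4
        [0.04, 0.66, 0.01, 0.29],  # +3
        [1.00, 0.00, 0.00, 0.00],  # +2 (A of AG)
        [0.00, 0.00, 1.00, 0.00],  # +1 (G of AG)
        # exonic -1..-3
        [0.24, 0.14, 0.52, 0.10],
        [0.30, 0.22, 0.24, 0.24],
        [0.24, 0.28, 0.25, 0.23],
    ]
)


def default_donor_table() -> FrequencyTable:
    return FrequencyTable(
        "donor", DONOR_EXONIC_SPAN, DONOR_INTRONIC_SPAN, np.array(_DONOR_FREQS)
    )


def default_acceptor_table() -> FrequencyTable:
    return FrequencyTable(
        "acceptor",
        ACCEPTOR_EXONIC_SPAN,
        ACCEPTOR_INTRONIC_SPAN,
        np.array(_ACCEPTOR_FREQS),
    )
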