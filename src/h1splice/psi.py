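"""Exon inclusion (PSI) from junction-spanning reads, and differential filters.

A spliced read is *informative* for a target exon when one of its splice
junctions joins the upstream flanking exon to the target, the target to the
downstream flanking exon (inclusion-supporting, with a minimum overhang on
both sides), or the upstream directly to the downstream exon
(exclusion-supporting, i.e. skipping).  PSI is estimated as

    psi = (I/2) / (I/2 + E)

where the halving balances the two inclusion junction classes against the
single skipping junction.  This closed-form estimator, together with a
Beta-posterior Savage-Dickey Bayes factor for the between-condition
difference, is a defined, testable stand-in for the Bayesian samplers of
isoform-quantification tools, while honoring the same downstream filter
semantics (num-inc 1, num-exc 1, delta-psi 0.1, num-total 10,
bayes-factor 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

MIN_OVERHANG = 8

PSI_LOW_MAX = 0.30
PSI_HIGH_MIN = 0.70

FPKM_EXPRESSED_MIN = 0.1


@dataclass(frozen=True)
class JunctionCounts:
    """Inclusion / exclusion junction-read counts for one exon, one condition."""

    exon_id: str
    condition: str
    inclusion_reads: int
    exclusion_reads: int

    def __post_init__(self) -> None:
        if self.inclusion_reads < 0 or self.exclusion_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def informative(self) -> int:
        return self.inclusion_reads + self.exclusion_reads


@dataclass(frozen=True)
class PsiEstimate:
    exon_id: str
    condition: str
    psi: float  # NaN when discarded
    informative: int
    alt_label: str  # alternative / constitutive / discarded


@dataclass(frozen=True)
class PsiDiff:
    exon_id: str
    psi_wt: float
    psi_kd: float
    delta_psi: float  # knockdown minus wild type
    bayes_factor: float
    passes_filter: bool


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    condition: str
    fpkm: float

    @property
    def expressed(self) -> bool:
        return self.fpkm >= FPKM_EXPRESSED_MIN


def _read_junctions(blocks: Sequence[tuple[int, int]]):
    """Splice junctions of one read as ((donor_end, acceptor_start), left_len,
    right_len) triples, from consecutive aligned blocks."""
    for i in range(len(blocks) - 1):
        left, right = blocks[i], blocks[i + 1]
        yield (left[1], right[0]), left[1] - left[0], right[1] - right[0]


def count_informative_reads(
    rna_reads: Iterable[tuple[str, Sequence[tuple[int, int]]]],
    exon_trio: Sequence,
    condition: str = "",
    min_overhang: int = MIN_OVERHANG,
) -> JunctionCounts:
    """Classify spliced reads against an (upstream, target, downstream) trio.

    ``rna_reads`` yields (chrom, blocks) with blocks as sorted (start, end)
    pairs.  ``exon_trio`` holds three non-overlapping exon-like records
    (``chrom``, ``start``, ``end``); the genomically middle one is the
    target, so the rule is strand-agnostic.  A read is exclusion-supporting
    when any of its junctions joins the outer exons, else
    inclusion-supporting when a junction joins a flank to the target with at
    least ``min_overhang`` aligned bases on both sides.
    """
    if len(exon_trio) != 3:
        raise ValueError("exon_trio must contain exactly three exons")
    trio = sorted(exon_trio, key=lambda e: (e.start, e.end))
    for a, b in zip(trio, trio[1:]):
        if b.start < a.end:
            raise ValueError("trio exons overlap")
    left, target, right = trio
    chrom = target.chrom
    inclusion_junctions = {
        (left.end, target.start),
        (target.end, right.start),
    }
    exclusion_junction = (left.end, right.start)
    target_id = getattr(target, "exon_id", f"{chrom}:{target.start}-{target.end}")

    n_inc = n_exc = 0
    for read_chrom, blocks in rna_reads:
        if read_chrom != chrom:
            continue
        is_exc = False
        is_inc = False
        for junction, llen, rlen in _read_junctions(blocks):
            if junction == exclusion_junction:
                is_exc = True
            elif junction in inclusion_junctions:
                if llen >= min_overhang and rlen >= min_overhang:
                    is_inc = True
        if is_exc:
            n_exc += 1
        elif is_inc:
            n_inc += 1
    return JunctionCounts(target_id, condition, n_inc, n_exc)


def estimate_psi(counts: JunctionCounts) -> PsiEstimate:
    """Closed-form PSI with alternative/constitutive labelling.

    Exons with no informative reads are discarded; any exclusion-supporting
    read makes the exon alternative, otherwise it is constitutive.
    """
    i_half = counts.inclusion_reads / 2.0
    informative = counts.informative
    if informative == 0:
        return PsiEstimate(counts.exon_id, counts.condition, float("nan"), 0, "discarded")
    psi = i_half / (i_half + counts.exclusion_reads)
    label = "alternative" if counts.exclusion_reads >= 1 else "constitutive"
    return PsiEstimate(counts.exon_id, counts.condition, psi, informative, label)


def _posterior(counts: JunctionCounts, prior_a: float, prior_b: float):
    return prior_a + counts.inclusion_reads / 2.0, prior_b + counts.exclusion_reads


def differential_psi(
    counts_wt: JunctionCounts,
    counts_kd: JunctionCounts,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
    n_grid: int = 1001,
    min_delta: float = 0.1,
    min_total: int = 10,
    min_bayes_factor: float = 1.0,
) -> PsiDiff:
    """Differential inclusion between conditions with the five-way filter.

    Each condition's PSI posterior is Beta(prior_a + I/2, prior_b + E); the
    reported per-condition PSI and delta come from the posterior means.  The
    Bayes factor for delta != 0 is the Savage-Dickey ratio of the prior to
    the posterior density of the difference at zero, both evaluated on a
    uniform grid.  The filter requires >= 1 inclusion read in the condition
    favoring inclusion, >= 1 exclusion read in the condition favoring
    exclusion, |delta| >= min_delta, total informative reads across the two
    conditions >= min_total, and Bayes factor >= min_bayes_factor.
    """
    if counts_wt.exon_id != counts_kd.exon_id and counts_wt.exon_id and counts_kd.exon_id:
        raise ValueError("conditions refer to different exons")
    a_wt, b_wt = _posterior(counts_wt, prior_a, prior_b)
    a_kd, b_kd = _posterior(counts_kd, prior_a, prior_b)
    psi_wt = a_wt / (a_wt + b_wt)
    psi_kd = a_kd / (a_kd + b_kd)
    delta = psi_kd - psi_wt

    x = np.linspace(0.0, 1.0, n_grid)
    post_wt = stats.beta.pdf(x, a_wt, b_wt)
    post_kd = stats.beta.pdf(x, a_kd, b_kd)
    prior = stats.beta.pdf(x, prior_a, prior_b)
    # density of (psi_kd - psi_wt) at 0 is the overlap integral of the two
    # marginal densities
    post_zero = float(np.trapezoid(post_wt * post_kd, x))
    prior_zero = float(np.trapezoid(prior * prior, x))
    bayes_factor = np.inf if post_zero == 0 else prior_zero / post_zero

    favors_inclusion = counts_wt if psi_wt >= psi_kd else counts_kd
    favors_exclusion = counts_kd if favors_inclusion is counts_wt else counts_wt
    passes = (
        favors_inclusion.inclusion_reads >= 1
        and favors_exclusion.exclusion_reads >= 1
        and abs(delta) >= min_delta
        and counts_wt.informative + counts_kd.informative >= min_total
        and bayes_factor >= min_bayes_factor
    )
    return PsiDiff(
        counts_wt.exon_id or counts_kd.exon_id,
        psi_wt,
        psi_kd,
        delta,
        bayes_factor,
        passes,
    )


def fpkm(
    gene_reads: int,
    gene_exonic_length: int,
    library_size: int,
    gene_id: str = "",
    condition: str = "",
) -> ExpressionRecord:
    """Fragments per kilobase of exon model per million mapped fragments."""
    if gene_exonic_length <= 0 or library_size <= 0:
        raise ValueError("gene_exonic_length and library_size must be positive")
    if gene_reads < 0:
        raise ValueError("gene_reads must be non-negative")
    value = gene_reads * 1e9 / (gene_exonic_length * library_size)
    return ExpressionRecord(gene_id, condition, value)


def psi_bin_labels(
    estimates: Iterable[PsiEstimate],
) -> dict[str, list[PsiEstimate]]:
    """Partition alternative exons into low (psi < 0.30) and high (psi > 0.70)
    inclusion groups; the middle band is excluded (strict inequalities)."""
    groups: dict[str, list[PsiEstimate]] = {"low": [], "high": []}
    for est in estimates:
        if est.alt_label != "alternative" or not np.isfinite(est.psi):
            continue
        if est.psi < PSI_LOW_MAX:
            groups["low"].append(est)
        elif est.psi > PSI_HIGH_MIN:
            groups["high"].append(est)
    return groups


def iter_block_reads(df) -> Iterable[tuple[str, list[tuple[int, int]]]]:
    """Yield (chrom, blocks) from a block-tabular frame with comma-separated
    ``block_starts`` / ``block_ends`` columns."""
    for chrom, bs, be in zip(df["chrom"], df["block_starts"], df["block_ends"]):
        starts = [int(v) for v in str(bs).split(",")]
        ends = [int(v) for v in str(be).split(",")]
        yield chrom, list(zip(starts, ends))
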