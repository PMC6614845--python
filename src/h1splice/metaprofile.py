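"""Anchor-aligned signal matrices, aggregated meta-profiles and tests.

A SignalMatrix holds one row of per-base signal per exon, aligned at either
the exon start (3'ss side) or exon end (5'ss side) and always oriented
5'->3' of the gene (minus-strand rows are reversed).  Meta-profiles are
column means with optional normalization (divide by the profile minimum, or
by the first exonic base) and optional non-overlapping binning.

The randomization occupancy test draws M random L bp intervals from a
target region set and compares their overall mean signal against N such
sample means drawn from the gene space, giving empirical one-sided p-values
with the +1/(N+1) correction (so p is never exactly 0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .annotation import ExonRecord, RegionSet
from .signal_tracks import SignalTrack

ANCHORS = ("exon_start", "exon_end")
NORMALIZATIONS = ("none", "divide_by_min", "divide_by_first_exon_base")


@dataclass(frozen=True)
class AnchorSpec:
    """Window around a splice-site anchor, in gene orientation.

    ``exon_start`` anchors at the first exonic base (3'ss side): negative
    offsets are upstream intron, offset 0 the first exonic base.
    ``exon_end`` anchors at the last exonic base (5'ss side): offset 0 is the
    last exonic base, positive offsets run into the downstream intron.
    """

    anchor: str
    upstream_bp: int
    downstream_bp: int

    def __post_init__(self) -> None:
        if self.anchor not in ANCHORS:
            raise ValueError(f"unknown anchor {self.anchor!r}")
        if self.upstream_bp <= 0 or self.downstream_bp <= 0:
            raise ValueError("window widths must be > 0")

    @property
    def width(self) -> int:
        return self.upstream_bp + self.downstream_bp

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.upstream_bp, self.downstream_bp)

    @property
    def anchor_col(self) -> int:
        """Column index of offset 0 (the anchored exonic boundary base)."""
        return self.upstream_bp


@dataclass
class SignalMatrix:
    """Per-exon anchored signal rows; NaN marks positions beyond the genome."""

    values: np.ndarray  # (n_exons, width)
    row_ids: list[str]
    spec: AnchorSpec
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), self.spec.width):
            raise ValueError("matrix shape inconsistent with row ids / window")

    @property
    def anchor_col(self) -> int:
        return self.spec.anchor_col


@dataclass
class MetaProfile:
    offsets: np.ndarray  # offset (or bin-center offset) per column
    mean: np.ndarray
    n: np.ndarray  # contributing rows per offset (min over bin for bins)
    normalization: str
    bin_width: int | None = None


@dataclass
class RandomizationResult:
    observed_mean: float
    baseline_means: np.ndarray
    p_enriched: float
    p_depleted: float
    m_intervals: int
    interval_length: int
    n_repetitions: int


def _anchor_base(exon: ExonRecord, anchor: str) -> int:
    """Genomic position of the anchored base, in gene orientation.

    first exonic base: start (+) / end-1 (-);
    last exonic base:  end-1 (+) / start (-).
    """
    if anchor == "exon_start":
        return exon.start if exon.strand == "+" else exon.end - 1
    return exon.end - 1 if exon.strand == "+" else exon.start


def extract_matrix(
    track: SignalTrack, exons: Sequence[ExonRecord], spec: AnchorSpec
) -> SignalMatrix:
    """One anchored, strand-oriented signal row per exon."""
    if len(exons) == 0:
        raise ValueError("empty exon list")
    offs = spec.offsets
    rows = np.empty((len(exons), spec.width))
    ids = []
    for i, exon in enumerate(exons):
        a = _anchor_base(exon, spec.anchor)
        if exon.strand == "+":
            rows[i] = track.values(exon.chrom, a + offs[0], a + offs[-1] + 1)
        else:
            # gene orientation runs right-to-left on the genome
            vals = track.values(exon.chrom, a - offs[-1], a - offs[0] + 1)
            rows[i] = vals[::-1]
        ids.append(exon.exon_id)
    return SignalMatrix(rows, ids, spec, units=track.units)


def aggregate(
    matrix: SignalMatrix,
    normalization: str = "none",
    bin_width: int | None = None,
) -> MetaProfile:
    """Column means (missing cells excluded), then normalization, then bins.

    ``divide_by_min`` rescales so the profile minimum is exactly 1 and
    raises if the minimum is not positive (difference tracks are profiled
    unnormalized instead of being silently shifted).
    ``divide_by_first_exon_base`` divides by the mean at the anchored exonic
    boundary base (offset 0).
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}")
    if matrix.values.shape[0] == 0:
        raise ValueError("empty matrix")
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # columns with no observed value (e.g. no CpG in any row) are NaN
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        mean = np.nanmean(matrix.values, axis=0)
    n = np.isfinite(matrix.values).sum(axis=0)
    offsets = matrix.spec.offsets.astype(float)

    if normalization == "divide_by_min":
        lo = np.nanmin(mean)
        if not lo > 0:
            raise ValueError(
                "divide_by_min requires a strictly positive profile minimum"
            )
        mean = mean / lo
    elif normalization == "divide_by_first_exon_base":
        ref = mean[matrix.anchor_col]
        if not np.isfinite(ref) or ref == 0:
            raise ValueError("first-exonic-base value is zero or missing")
        mean = mean / ref

    if bin_width is not None:
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        nbins = len(mean) // bin_width
        if nbins == 0:
            raise ValueError("bin_width larger than the window")
        use = nbins * bin_width
        mean = mean[:use].reshape(nbins, bin_width).mean(axis=1)
        n = n[:use].reshape(nbins, bin_width).min(axis=1)
        offsets = offsets[:use].reshape(nbins, bin_width).mean(axis=1)
    return MetaProfile(offsets, mean, n, normalization, bin_width)


class _RegionSampler:
    """Uniform sampler of L bp windows over a region set, with a cumulative-sum
    cache of the track so each sample mean costs O(M)."""

    def __init__(self, track: SignalTrack, regions: RegionSet, length: int):
        self.length = length
        ivs = [(c, s, e) for c, s, e in regions.intervals if e - s >= length]
        if not ivs:
            raise ValueError(
                f"no interval in {regions.category!r} region set can hold {length} bp"
            )
        self.chroms = sorted({c for c, _, _ in ivs})
        self.chrom_index = {c: i for i, c in enumerate(self.chroms)}
        self.iv_chrom = np.array([self.chrom_index[c] for c, _, _ in ivs])
        self.iv_start = np.array([s for _, s, _ in ivs])
        n_starts = np.array([e - s - length + 1 for _, s, e in ivs])
        self.cum = np.cumsum(n_starts)
        self.total = int(self.cum[-1])
        self._cs = {}
        self._cnt = {}  # None when the chromosome has no missing values
        for c in self.chroms:
            arr = track.data[c]
            finite = np.isfinite(arr)
            if finite.all():
                self._cs[c] = np.concatenate([[0.0], np.cumsum(arr)])
                self._cnt[c] = None
            else:
                vals = np.where(finite, arr, 0.0)
                self._cs[c] = np.concatenate([[0.0], np.cumsum(vals)])
                self._cnt[c] = np.concatenate(
                    [[0], np.cumsum(finite.astype(np.int64))]
                )

    def sample_mean(self, m: int, rng: np.random.Generator) -> float:
        """Mean track value over m random L bp windows (with replacement)."""
        r = rng.integers(0, self.total, size=m)
        idx = np.searchsorted(self.cum, r, side="right")
        offset = r - np.concatenate([[0], self.cum])[idx]
        starts = self.iv_start[idx] + offset
        total = 0.0
        count = 0
        for c in self.chroms:
            mask = self.iv_chrom[idx] == self.chrom_index[c]
            if not mask.any():
                continue
            s = starts[mask]
            cs, cnt = self._cs[c], self._cnt[c]
            total += float((cs[s + self.length] - cs[s]).sum())
            if cnt is None:
                count += int(mask.sum()) * self.length
            else:
                count += int((cnt[s + self.length] - cnt[s]).sum())
        if count == 0:
            return math.nan
        return total / count


def randomization_test(
    track: SignalTrack,
    target: RegionSet,
    gene_space: RegionSet,
    m_intervals: int = 10_000,
    interval_length: int = 50,
    n_repetitions: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> RandomizationResult:
    """Randomization occupancy test for a region category.

    The observed statistic is the mean signal over ``m_intervals`` random
    windows of ``interval_length`` bp drawn uniformly (with replacement)
    from the target set; the baseline is ``n_repetitions`` such means drawn
    from the gene space.  p_enriched = (1 + #{baseline >= observed}) /
    (n_repetitions + 1), and p_depleted analogously.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    target_sampler = _RegionSampler(track, target, interval_length)
    space_sampler = _RegionSampler(track, gene_space, interval_length)
    observed = target_sampler.sample_mean(m_intervals, rng)
    baseline = np.array(
        [space_sampler.sample_mean(m_intervals, rng) for _ in range(n_repetitions)]
    )
    p_enr = (1 + int((baseline >= observed).sum())) / (n_repetitions + 1)
    p_dep = (1 + int((baseline <= observed).sum())) / (n_repetitions + 1)
    return RandomizationResult(
        observed, baseline, p_enr, p_dep, m_intervals, interval_length, n_repetitions
    )


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group labelings.

    Midranks are used, so ties are handled exactly.  Feasible only for small
    pooled sizes; callers gate on n.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    observed = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    obs_dev = abs(observed - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "wilcoxon_rank_sum",
) -> float:
    """Two-sided p-value for a two-group comparison.

    ``wilcoxon_rank_sum`` uses exact enumeration for small samples (scipy's
    exact null without ties; exhaustive labeling enumeration with ties) and
    the tie-corrected normal approximation otherwise; ``two_sample_t`` is
    Student's t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "two_sample_t":
        return float(stats.ttest_ind(a, b).pvalue)
    if test != "wilcoxon_rank_sum":
        raise ValueError(f"unknown test {test!r}")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(a) <= 20 and len(b) <= 20
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.pvalue)
    if has_ties and len(pooled) <= 14:
        return _exact_ranksum_p(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def write_profile_tsv(profile: MetaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean\tn\n")
        for o, m, n in zip(profile.offsets, profile.mean, profile.n):
            fh.write(f"{o:g}\t{m:.6g}\t{n:g}\n")


def write_randomization_tsv(result: RandomizationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "observed_mean\tbaseline_mean\tbaseline_sd\tp_enriched\tp_depleted\t"
            "m_intervals\tinterval_length\tn_repetitions\n"
        )
        fh.write(
            f"{result.observed_mean:.6g}\t{result.baseline_means.mean():.6g}\t"
            f"{result.baseline_means.std(ddof=1):.6g}\t{result.p_enriched:.6g}\t"
            f"{result.p_depleted:.6g}\t{result.m_intervals}\t"
            f"{result.interval_length}\t{result.n_repetitions}\n"
        )
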