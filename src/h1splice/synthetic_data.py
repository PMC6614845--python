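"""Synthetic genome, annotation, reads and methylation with planted truth.

The generator emulates the statistical structure of the study system so the
whole pipeline is testable without external data:

* multi-exon genes whose internal exons are assigned a chromatin class
  (``marked_3ss`` / ``marked_5ss`` / ``distant`` / ``unmarked``);
* nucleosomes aligned at exon borders (edge 35 bp upstream of the start or
  45 bp downstream of the end, wrapping 146 bp), with the linker-histone
  site planted in the linker DNA just beyond the nucleosome edge nearer the
  relevant splice site — so the splice sites of exons near the optimal
  length fall under the linker histone, and the planted distance from a
  splice site to the site decreases with exon length;
* distant exons carry a linker-histone site a few hundred bp into *both*
  flanking introns (distant signal must be seen from both junction-anchored
  windows);
* ChIP libraries (linker histone, input, MNase, RNAP II with 3'ss pausing
  on marked exons) as single-end reads from fragments, emitted from the
  fragment 5' end on a random strand;
* spliced RNA reads per condition with planted per-exon inclusion levels;
  the knockdown condition lowers inclusion of marked exons only;
* per-CpG bisulfite methylation counts, elevated around marked and distant
  exons;
* higher exon than intron GC in the long-intron (low-GC) gene regime, and
  a short-intron high-GC regime hosting unmarked exons only.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import annotation, splice_strength
from .annotation import ExonRecord, TranscriptModel

BASES = np.frombuffer(b"ACGT", dtype="S1")

EXON_CLASSES = ("marked_3ss", "marked_5ss", "distant", "unmarked")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Exon lengths are lognormal with median ~110 bp and a spread putting the
    upper quartile at ~127 bp, matching the short-exon bias of linker-
    histone-marked exons.  ChIP geometry is 51 bp reads from 225 bp
    fragments (shift 87 bp); MNase restores a 147 bp footprint.
    """

    n_genes: int = 60
    chrom: str = "chr1"
    left_pad: int = 3000
    intergenic: int = 1200
    min_exons: int = 4
    max_exons: int = 7
    # exon lengths (bp): lognormal per class; marked exons have median 110
    # with ~75% <= 127, distant exons ~75% <= 141, unmarked exons are longer
    exon_len_median: float = 110.0
    exon_len_median_distant: float = 122.0
    exon_len_median_unmarked: float = 135.0
    exon_len_sigma: float = 0.213
    exon_len_min: int = 55
    exon_len_max: int = 400
    # intron lengths per GC regime
    long_intron_median: float = 950.0
    long_intron_sigma: float = 0.25
    long_intron_min: int = 660
    short_intron_median: float = 300.0
    short_intron_sigma: float = 0.25
    short_intron_min: int = 160
    frac_short_intron_genes: float = 0.3
    # class probabilities for eligible exons within long-intron genes
    p_marked_3ss: float = 0.25
    p_marked_5ss: float = 0.25
    p_distant: float = 0.25
    # base composition
    exon_gc: float = 0.55
    intron_gc: float = 0.40
    exon_gc_high: float = 0.60
    intron_gc_high: float = 0.58
    # nucleosome / linker geometry
    wrap_bp: int = 146
    upstream_edge_offset: int = 35
    downstream_edge_offset: int = 45
    # planted ChIP-site center beyond the core-particle edge: midpoint of the
    # ~20-40 bp linker stretch contacted by the linker-histone C-terminal tail
    linker_offset: int = 30
    distant_lo: int = 210
    distant_hi: int = 270
    # ChIP libraries
    chip_read_len: int = 51
    chip_frag_len: int = 225
    chip_coverage: float = 30.0
    chip_enrichment: float = 5.0
    site_jitter_sd: float = 10.0
    mnase_read_len: int = 50
    mnase_frag_len: int = 147
    mnase_coverage: float = 30.0
    mnase_enrichment: float = 4.0
    dyad_jitter_sd: float = 5.0
    rnap_coverage: float = 30.0
    rnap_pause_enrichment: float = 3.0
    pause_jitter_sd: float = 15.0
    # RNA libraries
    rna_read_len: int = 60
    rna_depth: int = 300  # transcript molecules sampled per internal exon
    min_overhang: int = 8
    delta_psi: float = 0.3
    frac_constitutive: float = 0.3
    # methylation
    meth_background: float = 0.4
    meth_elevated: float = 0.8
    meth_window: int = 200
    meth_depth: float = 30.0

    def __post_init__(self) -> None:
        for name in ("frac_short_intron_genes", "frac_constitutive", "delta_psi"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_marked_3ss + self.p_marked_5ss + self.p_distant > 1:
            raise ValueError("class probabilities exceed 1")
        if self.min_exons < 4:
            raise ValueError("genes need >= 4 exons (>= 2 internal)")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float, lo: int, hi: int
) -> np.ndarray:
    vals = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.clip(np.round(vals).astype(int), lo, hi)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _sample_pwm(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    out = np.empty(len(freqs), dtype="S1")
    for i, row in enumerate(freqs):
        out[i] = BASES[rng.choice(4, p=row)]
    return out


@dataclass
class SimStudy:
    """Everything one simulated study comprises."""

    config: SimConfig
    genome: dict[str, str]
    models: list[TranscriptModel]
    exons: list[ExonRecord]
    truth: pd.DataFrame
    chip_reads: dict[str, pd.DataFrame] | None = None
    rna_reads: dict[str, pd.DataFrame] | None = None
    methylation: pd.DataFrame | None = None

    @property
    def genome_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_genome_and_annotation(
    config: SimConfig, seed: int | np.random.Generator = 0
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame]:
    """Build the genome sequence, transcript models and per-exon truth table.

    Genes alternate strand at random; the gene sequence is constructed in
    transcript orientation (consensus donor/acceptor sites sampled from the
    default frequency tables, so every intron starts GT and ends AG) and
    reverse-complemented into the genome for minus-strand genes.
    """
    rng = _rng(seed)
    cfg = config
    donor = splice_strength.default_donor_table()
    acceptor = splice_strength.default_acceptor_table()

    chrom_parts: list[np.ndarray] = [
        _random_bases(rng, cfg.left_pad, cfg.intron_gc)
    ]
    cursor = cfg.left_pad
    models: list[TranscriptModel] = []
    truth_rows: list[dict] = []

    wrap = cfg.wrap_bp
    half = wrap // 2

    for gi in range(cfg.n_genes):
        gene_id = f"gene{gi:04d}"
        tx_id = f"tx{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        short_regime = rng.random() < cfg.frac_short_intron_genes
        exon_gc = cfg.exon_gc_high if short_regime else cfg.exon_gc
        intron_gc = cfg.intron_gc_high if short_regime else cfg.intron_gc

        n_exons = int(rng.integers(cfg.min_exons, cfg.max_exons + 1))
        # classes first (unmarked-only in the short-intron regime), then
        # class-specific exon lengths: marked exons are the shortest.
        # Chromatin classes and alternative splicing are planted only on
        # every other internal exon so that no two alternative exons are
        # adjacent — the two-isoform exon-trio model assumes constitutive
        # flanks, and the generator emulates that measurement condition.
        classes: list[str | None] = [None] * n_exons
        for j in range(1, n_exons - 1):
            if short_regime or j % 2 == 0:
                classes[j] = "unmarked"
                continue
            u = rng.random()
            if u < cfg.p_marked_3ss:
                classes[j] = "marked_3ss"
            elif u < cfg.p_marked_3ss + cfg.p_marked_5ss:
                classes[j] = "marked_5ss"
            elif u < cfg.p_marked_3ss + cfg.p_marked_5ss + cfg.p_distant:
                classes[j] = "distant"
            else:
                classes[j] = "unmarked"
        # marked exons are capped at the nucleosome wrap: splice-site-
        # proximal linker-histone marking is only geometrically possible for
        # exons no longer than the wrapped DNA
        medians = {
            None: (cfg.exon_len_median_unmarked, cfg.exon_len_max),
            "unmarked": (cfg.exon_len_median_unmarked, cfg.exon_len_max),
            "distant": (cfg.exon_len_median_distant, cfg.exon_len_max),
            "marked_3ss": (cfg.exon_len_median, cfg.wrap_bp),
            "marked_5ss": (cfg.exon_len_median, cfg.wrap_bp),
        }
        exon_lens = np.array(
            [
                _lognormal_lengths(
                    rng, 1, medians[classes[j]][0], cfg.exon_len_sigma,
                    cfg.exon_len_min, medians[classes[j]][1],
                )[0]
                for j in range(n_exons)
            ]
        )
        if short_regime:
            intron_lens = _lognormal_lengths(
                rng, n_exons - 1, cfg.short_intron_median, cfg.short_intron_sigma,
                cfg.short_intron_min, 10 * int(cfg.short_intron_median),
            )
        else:
            intron_lens = _lognormal_lengths(
                rng, n_exons - 1, cfg.long_intron_median, cfg.long_intron_sigma,
                cfg.long_intron_min, 10 * int(cfg.long_intron_median),
            )

        # transcript-orientation layout
        exon_tx: list[tuple[int, int]] = []
        pos = 0
        for j in range(n_exons):
            exon_tx.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        gene_len = pos

        seq = np.empty(gene_len, dtype="S1")
        for j, (es, ee) in enumerate(exon_tx):
            seq[es:ee] = _random_bases(rng, ee - es, exon_gc)
            if j < n_exons - 1:
                iv = (ee, exon_tx[j + 1][0])
                seq[iv[0] : iv[1]] = _random_bases(rng, iv[1] - iv[0], intron_gc)
        # plant splice-site consensus over every exon|intron boundary
        for j in range(n_exons - 1):
            ee = exon_tx[j][1]
            seq[ee - 3 : ee + 6] = _sample_pwm(rng, donor.freqs)
            ns = exon_tx[j + 1][0]
            seq[ns - 14 : ns + 3] = _sample_pwm(rng, acceptor.freqs)

        # genomic placement
        g0 = cursor
        if strand == "+":
            genomic_seq = seq
            exon_genomic = [(g0 + s, g0 + e) for s, e in exon_tx]

            def to_genomic(p: int) -> int:
                return g0 + p

        else:
            comp = np.empty_like(seq)
            lookup = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
            for b, c in lookup.items():
                comp[seq == b[0:1]] = c
            genomic_seq = comp[::-1]
            exon_genomic = sorted(
                (g0 + gene_len - e, g0 + gene_len - s) for s, e in exon_tx
            )

            def to_genomic(p: int) -> int:
                return g0 + gene_len - 1 - p

        chrom_parts.append(genomic_seq)
        chrom_parts.append(_random_bases(rng, cfg.intergenic, cfg.intron_gc))
        cursor += gene_len + cfg.intergenic

        models.append(
            TranscriptModel(tx_id, gene_id, cfg.chrom, strand, tuple(exon_genomic))
        )

        # per internal exon: class, geometry and inclusion truth
        for j in range(1, n_exons - 1):
            es, ee = exon_tx[j]
            length = ee - es
            klass = classes[j]

            h1_sites: list[int] = []
            dyad_tx: int | None = None
            if klass == "marked_5ss":
                # nucleosome edge 35 bp upstream of the exon start; the
                # linker histone sits just beyond the opposite (5'ss-side)
                # edge, linker_offset bp into the linker DNA
                edge = es - cfg.upstream_edge_offset
                dyad_tx = edge + half
                h1_sites = [edge + wrap + cfg.linker_offset]
            elif klass == "marked_3ss":
                edge_end = ee + cfg.downstream_edge_offset
                dyad_tx = edge_end - half
                h1_sites = [edge_end - wrap - cfg.linker_offset]
            elif klass == "distant":
                d1 = int(rng.integers(cfg.distant_lo, cfg.distant_hi + 1))
                d2 = int(rng.integers(cfg.distant_lo, cfg.distant_hi + 1))
                h1_sites = [es - d1, ee - 1 + d2]
                dyad_tx = (es + ee) // 2 + int(rng.normal(0, 20))
            else:
                if rng.random() < 0.5:
                    dyad_tx = (es + ee) // 2 + int(rng.normal(0, 30))

            marked = klass in ("marked_3ss", "marked_5ss")
            evaluated = j % 2 == 1 and not short_regime
            if marked:
                psi_wt = float(rng.uniform(0.45, 0.95))
                psi_kd = max(0.05, psi_wt - cfg.delta_psi)
            else:
                if not evaluated or rng.random() < cfg.frac_constitutive:
                    psi_wt = 1.0
                else:
                    psi_wt = float(rng.uniform(0.05, 0.95))
                psi_kd = psi_wt

            g_start, g_end = sorted((to_genomic(es), to_genomic(ee - 1)))
            g_end += 1
            left_tx, right_tx = exon_tx[j - 1], exon_tx[j + 1]
            flanks = sorted(
                sorted((to_genomic(s), to_genomic(e - 1))) for s, e in (left_tx, right_tx)
            )
            truth_rows.append(
                {
                    "exon_id": f"{cfg.chrom}:{g_start}-{g_end}",
                    "chrom": cfg.chrom,
                    "start": g_start,
                    "end": g_end,
                    "strand": strand,
                    "gene_id": gene_id,
                    "ordinal": j + 1 if strand == "+" else n_exons - j,
                    "length": length,
                    "klass": klass,
                    "psi_wt": psi_wt,
                    "psi_kd": psi_kd,
                    "h1_sites": ";".join(str(to_genomic(p)) for p in h1_sites),
                    "nuc_dyad": -1 if dyad_tx is None else to_genomic(dyad_tx),
                    "pause_strength": cfg.rnap_pause_enrichment if marked else 1.0,
                    "meth_elevated": klass != "unmarked",
                    "pos_3ss": to_genomic(es),
                    "pos_5ss": to_genomic(ee - 1),
                    "left_start": flanks[0][0],
                    "left_end": flanks[0][1] + 1,
                    "right_start": flanks[1][0],
                    "right_end": flanks[1][1] + 1,
                }
            )

    chrom_parts.append(_random_bases(rng, cfg.left_pad, cfg.intron_gc))
    chrom_seq = b"".join(part.tobytes() for part in chrom_parts).decode()
    genome = {cfg.chrom: chrom_seq}
    truth = pd.DataFrame(truth_rows)
    return genome, models, truth


def _reads_from_fragments(
    rng: np.random.Generator,
    frag_starts: np.ndarray,
    frag_len: int,
    read_len: int,
    chrom: str,
    size: int,
) -> pd.DataFrame:
    """Single-end reads from fragment 5' ends on uniformly random strands."""
    n = len(frag_starts)
    plus = rng.random(n) < 0.5
    starts = np.where(plus, frag_starts, frag_starts + frag_len - read_len)
    ends = starts + read_len
    starts = np.clip(starts, 0, size)
    ends = np.clip(ends, 0, size)
    keep = ends > starts
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts[keep].astype(int),
            "end": ends[keep].astype(int),
            "strand": np.where(plus[keep], "+", "-"),
        }
    )


def simulate_chip_libraries(
    truth: pd.DataFrame,
    config: SimConfig,
    genome_sizes: Mapping[str, int],
    gene_regions: Iterable[tuple[str, int, int]] | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, pd.DataFrame]:
    """Reads for the four DNA libraries: h1, input, mnase, rnapii.

    Backgrounds are uniform fragment processes at the configured coverage;
    planted features add Poisson numbers of fragments whose centers jitter
    normally around the feature.  ``chip_enrichment`` rho means the local
    coverage at a linker-histone site is ~rho times background.
    """
    rng = _rng(seed)
    cfg = config
    (chrom, size), = [(c, s) for c, s in genome_sizes.items()]  # single-chrom sim
    libs: dict[str, pd.DataFrame] = {}

    def uniform_frag_starts(n: int, frag_len: int) -> np.ndarray:
        return rng.integers(0, size - frag_len, size=n)

    def site_frag_starts(centers: np.ndarray, per_site: np.ndarray,
                         frag_len: int, jitter: float) -> np.ndarray:
        reps = np.repeat(centers, per_site)
        jit = rng.normal(0, jitter, size=len(reps))
        return np.round(reps + jit - frag_len / 2).astype(int)

    half_cov = cfg.chip_coverage
    n_bg = int(round(half_cov * size / cfg.chip_read_len))

    # --- linker-histone ChIP + input
    h1_centers = []
    for s in truth["h1_sites"]:
        if s:
            h1_centers.extend(int(v) for v in s.split(";"))
    h1_centers = np.array(sorted(h1_centers), dtype=int)
    per_site = rng.poisson(
        (cfg.chip_enrichment - 1.0) * cfg.chip_coverage, size=len(h1_centers)
    )
    frag_starts = np.concatenate(
        [
            uniform_frag_starts(n_bg, cfg.chip_frag_len),
            site_frag_starts(h1_centers, per_site, cfg.chip_frag_len, cfg.site_jitter_sd),
        ]
    )
    libs["h1"] = _reads_from_fragments(
        rng, frag_starts, cfg.chip_frag_len, cfg.chip_read_len, chrom, size
    )
    libs["input"] = _reads_from_fragments(
        rng, uniform_frag_starts(n_bg, cfg.chip_frag_len),
        cfg.chip_frag_len, cfg.chip_read_len, chrom, size,
    )

    # --- MNase: fragments centered on nucleosome dyads
    n_bg_mnase = int(round(cfg.mnase_coverage * size / cfg.mnase_read_len))
    dyads = truth.loc[truth["nuc_dyad"] >= 0, "nuc_dyad"].to_numpy(int)
    per_dyad = rng.poisson(
        (cfg.mnase_enrichment - 1.0) * cfg.mnase_coverage, size=len(dyads)
    )
    frag_starts = np.concatenate(
        [
            uniform_frag_starts(n_bg_mnase, cfg.mnase_frag_len),
            site_frag_starts(dyads, per_dyad, cfg.mnase_frag_len, cfg.dyad_jitter_sd),
        ]
    )
    libs["mnase"] = _reads_from_fragments(
        rng, frag_starts, cfg.mnase_frag_len, cfg.mnase_read_len, chrom, size
    )

    # --- RNAP II: background over gene bodies, pausing at 3'ss of marked exons
    if gene_regions is not None:
        regions = [(c, s, e) for c, s, e in gene_regions if e - s > cfg.chip_frag_len]
        weights = np.array([e - s for _, s, e in regions], dtype=float)
        n_rnap = int(round(cfg.rnap_coverage * weights.sum() / cfg.chip_read_len))
        which = rng.choice(len(regions), size=n_rnap, p=weights / weights.sum())
        offs = rng.random(n_rnap)
        frag_starts = np.array(
            [
                regions[w][1] + int(o * (regions[w][2] - regions[w][1] - cfg.chip_frag_len))
                for w, o in zip(which, offs)
            ]
        )
    else:
        n_rnap = int(round(cfg.rnap_coverage * size / cfg.chip_read_len))
        frag_starts = uniform_frag_starts(n_rnap, cfg.chip_frag_len)
    pause_sites = truth.loc[truth["pause_strength"] > 1.0, "pos_3ss"].to_numpy(int)
    pause_extra = truth.loc[truth["pause_strength"] > 1.0, "pause_strength"].to_numpy()
    per_pause = rng.poisson((pause_extra - 1.0) * cfg.rnap_coverage)
    frag_starts = np.concatenate(
        [
            frag_starts,
            site_frag_starts(pause_sites, per_pause, cfg.chip_frag_len, cfg.pause_jitter_sd),
        ]
    )
    libs["rnapii"] = _reads_from_fragments(
        rng, frag_starts, cfg.chip_frag_len, cfg.chip_read_len, chrom, size
    )
    return libs


def simulate_rna_libraries(
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str,
    models: Iterable[TranscriptModel],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Spliced junction reads for one condition ('wt' or 'kd').

    Per gene, ``rna_depth`` transcript molecules include each alternative
    internal exon independently with probability psi_condition (other exons
    are always included; the generator never plants adjacent alternative
    exons).  A molecule emits one read across every splice junction of its
    exon chain, so an included exon contributes reads to both flanking
    junctions and a skipped exon to the skipping junction.  Every junction
    read has at least ``min_overhang`` bases on both sides.
    """
    if condition not in ("wt", "kd"):
        raise ValueError("condition must be 'wt' or 'kd'")
    rng = _rng(seed)
    cfg = config
    rl = cfg.rna_read_len
    n = cfg.rna_depth
    psi_col = f"psi_{condition}"
    psi_by_id = dict(zip(truth["exon_id"], truth[psi_col]))
    rows: list[tuple[str, str, str, str]] = []

    def emit(chrom: str, strand: str, j0: int, j1: int, count: int) -> None:
        if count <= 0:
            return
        splits = rng.integers(cfg.min_overhang, rl - cfg.min_overhang + 1, size=count)
        for a in splits:
            rows.append((chrom, f"{j0 - a},{j1}", f"{j0},{j1 + rl - a}", strand))

    for m in models:
        exons = list(m.exons)  # genomic order; junction structure is
        # strand-agnostic, so molecules are laid out left to right
        psis = np.ones(len(exons))
        for j in range(1, len(exons) - 1):
            eid = f"{m.chrom}:{exons[j][0]}-{exons[j][1]}"
            psis[j] = psi_by_id.get(eid, 1.0)
        included = rng.binomial(n, psis)  # molecules including each exon
        for j in range(len(exons) - 1):
            # junction present when both exons are included; alternative
            # exons are never adjacent, so one side always has psi = 1
            count = int(min(included[j], included[j + 1]))
            emit(m.chrom, m.strand, exons[j][1], exons[j + 1][0], count)
        for j in range(1, len(exons) - 1):
            if psis[j] < 1.0:
                emit(
                    m.chrom, m.strand,
                    exons[j - 1][1], exons[j + 1][0], n - int(included[j]),
                )
    return pd.DataFrame(rows, columns=["chrom", "block_starts", "block_ends", "strand"])


def simulate_methylation(
    truth: pd.DataFrame,
    config: SimConfig,
    genome: Mapping[str, str],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-CpG binomial methylation counts.

    CpG positions are taken from the genome sequence; positions within
    ``meth_window`` bp of a marked or distant exon draw from the elevated
    proportion, the rest from background.
    """
    rng = _rng(seed)
    cfg = config
    frames = []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        cpg = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G"))
        p = np.full(len(cpg), cfg.meth_background)
        elevated = truth[(truth["chrom"] == chrom) & truth["meth_elevated"]]
        mask = np.zeros(len(arr), dtype=bool)
        for rec in elevated.itertuples():
            lo = max(0, rec.start - cfg.meth_window)
            hi = min(len(arr), rec.end + cfg.meth_window)
            mask[lo:hi] = True
        p[mask[cpg]] = cfg.meth_elevated
        depth = rng.poisson(cfg.meth_depth, size=len(cpg)) + 1
        meth = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": cpg,
                    "methylated_reads": meth,
                    "total_reads": depth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_study(
    config: SimConfig = SimConfig(), seed: int = 0
) -> SimStudy:
    """Run every generator stage with seeds derived from one master seed."""
    seeds = np.random.SeedSequence(seed).generate_state(5) % (2**31)
    genome, models, truth = simulate_genome_and_annotation(config, int(seeds[0]))
    exons = annotation.build_internal_exon_table(models)
    genome_sizes = {c: len(s) for c, s in genome.items()}
    gene_regions = [
        (m.chrom, m.exons[0][0], m.exons[-1][1]) for m in models
    ]
    chip = simulate_chip_libraries(
        truth, config, genome_sizes, gene_regions, int(seeds[1])
    )
    rna = {
        "wt": simulate_rna_libraries(truth, config, "wt", models, int(seeds[2])),
        "kd": simulate_rna_libraries(truth, config, "kd", models, int(seeds[3])),
    }
    meth = simulate_methylation(truth, config, genome, int(seeds[4]))
    return SimStudy(config, genome, models, exons, truth, chip, rna, meth)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";\n'
                )


def write_study(study: SimStudy, outdir: str | Path) -> None:
    """Write every artifact of a simulated study as plain-text files."""
    from .signal_tracks import write_alignments

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, out / "genome.fa")
    write_gtf(study.models, out / "annotation.gtf")
    annotation.write_exon_table(study.exons, out / "internal_exons.tsv")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if study.chip_reads:
        for name, reads in study.chip_reads.items():
            write_alignments(reads, out / f"reads_{name}.tsv")
    if study.rna_reads:
        for cond, reads in study.rna_reads.items():
            reads.to_csv(out / f"rna_{cond}.tsv", sep="\t", index=False)
    if study.methylation is not None:
        study.methylation.to_csv(
            out / "methylation.tsv", sep="\t", index=False, header=False
        )
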