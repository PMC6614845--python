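"""High-level wiring of the pipeline stages.

These helpers chain the module-level operations the way the analysis runs
end to end: reads -> shifted/extended reads -> RPM tracks -> input-corrected
occupancy -> junction-anchored matrices -> k-means exon classes -> splice-
site distances, and RNA reads -> junction counts -> PSI -> differential
filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import exon_classes, metaprofile, psi as psi_mod, signal_tracks
from .annotation import ExonRecord
from .metaprofile import AnchorSpec, SignalMatrix
from .signal_tracks import SignalTrack

# junction-anchored clustering windows (bp): 300 of intron and 150 of exon
# at each splice site, wide enough that a linker-histone site at the
# opposite nucleosome edge (wrap - edge offset + linker, ~111-131 bp into
# the exon) stays inside the window
CLUSTER_INTRON_BP = 300
CLUSTER_EXON_BP = 150

SPEC_3SS = AnchorSpec("exon_start", upstream_bp=CLUSTER_INTRON_BP, downstream_bp=CLUSTER_EXON_BP)
SPEC_5SS = AnchorSpec("exon_end", upstream_bp=CLUSTER_EXON_BP, downstream_bp=CLUSTER_INTRON_BP)


def chip_occupancy_track(
    chip_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    read_len: int = 51,
    frag_len: int = 225,
) -> SignalTrack:
    """Input-corrected ChIP occupancy: shift ChIP reads (not the input) to
    the fragment midpoint, normalize both to RPM, subtract."""
    shift = signal_tracks.fragment_midpoint_shift(read_len, frag_len)
    shifted = signal_tracks.shift_reads(chip_reads, shift, genome_sizes)
    chip = signal_tracks.depth_rpm(shifted, genome_sizes, provenance=f"chip shift={shift}")
    ctrl = signal_tracks.depth_rpm(input_reads, genome_sizes, provenance="input")
    return signal_tracks.subtract_input(chip, ctrl)


def mnase_occupancy_track(
    reads: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    footprint: int = 147,
) -> SignalTrack:
    """Nucleosome occupancy: extend reads to the footprint, RPM depth."""
    extended = signal_tracks.extend_reads(reads, footprint, genome_sizes)
    return signal_tracks.depth_rpm(extended, genome_sizes, provenance=f"mnase ext={footprint}")


@dataclass
class ExonClassification:
    classes: dict[str, str]  # exon_id -> marked_3ss/marked_5ss/distant/unmarked
    pvalues: dict[str, float]
    run_3ss: exon_classes.ClusterAssignment
    run_5ss: exon_classes.ClusterAssignment
    labels_3ss: list
    labels_5ss: list
    matrix_3ss: SignalMatrix
    matrix_5ss: SignalMatrix


def classify_exons(
    track: SignalTrack,
    exons: Sequence[ExonRecord],
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
    near_window: int = 50,
    distant_min: int = 200,
) -> ExonClassification:
    """Two junction-anchored k-means runs, labelled and intersected."""
    mat3 = metaprofile.extract_matrix(track, exons, SPEC_3SS)
    mat5 = metaprofile.extract_matrix(track, exons, SPEC_5SS)
    run3 = exon_classes.kmeans_profiles(mat3, "anchored_3ss", k=k, seed=seed, n_restarts=n_restarts)
    run5 = exon_classes.kmeans_profiles(mat5, "anchored_5ss", k=k, seed=seed, n_restarts=n_restarts)
    lab3 = exon_classes.label_clusters(run3, near_window, distant_min)
    lab5 = exon_classes.label_clusters(run5, near_window, distant_min)
    classes, pvals = exon_classes.intersect_classes(run3, lab3, run5, lab5)
    return ExonClassification(classes, pvals, run3, run5, lab3, lab5, mat3, mat5)


def marked_site_distances(
    classification: ExonClassification,
) -> dict[str, int]:
    """Distance from the marked splice site to the signal peak, per marked exon.

    Exons marked at the 3'ss are measured in the 3'ss-anchored window,
    exons marked at the 5'ss in the 5'ss-anchored window.
    """
    d3 = exon_classes.exon_h1_distances(classification.matrix_3ss, "3ss")
    d5 = exon_classes.exon_h1_distances(classification.matrix_5ss, "5ss")
    out = {}
    for exon_id, klass in classification.classes.items():
        if klass == "marked_3ss" and exon_id in d3:
            out[exon_id] = d3[exon_id]
        elif klass == "marked_5ss" and exon_id in d5:
            out[exon_id] = d5[exon_id]
    return out


def estimate_condition_psi(
    rna_reads: pd.DataFrame,
    trios: pd.DataFrame,
    condition: str,
    min_overhang: int = psi_mod.MIN_OVERHANG,
) -> dict[str, psi_mod.JunctionCounts]:
    """Junction counts per internal exon for one condition.

    ``trios`` needs columns chrom/start/end and left_*/right_* flank
    coordinates (see ``annotation.exon_trios`` or the generator truth).
    Reads are bucketed by their junctions first, so counting is linear in
    the number of reads.
    """

    class _Iv:
        __slots__ = ("chrom", "start", "end", "exon_id")

        def __init__(self, chrom, start, end, exon_id=""):
            self.chrom, self.start, self.end, self.exon_id = chrom, start, end, exon_id

    # index reads by junction for fast lookup
    by_junction: dict[tuple[str, int, int], list[tuple[tuple[int, int], ...]]] = {}
    for chrom, blocks in psi_mod.iter_block_reads(rna_reads):
        for i in range(len(blocks) - 1):
            key = (chrom, blocks[i][1], blocks[i + 1][0])
            by_junction.setdefault(key, []).append(tuple(blocks))

    counts = {}
    for rec in trios.itertuples():
        trio = [
            _Iv(rec.chrom, rec.left_start, rec.left_end),
            _Iv(rec.chrom, rec.start, rec.end, rec.exon_id),
            _Iv(rec.chrom, rec.right_start, rec.right_end),
        ]
        relevant: list[tuple[str, tuple]] = []
        seen: set[int] = set()
        for j0, j1 in (
            (rec.left_end, rec.start),
            (rec.end, rec.right_start),
            (rec.left_end, rec.right_start),
        ):
            for blocks in by_junction.get((rec.chrom, j0, j1), []):
                if id(blocks) not in seen:
                    seen.add(id(blocks))
                    relevant.append((rec.chrom, blocks))
        counts[rec.exon_id] = psi_mod.count_informative_reads(
            relevant, trio, condition=condition, min_overhang=min_overhang
        )
    return counts


def differential_psi_table(
    counts_wt: Mapping[str, psi_mod.JunctionCounts],
    counts_kd: Mapping[str, psi_mod.JunctionCounts],
    **filter_kwargs,
) -> pd.DataFrame:
    """PsiDiff rows (one per exon counted in both conditions)."""
    rows = []
    for exon_id in sorted(set(counts_wt) & set(counts_kd)):
        d = psi_mod.differential_psi(counts_wt[exon_id], counts_kd[exon_id], **filter_kwargs)
        rows.append(
            {
                "exon_id": exon_id,
                "psi_wt": d.psi_wt,
                "psi_kd": d.psi_kd,
                "delta_psi": d.delta_psi,
                "bayes_factor": d.bayes_factor,
                "passes_filter": d.passes_filter,
            }
        )
    return pd.DataFrame(rows)
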