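"""Junction-anchored exon classes and the nucleosome-geometry model.

Exons are grouped by k-means clustering of their linker-histone signal in
two junction-anchored windows (one anchored at the 3'ss, one at the 5'ss).
Cluster centroids are labelled by where they peak (near a splice site,
deep in the intron, or low everywhere), the two runs are intersected, and
each intersection is scored with an upper-tail hypergeometric test:

* marked_3ss / marked_5ss — near-site label at the same site in both runs;
* distant — intronic peak several hundred bp from the site in both runs;
* unmarked — everything else.

The geometry model: a nucleosome wraps ~146 bp of DNA and sits with one
edge a fixed offset outside the exon border, so the splice site of an exon
of near-optimal length falls in the linker DNA where the linker histone
binds.  The optimal exon length is wrap - edge offset, rounded to 10 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .metaprofile import SignalMatrix

logger = logging.getLogger(__name__)

RUNS = ("anchored_3ss", "anchored_5ss")
CLUSTER_LABELS = ("near_3ss", "near_5ss", "distant", "low")
EXON_CLASSES = ("marked_3ss", "marked_5ss", "distant", "unmarked")


@dataclass
class ClusterAssignment:
    """k-means result for one anchored run.

    ``labels[i]`` is the cluster id of ``row_ids[i]``; centroids are raw
    per-base profiles over the run's window.
    """

    run: str
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    row_ids: list[str]
    seed: int
    inertia: float
    matrix: SignalMatrix

    def __post_init__(self) -> None:
        if self.run not in RUNS:
            raise ValueError(f"unknown run {self.run!r}")


@dataclass(frozen=True)
class ClusterLabel:
    cluster_id: int
    label: str
    peak_offset: int  # columns from the anchored junction (exon side > 0 iff downstream)
    peak_height: float


@dataclass(frozen=True)
class H1Distance:
    exon_id: str
    site: str  # '3ss' or '5ss'
    distance: int


@dataclass(frozen=True)
class NucleosomeGeometry:
    """Nucleosome wrap length and edge offsets relative to exon borders."""

    wrap_bp: int = 146
    upstream_edge_offset: int = 35  # nucleosome edge upstream of the exon start
    downstream_edge_offset: int = 45  # edge downstream of the exon end

    def __post_init__(self) -> None:
        if self.wrap_bp <= self.upstream_edge_offset:
            raise ValueError("wrap_bp must exceed upstream_edge_offset")
        if self.wrap_bp <= self.downstream_edge_offset:
            raise ValueError("wrap_bp must exceed downstream_edge_offset")


def kmeans_profiles(
    matrix: SignalMatrix,
    run: str,
    k: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    n_restarts: int = 10,
) -> ClusterAssignment:
    """Lloyd k-means on raw per-base rows, best of ``n_restarts`` by objective.

    Rows that are entirely missing are excluded; partially missing cells are
    imputed with their column mean for the distance computation only.
    """
    values = matrix.values
    keep = np.isfinite(values).any(axis=1)
    if keep.sum() < k:
        raise ValueError("fewer usable rows than clusters")
    vals = values[keep].copy()
    if not np.isfinite(vals).all():
        col_mean = np.nanmean(vals, axis=0)
        nan_r, nan_c = np.nonzero(~np.isfinite(vals))
        vals[nan_r, nan_c] = col_mean[nan_c]
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=seed,
    ).fit(vals)
    row_ids = [r for r, m in zip(matrix.row_ids, keep) if m]
    return ClusterAssignment(
        run=run,
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        row_ids=row_ids,
        seed=seed,
        inertia=float(km.inertia_),
        matrix=matrix,
    )


def label_clusters(
    assignment: ClusterAssignment,
    near_window: int = 50,
    distant_min: int = 200,
) -> list[ClusterLabel]:
    """Label each centroid by its peak position relative to the junctions.

    ``low``: peak height below the global matrix mean.  Otherwise the peak
    is located relative to the anchored junction; peaks within
    ``near_window`` bp are near the anchored site, intronic peaks at least
    ``distant_min`` bp away are distant, and exonic peaks closer to the far
    exonic window edge than to the anchor are attributed to the opposite
    splice site (for short exons that edge is where the opposite junction
    lies).  Anything else goes to the nearest junction.
    """
    spec = assignment.matrix.spec
    anchor_col = spec.anchor_col
    # which window side is exonic depends on the anchored site
    exon_side_down = spec.anchor == "exon_start"
    exon_span = spec.downstream_bp if exon_side_down else spec.upstream_bp
    anchor_site = "3ss" if assignment.run == "anchored_3ss" else "5ss"
    opposite_site = "5ss" if anchor_site == "3ss" else "3ss"
    global_mean = float(np.nanmean(assignment.matrix.values))

    out = []
    for cid, centroid in enumerate(assignment.centroids):
        peak_col = int(np.argmax(centroid))
        height = float(centroid[peak_col])
        offset = peak_col - anchor_col
        exonic = offset >= 0 if exon_side_down else offset <= 0
        d_anchor = abs(offset)
        if height < global_mean:
            label = "low"
        elif exonic:
            d_far = exon_span - d_anchor
            if d_anchor <= near_window:
                label = f"near_{anchor_site}"
            elif d_far <= near_window:
                label = f"near_{opposite_site}"
            else:
                label = (
                    f"near_{anchor_site}"
                    if d_anchor <= d_far
                    else f"near_{opposite_site}"
                )
        else:  # intronic side
            if d_anchor >= distant_min:
                label = "distant"
            else:
                label = f"near_{anchor_site}"
        out.append(ClusterLabel(cid, label, offset, height))
    return out


def hypergeometric_tail(overlap: int, n_a: int, n_b: int, universe: int) -> float:
    """Upper-tail P[X >= overlap] for X ~ Hypergeometric(universe, n_a, n_b)."""
    if not (0 <= n_a <= universe and 0 <= n_b <= universe):
        raise ValueError("set sizes must lie within the universe")
    if overlap < 0 or overlap > min(n_a, n_b):
        raise ValueError("overlap inconsistent with set sizes")
    if overlap < n_a + n_b - universe:
        raise ValueError("overlap below the minimum achievable")
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def intersect_classes(
    run_a: ClusterAssignment,
    labels_a: Sequence[ClusterLabel],
    run_b: ClusterAssignment,
    labels_b: Sequence[ClusterLabel],
) -> tuple[dict[str, str], dict[str, float]]:
    """Intersect per-exon cluster labels across the two anchored runs.

    Returns (exon_id -> class, intersection -> hypergeometric p).  Classes
    are mutually exclusive and cover the shared exon universe; marked and
    distant classes require the same label in both runs.
    """
    if set(run_a.row_ids) != set(run_b.row_ids):
        raise ValueError("the two runs cover different exon universes")
    la = {cl.cluster_id: cl.label for cl in labels_a}
    lb = {cl.cluster_id: cl.label for cl in labels_b}
    label_a = {r: la[c] for r, c in zip(run_a.row_ids, run_a.labels)}
    label_b = {r: lb[c] for r, c in zip(run_b.row_ids, run_b.labels)}
    universe = run_a.row_ids
    classes: dict[str, str] = {}
    for r in universe:
        a, b = label_a[r], label_b[r]
        if a == b == "near_3ss":
            classes[r] = "marked_3ss"
        elif a == b == "near_5ss":
            classes[r] = "marked_5ss"
        elif a == b == "distant":
            classes[r] = "distant"
        else:
            classes[r] = "unmarked"
    pvals: dict[str, float] = {}
    n_u = len(universe)
    for key, lab in (
        ("marked_3ss", "near_3ss"),
        ("marked_5ss", "near_5ss"),
        ("distant", "distant"),
    ):
        set_a = {r for r in universe if label_a[r] == lab}
        set_b = {r for r in universe if label_b[r] == lab}
        overlap = len(set_a & set_b)
        if set_a or set_b:
            pvals[key] = hypergeometric_tail(overlap, len(set_a), len(set_b), n_u)
        else:
            pvals[key] = 1.0
    return classes, pvals


def h1_distance(
    row: np.ndarray, anchor_col: int, site: str
) -> H1Distance | None:
    """Distance (bp) from the anchored splice site to the row's signal maximum.

    Ties break toward the junction; an all-missing row yields None.
    """
    row = np.asarray(row, dtype=float)
    if not np.isfinite(row).any():
        return None
    peak = np.nanmax(row)
    candidates = np.flatnonzero(row == peak)
    distance = int(np.min(np.abs(candidates - anchor_col)))
    return H1Distance("", site, distance)


def exon_h1_distances(
    matrix: SignalMatrix, site: str
) -> dict[str, int]:
    """Per-exon splice-site-to-peak distances for one anchored matrix."""
    out = {}
    for rid, row in zip(matrix.row_ids, matrix.values):
        d = h1_distance(row, matrix.anchor_col, site)
        if d is not None:
            out[rid] = d.distance
    return out


def optimal_exon_length(
    geometry: NucleosomeGeometry = NucleosomeGeometry(), site: str = "5ss"
) -> int:
    """Optimal exon length (rounded to 10 bp) for the given splice site to
    land in the linker DNA at the nucleosome edge.

    With the nucleosome edge ``upstream_edge_offset`` bp before the exon
    start, an exon of wrap - offset bp puts its 5'ss right at the opposite
    edge; symmetrically for the 3'ss with the downstream offset.
    """
    if site == "5ss":
        raw = geometry.wrap_bp - geometry.upstream_edge_offset
    elif site == "3ss":
        raw = geometry.wrap_bp - geometry.downstream_edge_offset
    else:
        raise ValueError(f"site must be '3ss' or '5ss', got {site!r}")
    return int(raw / 10 + 0.5) * 10


def correlate_distance_inclusion(
    distances: Mapping[str, float], psi: Mapping[str, float]
) -> tuple[float, float]:
    """Pearson correlation between splice-site distance and inclusion level."""
    keys = sorted(set(distances) & set(psi))
    if len(keys) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.array([distances[k] for k in keys], dtype=float)
    y = np.array([psi[k] for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
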