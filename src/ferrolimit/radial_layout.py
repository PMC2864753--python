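"""Modified radial-coordinate (RadViz-style) layout of expression profiles.

Each of the pooled microarray samples (by default one per treatment x day)
receives a dimensional anchor on the unit circle.  Every gene becomes one
point placed at the convex combination of the anchors weighted by its
relative log10 abundance across samples, so genes are attracted toward the
samples in which they are most abundant; a gene expressed equally
everywhere sits at the anchor centroid.  Point size is the largest
condition-to-condition change in log10 signal (max minus min).  Cluster
labels (exponential growth, stationary phase, early iron stress, late iron
stress) are assigned by nearest anchor through a user-supplied
anchor-to-cluster sector map, with an unassigned core around the centroid.

The weighting rule — per-gene min-subtracted log signals normalized to sum
to one — is the standard radial-coordinate construction: it is baseline-free
(adding a constant to a gene's log signals changes nothing) and keeps every
point inside the anchors' convex hull.  It is isolated in
:func:`gene_position` so an alternative placement rule can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel_io import ExpressionMatrix, ValidationError

CLUSTERS = ("exponential", "stationary", "early_iron", "late_iron")
UNASSIGNED = "unassigned"

#: default anchor angles (degrees) for the six treatment x day samples:
#: iron-limited on the left, iron-replete on the right, exponential-phase
#: samples at the bottom, stationary-phase at the top.
STUDY_ANCHOR_ANGLES = {
    "replete-day17": 300.0,
    "replete-day18": 0.0,
    "replete-day28": 60.0,
    "limited-day28": 120.0,
    "limited-day18": 180.0,
    "limited-day17": 240.0,
}

#: default sector map: which expression program each anchor's neighbourhood
#: represents.
STUDY_SECTOR_MAP = {
    "replete-day17": "exponential",
    "replete-day18": "exponential",
    "limited-day17": "exponential",
    "replete-day28": "stationary",
    "limited-day18": "early_iron",
    "limited-day28": "late_iron",
}


@dataclass(frozen=True)
class DimensionalAnchor:
    """A sample's anchor position on the unit circle."""

    sample_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if abs(self.x ** 2 + self.y ** 2 - 1.0) > 1e-9:
            raise ValidationError(
                f"anchor {self.sample_id!r} must lie on the unit circle"
            )


def sample_label(treatment: str, day: int) -> str:
    short = "limited" if treatment == "iron_limited" else "replete"
    return f"{short}-day{day}"


def default_sample_grouping(matrix: ExpressionMatrix) -> dict[str, list[str]]:
    """Pool chips into treatment x day samples (e.g. ``limited-day18``)."""
    grouping: dict[str, list[str]] = {}
    for chip in matrix.chips:
        grouping.setdefault(sample_label(chip.treatment, chip.day), []).append(
            chip.chip_id
        )
    return grouping


def compute_log_signals(
    matrix: ExpressionMatrix,
    grouping: dict[str, list[str]] | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """log10 of replicate-mean fluorescence per (gene, sample).

    ``floor`` replaces the group mean before the log when the mean falls
    below it; by default the smallest positive value in the matrix, so the
    log is always finite.
    """
    if grouping is None:
        grouping = default_sample_grouping(matrix)
    values = matrix.values
    if floor is None:
        positive = values.to_numpy()[values.to_numpy() > 0]
        if positive.size == 0:
            raise ValidationError("matrix has no positive value to derive a floor")
        floor = float(positive.min())
    cols = {}
    for sample_id, chip_ids in grouping.items():
        if not chip_ids:
            raise ValidationError(f"sample {sample_id!r} has an empty chip group")
        mean = values[chip_ids].mean(axis=1)
        cols[sample_id] = np.log10(np.maximum(mean.to_numpy(), floor))
    return pd.DataFrame(cols, index=values.index)


def place_anchors(
    order: list[str], angles_deg: list[float] | dict[str, float] | None = None
) -> list[DimensionalAnchor]:
    """Anchors on the unit circle, evenly spaced starting at the top
    (90 degrees, counterclockwise) or at explicit angles."""
    if len(set(order)) != len(order):
        raise ValidationError("duplicate sample_id in anchor order")
    if len(order) < 3:
        raise ValidationError("radial layout needs at least 3 samples")
    if angles_deg is None:
        angles = [90.0 + 360.0 * k / len(order) for k in range(len(order))]
    elif isinstance(angles_deg, dict):
        angles = [float(angles_deg[s]) for s in order]
    else:
        if len(angles_deg) != len(order):
            raise ValidationError("angles and sample order differ in length")
        angles = [float(a) for a in angles_deg]
    out = []
    for sample_id, ang in zip(order, angles):
        rad = np.deg2rad(ang % 360.0)
        out.append(DimensionalAnchor(sample_id, float(np.cos(rad)), float(np.sin(rad))))
    return out


def study_default_anchors(sample_ids=None) -> list[DimensionalAnchor]:
    """The study layout: limited left, replete right, exponential bottom,
    stationary top."""
    if sample_ids is None:
        sample_ids = list(STUDY_ANCHOR_ANGLES)
    return place_anchors(list(sample_ids), {s: STUDY_ANCHOR_ANGLES[s] for s in sample_ids})


def _anchor_arrays(anchors: list[DimensionalAnchor]) -> tuple[list[str], np.ndarray]:
    ids = [a.sample_id for a in anchors]
    xy = np.array([[a.x, a.y] for a in anchors], dtype=float)
    return ids, xy


def gene_position(signals: pd.DataFrame, anchors: list[DimensionalAnchor]) -> pd.DataFrame:
    """Convex-weight barycenter of the anchors per gene.

    Weight of sample i for gene g is S[i,g] minus the gene's minimum over
    samples, normalized to sum to one (uniform if the gene is flat); the
    position is the weighted sum of anchor coordinates.
    """
    ids, xy = _anchor_arrays(anchors)
    missing = set(ids) ^ set(signals.columns)
    if missing:
        raise ValidationError(f"anchors and signals disagree on samples: {sorted(missing)}")
    s = signals[ids].to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("log signals must be finite")
    w = s - s.min(axis=1, keepdims=True)
    totals = w.sum(axis=1, keepdims=True)
    flat = totals[:, 0] == 0
    with np.errstate(invalid="ignore"):
        w = np.where(flat[:, None], 1.0 / len(ids), w / totals)
    pos = w @ xy
    return pd.DataFrame(pos, index=signals.index, columns=["x", "y"])


def gene_size(signals: pd.DataFrame) -> pd.Series:
    """Largest observed change in log10 signal: max minus min per gene."""
    if signals.shape[1] < 2:
        raise ValidationError("gene_size needs at least 2 samples")
    s = signals.to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise ValidationError("log signals must be finite")
    return pd.Series(s.max(axis=1) - s.min(axis=1), index=signals.index, name="s")


def assign_clusters(
    points: pd.DataFrame,
    anchors: list[DimensionalAnchor],
    sector_map: dict[str, str],
    min_radius: float = 0.1,
) -> pd.Series:
    """Nearest-anchor cluster labels with an unassigned central core.

    ``min_radius`` is a fraction of the circumradius (largest anchor
    distance from the anchor centroid); genes closer to the centroid than
    that are uninformative and stay unassigned.  A gene equidistant from
    nearest anchors that map to different clusters is also unassigned;
    equidistant anchors sharing one label yield that label.
    """
    ids, xy = _anchor_arrays(anchors)
    missing = set(ids) - set(sector_map)
    if missing:
        raise ValidationError(f"sector_map missing anchors: {sorted(missing)}")
    centroid = xy.mean(axis=0)
    circumradius = float(np.linalg.norm(xy - centroid, axis=1).max())
    p = points[["x", "y"]].to_numpy(dtype=float)
    d_centroid = np.linalg.norm(p - centroid, axis=1)
    d_anchor = np.linalg.norm(p[:, None, :] - xy[None, :, :], axis=2)
    labels = []
    tol = 1e-9
    for i in range(p.shape[0]):
        if d_centroid[i] < min_radius * circumradius:
            labels.append(UNASSIGNED)
            continue
        d0 = d_anchor[i].min()
        tied = {sector_map[ids[j]] for j in np.nonzero(d_anchor[i] <= d0 + tol)[0]}
        labels.append(tied.pop() if len(tied) == 1 else UNASSIGNED)
    return pd.Series(labels, index=points.index, name="cluster")


def layout_genes(
    matrix: ExpressionMatrix,
    anchors: list[DimensionalAnchor] | None = None,
    sector_map: dict[str, str] | None = None,
    grouping: dict[str, list[str]] | None = None,
    min_radius: float = 0.1,
    floor: float | None = None,
) -> pd.DataFrame:
    """End-to-end layout: log signals -> positions, sizes, cluster labels.

    Returns a DataFrame indexed by locus_id with columns x, y, s, cluster.
    """
    signals = compute_log_signals(matrix, grouping=grouping, floor=floor)
    if anchors is None:
        order = [s for s in STUDY_ANCHOR_ANGLES if s in signals.columns]
        if set(order) == set(signals.columns):
            anchors = study_default_anchors(order)
        else:
            anchors = place_anchors(list(signals.columns))
    if sector_map is None:
        sector_map = {
            a.sample_id: STUDY_SECTOR_MAP.get(a.sample_id, UNASSIGNED)
            for a in anchors
        }
    out = gene_position(signals, anchors)
    out["s"] = gene_size(signals)
    out["cluster"] = assign_clusters(out, anchors, sector_map, min_radius=min_radius)
    return out


def plot_layout(points: pd.DataFrame, anchors: list[DimensionalAnchor], path) -> None:
    """Scatter of the layout with anchors marked, written to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    palette = {
        "exponential": "tab:green",
        "stationary": "tab:orange",
        "early_iron": "tab:red",
        "late_iron": "tab:purple",
        UNASSIGNED: "lightgray",
    }
    for cluster, sub in points.groupby("cluster"):
        ax.scatter(
            sub["x"], sub["y"], s=10 + 60 * sub["s"], alpha=0.6,
            color=palette.get(cluster, "black"), label=str(cluster), linewidths=0,
        )
    for a in anchors:
        ax.plot(a.x, a.y, "o", mfc="none", mec="black")
        ax.annotate(a.sample_id, (a.x * 1.08, a.y * 1.08), ha="center", fontsize=8)
    circle = plt.Circle((0, 0), 1.0, fill=False, color="black", lw=0.5)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.legend(loc="upper right", fontsize=7)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
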