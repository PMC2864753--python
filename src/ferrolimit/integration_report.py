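"""Transcript-protein integration: decoupling (R^2), global proteome
suppression summaries, and the iron-limitation marker report.

Transcript and protein tables are inner-joined on locus (only genes
quantified on both platforms enter the scatter), restricted to genes with
a significant (p <= alpha) change on either platform — the same inclusion
rule as the original cross-platform comparison — and summarized by the
squared Pearson correlation of the two log10 ratio columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel_io import ValidationError

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FOLD = 1.5


@dataclass(frozen=True)
class ProteomeSummary:
    """Global proteome response in one comparison."""

    n_detected: int
    n_significantly_down: int
    mean_percent_change: float


def build_pairs(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Join per-day transcript and protein ratios into OmicsPair rows.

    ``transcripts`` needs columns locus_id, day, ratio, p_value;
    ``proteins`` needs locus_id, day, log10_ratio, combined_p.  Rows are
    kept iff min(mrna_p, protein_p) <= alpha.
    """
    t = transcripts[["locus_id", "day", "ratio", "p_value"]].copy()
    if (t["ratio"] <= 0).any():
        raise ValidationError("transcript ratios must be positive")
    t["mrna_log10_ratio"] = np.log10(t["ratio"])
    t = t.rename(columns={"p_value": "mrna_p"})
    p = proteins[["locus_id", "day", "log10_ratio", "combined_p"]].rename(
        columns={"log10_ratio": "protein_log10_ratio", "combined_p": "protein_p"})
    pairs = t.merge(p, on=["locus_id", "day"], how="inner")
    keep = np.minimum(pairs["mrna_p"], pairs["protein_p"]) <= alpha
    pairs = pairs[keep].reset_index(drop=True)
    pairs["comparison"] = "limited_vs_replete_day" + pairs["day"].astype(str)
    return pairs[["locus_id", "day", "comparison", "mrna_log10_ratio",
                  "protein_log10_ratio", "mrna_p", "protein_p"]]


def r_squared(pairs: pd.DataFrame) -> float:
    """Coefficient of determination (squared Pearson r) of protein vs
    mRNA log10 ratios."""
    if len(pairs) < 3:
        raise ValidationError("r_squared needs at least 3 pairs")
    r = stats.pearsonr(pairs["mrna_log10_ratio"], pairs["protein_log10_ratio"])[0]
    return float(r ** 2)


def proteome_summary(
    proteins: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    mean_kind: str = "arithmetic",
) -> ProteomeSummary:
    """Counts of detected and significantly less-abundant proteins plus
    the mean percent abundance change.

    ``mean_kind`` selects the fold average: ``arithmetic`` (default) or
    ``geometric`` (mean of log10 ratios, back-transformed).
    """
    folds = 10.0 ** proteins["log10_ratio"].to_numpy(dtype=float)
    down = (proteins["combined_p"].to_numpy() <= alpha) & (folds < 1.0)
    if mean_kind == "arithmetic":
        mean_fold = float(folds.mean()) if folds.size else 1.0
    elif mean_kind == "geometric":
        mean_fold = float(10.0 ** np.log10(folds).mean()) if folds.size else 1.0
    else:
        raise ValidationError(f"unknown mean_kind {mean_kind!r}")
    return ProteomeSummary(
        n_detected=int(len(proteins)),
        n_significantly_down=int(down.sum()),
        mean_percent_change=100.0 * (mean_fold - 1.0),
    )


def marker_report(
    transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    marker_locus: str,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> pd.DataFrame:
    """Per-day mRNA and protein folds for the iron-limitation marker.

    The marker is flagged ``coupled`` on a day when both its mRNA and
    protein folds are at least ``min_fold``.
    """
    t = transcripts[transcripts["locus_id"] == marker_locus]
    p = proteins[proteins["locus_id"] == marker_locus]
    if len(t) == 0:
        raise ValidationError(f"marker {marker_locus!r} absent from transcript table")
    if len(p) == 0:
        raise ValidationError(f"marker {marker_locus!r} absent from protein table")
    merged = t[["locus_id", "day", "ratio", "p_value"]].merge(
        p[["locus_id", "day", "log10_ratio", "combined_p"]],
        on=["locus_id", "day"], how="inner",
    )
    if len(merged) == 0:
        raise ValidationError(
            f"marker {marker_locus!r}: no shared day between platforms")
    out = pd.DataFrame({
        "locus_id": merged["locus_id"],
        "day": merged["day"],
        "comparison": "limited_vs_replete_day" + merged["day"].astype(str),
        "mrna_fold": merged["ratio"],
        "mrna_p": merged["p_value"],
        "protein_fold": 10.0 ** merged["log10_ratio"],
        "protein_p": merged["combined_p"],
    })
    out["coupled"] = (out["mrna_fold"] >= min_fold) & (out["protein_fold"] >= min_fold)
    return out.reset_index(drop=True)


def coupled_loci(
    pairs_source_transcripts: pd.DataFrame,
    proteins: pd.DataFrame,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Loci with both folds >= min_fold and both p <= alpha on some day."""
    t = pairs_source_transcripts[["locus_id", "day", "ratio", "p_value"]]
    p = proteins[["locus_id", "day", "log10_ratio", "combined_p"]]
    merged = t.merge(p, on=["locus_id", "day"], how="inner")
    hit = (
        (merged["ratio"] >= min_fold)
        & (10.0 ** merged["log10_ratio"] >= min_fold)
        & (merged["p_value"] <= alpha)
        & (merged["combined_p"] <= alpha)
    )
    return sorted(merged.loc[hit, "locus_id"].unique())


def plot_pairs(pairs: pd.DataFrame, path) -> None:
    """Protein vs mRNA log10 ratio scatter with per-comparison R^2."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for i, (label, sub) in enumerate(pairs.groupby("comparison")):
        note = ""
        if len(sub) >= 3:
            note = f" (R$^2$={r_squared(sub):.2f})"
        ax.scatter(sub["mrna_log10_ratio"], sub["protein_log10_ratio"],
                   s=12, alpha=0.6, label=f"{label}{note}")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("mRNA log10 ratio (limited / replete)")
    ax.set_ylabel("protein log10 ratio (limited / replete)")
    ax.legend(fontsize=7)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
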