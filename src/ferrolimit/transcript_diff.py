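"""Differential transcript calling for the iron-limitation microarray design.

Chips are first brought onto a common scale (median scaling: each chip is
rescaled so its median gene fluorescence equals the global median of
per-chip medians; the construction is idempotent and preserves within-chip
ordering).  For each gene and day the iron-limited / iron-replete ratio of
replicate-mean fluorescence is computed together with a two-tailed
pooled-variance (Student) t-test over the three biological replicates per
arm, and genes at least 50% more abundant under iron limitation
(ratio >= 1.5, boundary inclusive) are flagged.

Raw p-values are reported without multiple-testing correction, mirroring
the original reporting convention for these tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import pooled_t_pvalue
from .datamodel_io import ExpressionMatrix, ValidationError

DEFAULT_MIN_RATIO = 1.5


def normalize_chips(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-scale every chip to the global median of per-chip medians.

    Each chip column is multiplied by a single positive constant, so
    within-chip ordering is preserved; applying the operation twice gives
    the same result as applying it once.
    """
    if len(matrix.chip_ids) < 2:
        raise ValidationError("normalization needs at least 2 chips")
    values = matrix.values
    medians = values.median(axis=0)
    if (medians <= 0).any():
        bad = medians.index[medians <= 0][0]
        raise ValidationError(f"chip {bad!r} has non-positive median fluorescence")
    target = float(np.median(medians.to_numpy()))
    scaled = values * (target / medians)
    return matrix.with_values(scaled)


def _group_values(matrix: ExpressionMatrix, day: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    limited = matrix.select_chips(treatment="iron_limited", day=day)
    replete = matrix.select_chips(treatment="iron_replete", day=day)
    if not limited or not replete:
        raise ValidationError(f"no chips for both treatments on day {day}")
    return matrix.values[limited], matrix.values[replete]


def transcript_ratio(matrix: ExpressionMatrix, day: int, gene: str) -> float:
    """Replicate-mean fluorescence ratio (iron-limited / iron-replete)."""
    lim, rep = _group_values(matrix, day)
    lim_mean = float(lim.loc[gene].mean())
    rep_mean = float(rep.loc[gene].mean())
    if rep_mean == 0:
        raise ValidationError(
            f"gene {gene!r} day {day}: iron-replete mean fluorescence is zero"
        )
    return lim_mean / rep_mean


def transcript_ttest(matrix: ExpressionMatrix, day: int, gene: str) -> float:
    """Two-tailed pooled-variance t-test over biological replicates."""
    lim, rep = _group_values(matrix, day)
    a = lim.loc[gene].to_numpy(dtype=float)
    b = rep.loc[gene].to_numpy(dtype=float)
    p = pooled_t_pvalue(
        a.size, a.mean(), a.var(ddof=1), b.size, b.mean(), b.var(ddof=1)
    )
    return float(p)


def differential_transcripts(
    matrix: ExpressionMatrix,
    days=None,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> pd.DataFrame:
    """Per-gene, per-day ratio and p-value table (vectorized over genes).

    Columns: locus_id, day, ratio, p_value, passes_filter.
    """
    if min_ratio <= 0:
        raise ValidationError("min_ratio must be positive")
    if days is None:
        days = matrix.days
    frames = []
    for day in days:
        lim, rep = _group_values(matrix, day)
        a = lim.to_numpy(dtype=float)
        b = rep.to_numpy(dtype=float)
        lim_mean = a.mean(axis=1)
        rep_mean = b.mean(axis=1)
        if (rep_mean == 0).any():
            bad = matrix.values.index[rep_mean == 0][0]
            raise ValidationError(
                f"gene {bad!r} day {day}: iron-replete mean fluorescence is zero"
            )
        p = pooled_t_pvalue(
            a.shape[1], lim_mean, a.var(axis=1, ddof=1),
            b.shape[1], rep_mean, b.var(axis=1, ddof=1),
        )
        frames.append(pd.DataFrame({
            "locus_id": matrix.values.index,
            "day": day,
            "ratio": lim_mean / rep_mean,
            "p_value": p,
        }))
    table = pd.concat(frames, ignore_index=True)
    table["passes_filter"] = table["ratio"] >= min_ratio
    return table


def filter_upregulated(
    table: pd.DataFrame, min_ratio: float = DEFAULT_MIN_RATIO
) -> pd.DataFrame:
    """Rows with ratio >= min_ratio (inclusive boundary), sorted by locus_id."""
    if min_ratio <= 0:
        raise ValidationError("min_ratio must be positive")
    if len(table) == 0:
        raise ValidationError("differential table is empty")
    kept = table[table["ratio"] >= min_ratio]
    return kept.sort_values("locus_id", kind="stable").reset_index(drop=True)
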