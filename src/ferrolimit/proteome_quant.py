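"""AMT-tag label-free protein quantitation.

The procedure, in fixed order:

1. :func:`match_features` — assign LC-MS features to library peptides
   inside a +/-6 ppm mass window and +/-0.001 NET window.
2. :func:`replicate_presence_filter` — keep a (peptide, sample) only when
   observed in at least 2 of the 3 technical replicates.
3. :func:`ma_normalize` — minus-vs-average regression normalization of
   each technical replicate against a within-sample reference replicate:
   m = log10(A_i) - log10(A_ref), a = (log10(A_i) + log10(A_ref)) / 2;
   least squares of m on a gives m*(a), and the corrected log abundance
   is x' = log10(A_i) - m*(a).
4. :func:`variability_filter` — drop a (peptide, sample) when the
   standard deviation of the normalized linear abundances exceeds their
   mean across technical replicates.
5. :func:`fscore_filter` — per protein, drop the lowest floor(k/3)
   peptides by maximum PeptideProphet F-score.
6. :func:`peptide_ratio_and_p` — per-peptide log10 ratio of replicate-mean
   abundances between two samples, with a one-tailed Student t-test on the
   x' values in the direction of the protein-level mean (peptides moving
   against their protein's direction get p = 1).
7. :func:`protein_rollup` — proteins with >= 3 passing peptides: mean
   peptide log10 ratio, and Fisher's method (chi2 = -2 sum ln p, 2k df)
   for a combined p-value.

Every filter only removes records; only step 3 alters abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import fisher_combine, pooled_t_pvalue
from .datamodel_io import ValidationError, features_frame, tags_frame

logger = logging.getLogger(__name__)

DEFAULT_PPM_TOL = 6.0
DEFAULT_NET_TOL = 0.001
DEFAULT_MIN_PEPTIDES = 3
DEFAULT_P_FLOOR = 1e-300


@dataclass(frozen=True)
class NormalizationFit:
    """Linear fit of m on a for one technical replicate vs its reference."""

    sample_id: str
    technical_replicate: int
    slope: float
    intercept: float
    n_shared: int

    def m_star(self, a) -> np.ndarray:
        return self.slope * np.asarray(a, dtype=float) + self.intercept


# ---------------------------------------------------------------------------
# 1. matching
# ---------------------------------------------------------------------------

def match_features(
    features,
    tags,
    ppm_tol: float = DEFAULT_PPM_TOL,
    net_tol: float = DEFAULT_NET_TOL,
) -> pd.DataFrame:
    """Match features to AMT tags within the mass/NET windows.

    A feature matches tag t iff |mass - t.mono_mass| <= ppm_tol * 1e-6 *
    t.mono_mass and |net - t.net| <= net_tol (both boundaries inclusive).
    Among several candidates the smallest combined tolerance-normalized
    distance wins; ties fall back to the closest mass, then the
    lexicographically smallest peptide_id.  If two features claim the same
    (peptide, sample, replicate), the closer one is kept.

    Returns a DataFrame with columns peptide_id, locus_id, f_score,
    sample_id, technical_replicate, abundance, mass, net, match_distance.
    """
    tags = tags_frame(tags)
    feats = features_frame(features)
    if len(tags) == 0:
        raise ValidationError("tag library is empty")
    order = np.argsort(tags["mono_mass"].to_numpy(), kind="stable")
    t_mass = tags["mono_mass"].to_numpy(dtype=float)[order]
    t_net = tags["net"].to_numpy(dtype=float)[order]
    t_pep = tags["peptide_id"].to_numpy(dtype=object)[order]
    t_locus = tags["locus_id"].to_numpy(dtype=object)[order]
    t_fscore = tags["f_score"].to_numpy(dtype=float)[order]

    f_mass = feats["mass"].to_numpy(dtype=float)
    f_net = feats["net"].to_numpy(dtype=float)
    eps = ppm_tol * 1e-6
    lo = np.searchsorted(t_mass, f_mass / (1.0 + eps), side="left")
    hi = np.searchsorted(t_mass, f_mass / (1.0 - eps), side="right")

    rows = []
    n_unmatched = 0
    for i in range(len(feats)):
        best = None  # (distance, dmass, peptide_id, tag index)
        for j in range(lo[i], hi[i]):
            dmass = abs(f_mass[i] - t_mass[j])
            if dmass > eps * t_mass[j]:
                continue
            dnet = abs(f_net[i] - t_net[j])
            if dnet > net_tol:
                continue
            dist = math.hypot(dmass / (eps * t_mass[j]), dnet / net_tol)
            key = (dist, dmass, t_pep[j])
            if best is None or key < best[0]:
                best = (key, j)
        if best is None:
            n_unmatched += 1
            continue
        _, j = best
        rows.append((
            t_pep[j], t_locus[j], t_fscore[j],
            feats["sample_id"].iat[i], int(feats["technical_replicate"].iat[i]),
            float(feats["abundance"].iat[i]), f_mass[i], f_net[i], best[0][0],
        ))
    if n_unmatched:
        logger.info("match_features: %d of %d features unmatched",
                    n_unmatched, len(feats))
    matched = pd.DataFrame(rows, columns=[
        "peptide_id", "locus_id", "f_score", "sample_id",
        "technical_replicate", "abundance", "mass", "net", "match_distance",
    ])
    # at most one observation per (peptide, sample, replicate): keep closest
    matched = (
        matched.sort_values("match_distance", kind="stable")
        .drop_duplicates(["peptide_id", "sample_id", "technical_replicate"])
        .sort_index()
        .reset_index(drop=True)
    )
    return matched


# ---------------------------------------------------------------------------
# 2. replicate presence
# ---------------------------------------------------------------------------

def replicate_presence_filter(matched: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Keep (peptide, sample) groups observed in >= min_replicates
    technical replicates; remove the others entirely."""
    if len(matched) == 0:
        return matched.copy()
    counts = matched.groupby(["peptide_id", "sample_id"])["technical_replicate"].transform("nunique")
    return matched[counts >= min_replicates].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 3. minus-vs-average normalization
# ---------------------------------------------------------------------------

def ma_normalize(
    matched: pd.DataFrame, reference_replicate: int = 1
) -> tuple[pd.DataFrame, list[NormalizationFit]]:
    """Fill ``x_prime`` (normalized log10 abundance) per observation.

    Within each sample, every non-reference technical replicate is
    regressed against the reference over their shared peptides in
    (m, a) space and corrected by the fitted m*(a); the reference
    replicate's x' is its raw log10 abundance.  Peptides without a
    reference observation cannot be placed in (m, a) space and keep
    their raw log10 abundance.
    """
    matched = matched.copy()
    matched["x_prime"] = np.log10(matched["abundance"].to_numpy(dtype=float))
    fits: list[NormalizationFit] = []
    for sample_id, sub in matched.groupby("sample_id"):
        ref = sub[sub["technical_replicate"] == reference_replicate]
        if len(ref) == 0:
            raise ValidationError(
                f"sample {sample_id!r}: reference replicate "
                f"{reference_replicate} has no observations"
            )
        ref_log = ref.set_index("peptide_id")["x_prime"]
        for rep, rep_sub in sub.groupby("technical_replicate"):
            if rep == reference_replicate:
                continue
            rep_log = rep_sub.set_index("peptide_id")["x_prime"]
            shared = rep_log.index.intersection(ref_log.index)
            a = ((rep_log[shared] + ref_log[shared]) / 2.0).to_numpy()
            m = (rep_log[shared] - ref_log[shared]).to_numpy()
            if len(shared) < 2 or np.unique(a).size < 2:
                raise ValidationError(
                    f"sample {sample_id!r} replicate {rep}: fewer than 2 "
                    "distinct shared peptides with the reference replicate"
                )
            slope, intercept = np.polyfit(a, m, 1)
            fit = NormalizationFit(sample_id, int(rep), float(slope),
                                   float(intercept), int(len(shared)))
            fits.append(fit)
            # correct only observations pairable with the reference
            idx = rep_sub.index[rep_sub["peptide_id"].isin(shared)]
            pairable = matched.loc[idx]
            a_obs = (
                pairable["x_prime"].to_numpy()
                + ref_log[pairable["peptide_id"]].to_numpy()
            ) / 2.0
            matched.loc[idx, "x_prime"] = (
                pairable["x_prime"].to_numpy() - fit.m_star(a_obs)
            )
    return matched, fits


# ---------------------------------------------------------------------------
# 4. variability filter
# ---------------------------------------------------------------------------

def variability_filter(matched: pd.DataFrame) -> pd.DataFrame:
    """Drop (peptide, sample) groups whose normalized linear abundances
    (10**x') have sample standard deviation exceeding their mean."""
    if "x_prime" not in matched.columns:
        raise ValidationError("run ma_normalize before variability_filter")
    if len(matched) == 0:
        return matched.copy()
    linear = 10.0 ** matched["x_prime"]
    grp = linear.groupby([matched["peptide_id"], matched["sample_id"]])
    sd = grp.transform("std").fillna(0.0)  # single observation -> sd 0
    mean = grp.transform("mean")
    return matched[sd <= mean].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 5. F-score filter
# ---------------------------------------------------------------------------

def fscore_filter(matched: pd.DataFrame) -> pd.DataFrame:
    """Per protein, drop the lowest floor(k/3) of its k peptides by
    maximum PeptideProphet F-score (proteins with k <= 2 are untouched).

    Ties at the cut are broken deterministically: among equal F-scores the
    lexicographically larger peptide_id is dropped first.
    """
    if len(matched) == 0:
        return matched.copy()
    per_pep = (
        matched.groupby(["locus_id", "peptide_id"])["f_score"].max().reset_index()
    )
    dropped: set[str] = set()
    for _, sub in per_pep.groupby("locus_id"):
        k = len(sub)
        n_drop = k // 3
        if k <= 2 or n_drop == 0:
            continue
        ranked = sub.sort_values(
            ["f_score", "peptide_id"], ascending=[True, False], kind="stable"
        )
        dropped.update(ranked["peptide_id"].head(n_drop))
    return matched[~matched["peptide_id"].isin(dropped)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 6. peptide ratios and one-tailed p-values
# ---------------------------------------------------------------------------

def peptide_ratio_and_p(
    matched: pd.DataFrame, sample_1: str, sample_2: str
) -> pd.DataFrame:
    """Per-peptide log10 abundance ratio (sample_1 / sample_2) and
    one-tailed p-value.

    Replicate-mean normalized abundances (linear scale) are ratioed and
    log10-transformed.  The one-tailed Student t-test runs on the x'
    (log-scale) values, in the direction of the peptide's protein-level
    mean ratio (a provisional equal-weight rollup); peptides whose own
    ratio opposes that direction are assigned p = 1.  Peptides observed in
    only one of the two samples are excluded and logged.
    """
    if "x_prime" not in matched.columns:
        raise ValidationError("run ma_normalize before peptide_ratio_and_p")
    sub = matched[matched["sample_id"].isin([sample_1, sample_2])].copy()
    sub["linear"] = 10.0 ** sub["x_prime"]
    agg = sub.groupby(["peptide_id", "sample_id"]).agg(
        locus_id=("locus_id", "first"),
        n=("x_prime", "size"),
        mean_linear=("linear", "mean"),
        mean_log=("x_prime", "mean"),
        var_log=("x_prime", lambda v: v.var(ddof=1) if len(v) > 1 else 0.0),
    ).reset_index()
    empty = pd.DataFrame(columns=["peptide_id", "locus_id", "log10_ratio",
                                  "p_one_tailed"])
    present = set(agg["sample_id"])
    if not {sample_1, sample_2} <= present:
        logger.info("peptide_ratio_and_p: no observations in one of %r / %r",
                    sample_1, sample_2)
        return empty
    wide = agg.pivot(index="peptide_id", columns="sample_id",
                     values=["locus_id", "n", "mean_linear", "mean_log", "var_log"])
    have_both = wide[("n", sample_1)].notna() & wide[("n", sample_2)].notna()
    n_excluded = int((~have_both).sum())
    if n_excluded:
        logger.info(
            "peptide_ratio_and_p: %d peptides present in only one of "
            "%r / %r excluded", n_excluded, sample_1, sample_2)
    wide = wide[have_both]
    if len(wide) == 0:
        return empty

    log10_ratio = np.log10(
        wide[("mean_linear", sample_1)].to_numpy(dtype=float)
        / wide[("mean_linear", sample_2)].to_numpy(dtype=float)
    )
    locus = wide[("locus_id", sample_1)].to_numpy(dtype=object)
    out = pd.DataFrame({
        "peptide_id": wide.index,
        "locus_id": locus,
        "log10_ratio": log10_ratio,
    }).reset_index(drop=True)

    # provisional protein direction from an equal-weight rollup
    protein_mean = out.groupby("locus_id")["log10_ratio"].transform("mean")
    protein_up = protein_mean.to_numpy() >= 0

    p_greater = pooled_t_pvalue(
        wide[("n", sample_1)].to_numpy(dtype=float),
        wide[("mean_log", sample_1)].to_numpy(dtype=float),
        wide[("var_log", sample_1)].to_numpy(dtype=float),
        wide[("n", sample_2)].to_numpy(dtype=float),
        wide[("mean_log", sample_2)].to_numpy(dtype=float),
        wide[("var_log", sample_2)].to_numpy(dtype=float),
        alternative="greater",
    )
    p_less = pooled_t_pvalue(
        wide[("n", sample_1)].to_numpy(dtype=float),
        wide[("mean_log", sample_1)].to_numpy(dtype=float),
        wide[("var_log", sample_1)].to_numpy(dtype=float),
        wide[("n", sample_2)].to_numpy(dtype=float),
        wide[("mean_log", sample_2)].to_numpy(dtype=float),
        wide[("var_log", sample_2)].to_numpy(dtype=float),
        alternative="less",
    )
    p = np.where(protein_up, p_greater, p_less)
    opposes = np.sign(out["log10_ratio"].to_numpy()) == np.where(protein_up, -1.0, 1.0)
    out["p_one_tailed"] = np.where(opposes, 1.0, p)
    return out


# ---------------------------------------------------------------------------
# 7. protein rollup (Fisher's method)
# ---------------------------------------------------------------------------

def protein_rollup(
    peptide_ratios: pd.DataFrame,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    p_floor: float = DEFAULT_P_FLOOR,
) -> pd.DataFrame:
    """Roll peptide ratios up to proteins with >= min_peptides members.

    Columns: locus_id, n_peptides, log10_ratio (mean member log10 ratio),
    fold, chi_square, df, combined_p.
    """
    rows = []
    for locus, sub in peptide_ratios.groupby("locus_id"):
        k = len(sub)
        if k < min_peptides:
            continue
        chi2, df, combined = fisher_combine(sub["p_one_tailed"], p_floor=p_floor)
        log_ratio = float(sub["log10_ratio"].mean())
        rows.append((locus, k, log_ratio, 10.0 ** log_ratio, chi2, df, combined))
    return pd.DataFrame(rows, columns=[
        "locus_id", "n_peptides", "log10_ratio", "fold",
        "chi_square", "df", "combined_p",
    ])


def filter_up_proteins(proteins: pd.DataFrame, min_fold: float = 1.5) -> pd.DataFrame:
    """Proteins at least ``min_fold`` more abundant (boundary inclusive)."""
    if min_fold <= 0:
        raise ValidationError("min_fold must be positive")
    return proteins[10.0 ** proteins["log10_ratio"] >= min_fold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def quantify_comparison(
    features,
    tags,
    sample_1: str,
    sample_2: str,
    ppm_tol: float = DEFAULT_PPM_TOL,
    net_tol: float = DEFAULT_NET_TOL,
    reference_replicate: int = 1,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    matched: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain for one two-sample comparison.

    Returns (protein table, peptide ratio table).  Pass a pre-filtered
    ``matched`` table (through :func:`fscore_filter`) to reuse matching
    across comparisons.
    """
    if matched is None:
        matched = match_features(features, tags, ppm_tol=ppm_tol, net_tol=net_tol)
        matched = replicate_presence_filter(matched)
        matched, _ = ma_normalize(matched, reference_replicate=reference_replicate)
        matched = variability_filter(matched)
        matched = fscore_filter(matched)
    ratios = peptide_ratio_and_p(matched, sample_1, sample_2)
    proteins = protein_rollup(ratios, min_peptides=min_peptides)
    return proteins, ratios


def prepare_matched(
    features,
    tags,
    ppm_tol: float = DEFAULT_PPM_TOL,
    net_tol: float = DEFAULT_NET_TOL,
    reference_replicate: int = 1,
) -> pd.DataFrame:
    """Match + presence filter + normalization + variability + F-score
    filter, ready for any number of comparisons."""
    matched = match_features(features, tags, ppm_tol=ppm_tol, net_tol=net_tol)
    matched = replicate_presence_filter(matched)
    matched, _ = ma_normalize(matched, reference_replicate=reference_replicate)
    matched = variability_filter(matched)
    return fscore_filter(matched)
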