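"""AMT-tag quantitation: matching windows, filters, MA normalization,
peptide tests and the Fisher-combined protein rollup."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ferrolimit.datamodel_io import AmtTag, FeatureObservation, ValidationError
from ferrolimit.proteome_quant import (
    fscore_filter,
    ma_normalize,
    match_features,
    peptide_ratio_and_p,
    protein_rollup,
    filter_up_proteins,
    replicate_presence_filter,
    variability_filter,
)


def _tag(pid="P1", locus="L1", mass=1000.0, net=0.5, f=5.0):
    return AmtTag(pid, locus, mass, net, f)


def _feat(mass=1000.0, net=0.5, abundance=100.0, sample="s1", rep=1):
    return FeatureObservation(mass, net, abundance, sample, rep)


# -- matching ---------------------------------------------------------------

def test_mass_window_boundary_at_6ppm():
    tags = [_tag(mass=1000.0)]
    inside = match_features([_feat(mass=1000.005999)], tags)
    outside = match_features([_feat(mass=1000.006001)], tags)
    assert len(inside) == 1 and inside["peptide_id"].iloc[0] == "P1"
    assert len(outside) == 0


def test_net_window_boundary():
    tags = [_tag(net=0.5)]
    assert len(match_features([_feat(net=0.502)], tags)) == 0
    assert len(match_features([_feat(net=0.5009)], tags)) == 1


def test_exact_features_all_match():
    rng = np.random.default_rng(1)
    tags = [_tag(pid=f"P{i}", mass=float(m), net=float(n))
            for i, (m, n) in enumerate(zip(rng.uniform(800, 3000, 50),
                                           rng.uniform(0.1, 0.9, 50)))]
    feats = [_feat(mass=t.mono_mass, net=t.net) for t in tags]
    matched = match_features(feats, tags)
    assert len(matched) == 50
    assert set(matched["peptide_id"]) == {t.peptide_id for t in tags}


def test_tie_breaks_closest_mass_then_peptide_id():
    # two tags both in window; second is closer in mass
    tags = [_tag(pid="PA", mass=1000.004), _tag(pid="PB", mass=1000.001)]
    m = match_features([_feat(mass=1000.0)], tags)
    assert m["peptide_id"].iloc[0] == "PB"
    # exact tie in distance and mass -> lexicographically smallest peptide id
    tags = [_tag(pid="PZ", mass=1000.002), _tag(pid="PA", mass=1000.002)]
    m = match_features([_feat(mass=1000.0)], tags)
    assert m["peptide_id"].iloc[0] == "PA"


def test_one_record_per_peptide_run():
    tags = [_tag(mass=1000.0)]
    feats = [_feat(mass=1000.0, abundance=10.0),
             _feat(mass=1000.003, abundance=20.0)]  # same (sample, rep)
    m = match_features(feats, tags)
    assert len(m) == 1
    assert m["abundance"].iloc[0] == 10.0  # the closer feature wins


# -- presence filter --------------------------------------------------------

def test_presence_filter_examples():
    rows = pd.DataFrame({
        "peptide_id": ["P1", "P1", "P2"],
        "sample_id": ["s1"] * 3,
        "technical_replicate": [1, 3, 2],
        "abundance": [1.0, 2.0, 3.0],
    })
    out = replicate_presence_filter(rows)
    assert set(out["peptide_id"]) == {"P1"}  # P2 seen once -> dropped


def test_presence_filter_matches_brute_force():
    rng = np.random.default_rng(8)
    rows = []
    for pep in range(30):
        for sample in ("s1", "s2"):
            for rep in (1, 2, 3):
                if rng.random() < 0.6:
                    rows.append((f"P{pep}", sample, rep, 1.0))
    df = pd.DataFrame(rows, columns=["peptide_id", "sample_id",
                                     "technical_replicate", "abundance"])
    out = replicate_presence_filter(df)
    # brute force over all (peptide, sample) groups
    expected = set()
    for (pep, sample), grp in df.groupby(["peptide_id", "sample_id"]):
        if grp["technical_replicate"].nunique() >= 2:
            expected.add((pep, sample))
    assert set(map(tuple, out[["peptide_id", "sample_id"]].values)) == expected


# -- MA normalization -------------------------------------------------------

def _matched_from(abundances: dict[int, dict[str, float]], sample="s1"):
    rows = []
    for rep, peps in abundances.items():
        for pid, ab in peps.items():
            rows.append((pid, "L1", 5.0, sample, rep, ab, 1000.0, 0.5, 0.0))
    return pd.DataFrame(rows, columns=[
        "peptide_id", "locus_id", "f_score", "sample_id",
        "technical_replicate", "abundance", "mass", "net", "match_distance"])


def test_identical_replicate_gives_null_fit():
    peps = {f"P{i}": 10.0 ** (3 + 0.2 * i) for i in range(6)}
    matched, fits = ma_normalize(_matched_from({1: peps, 2: dict(peps)}))
    [fit] = fits
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(matched["x_prime"],
                               np.log10(matched["abundance"]))


def test_tenfold_replicate_reduced_to_reference():
    peps = {f"P{i}": 10.0 ** (3 + 0.2 * i) for i in range(6)}
    tenfold = {k: v * 10.0 for k, v in peps.items()}
    matched, fits = ma_normalize(_matched_from({1: peps, 2: tenfold}))
    [fit] = fits
    assert fit.slope == pytest.approx(0.0, abs=1e-9)
    assert fit.intercept == pytest.approx(1.0, rel=1e-9)
    rep2 = matched[matched["technical_replicate"] == 2].set_index("peptide_id")
    for pid, ab in peps.items():
        assert rep2.loc[pid, "x_prime"] == pytest.approx(np.log10(ab), rel=1e-9)


def test_planted_linear_bias_recovered():
    # construct replicate 2 so that m = 0.1*a + 0.05 holds exactly
    slope, intercept = 0.1, 0.05
    ref = {f"P{i}": 3.0 + 0.25 * i for i in range(8)}  # log10 values
    rep2 = {}
    for pid, x_ref in ref.items():
        m = (slope * x_ref + intercept) / (1.0 - slope / 2.0)
        rep2[pid] = 10.0 ** (x_ref + m)
    matched, fits = ma_normalize(_matched_from(
        {1: {k: 10.0 ** v for k, v in ref.items()}, 2: rep2}))
    [fit] = fits
    assert fit.slope == pytest.approx(slope, abs=1e-6)
    assert fit.intercept == pytest.approx(intercept, abs=1e-6)
    rep2_out = matched[matched["technical_replicate"] == 2].set_index("peptide_id")
    for pid, x_ref in ref.items():
        assert rep2_out.loc[pid, "x_prime"] == pytest.approx(x_ref, abs=1e-9)


def test_too_few_shared_peptides_errors():
    with pytest.raises(ValidationError, match="shared"):
        ma_normalize(_matched_from({1: {"P1": 10.0, "P2": 20.0}, 2: {"P1": 10.0}}))


# -- variability filter -----------------------------------------------------

def test_variability_filter_arithmetic():
    base = _matched_from({1: {"P1": 10.0, "P2": 1.0},
                          2: {"P1": 10.0, "P2": 1.0},
                          3: {"P1": 10.0, "P2": 100.0}})
    base["x_prime"] = np.log10(base["abundance"])
    out = variability_filter(base)
    # P1: sd 0 <= mean 10 kept; P2: sd(1,1,100)=57.16 > mean 34 dropped
    assert set(out["peptide_id"]) == {"P1"}
    sd = np.std([1.0, 1.0, 100.0], ddof=1)
    assert sd > np.mean([1.0, 1.0, 100.0])  # oracle for the dropped case


def test_variability_filter_keeps_two_equal_observations():
    base = _matched_from({1: {"P1": 7.0}, 2: {"P1": 7.0}})
    base["x_prime"] = np.log10(base["abundance"])
    assert len(variability_filter(base)) == 2


# -- F-score filter ---------------------------------------------------------

def _fscore_table(scores: dict[str, float], locus="L1"):
    rows = [(pid, locus, f, "s1", 1, 10.0, 1000.0, 0.5, 0.0)
            for pid, f in scores.items()]
    return pd.DataFrame(rows, columns=[
        "peptide_id", "locus_id", "f_score", "sample_id",
        "technical_replicate", "abundance", "mass", "net", "match_distance"])


def test_fscore_filter_drops_lowest_third():
    scores = {f"P{i}": float(i) for i in range(6)}  # P0 lowest
    out = fscore_filter(_fscore_table(scores))
    assert set(out["peptide_id"]) == {"P2", "P3", "P4", "P5"}
    scores4 = {f"P{i}": float(i) for i in range(4)}
    out4 = fscore_filter(_fscore_table(scores4))
    assert set(out4["peptide_id"]) == {"P1", "P2", "P3"}


def test_fscore_filter_small_proteins_untouched():
    out = fscore_filter(_fscore_table({"P1": 1.0, "P2": 2.0}))
    assert set(out["peptide_id"]) == {"P1", "P2"}


def test_fscore_tie_at_cut_drops_larger_peptide_id():
    scores = {"PA": 1.0, "PB": 1.0, "PC": 5.0}  # k=3, drop 1; tie PA/PB
    out = fscore_filter(_fscore_table(scores))
    assert set(out["peptide_id"]) == {"PA", "PC"}
    # brute-force oracle: stable sort ascending by (f, reversed id)
    ranked = sorted(scores, key=lambda p: (scores[p], tuple(-ord(c) for c in p)))
    assert ranked[0] == "PB"


# -- peptide ratios ---------------------------------------------------------

def _two_sample_matched(peptides: dict[str, tuple[list, list]], locus="L1"):
    rows = []
    for pid, (s1_vals, s2_vals) in peptides.items():
        for rep, v in enumerate(s1_vals, start=1):
            rows.append((pid, locus, 5.0, "s1", rep, v, 1000.0, 0.5, 0.0))
        for rep, v in enumerate(s2_vals, start=1):
            rows.append((pid, locus, 5.0, "s2", rep, v, 1000.0, 0.5, 0.0))
    df = pd.DataFrame(rows, columns=[
        "peptide_id", "locus_id", "f_score", "sample_id",
        "technical_replicate", "abundance", "mass", "net", "match_distance"])
    df["x_prime"] = np.log10(df["abundance"])
    return df


def test_peptide_log_ratio_of_tenfold_change():
    m = _two_sample_matched({"P1": ([100.0, 100.0, 100.0], [10.0, 10.0, 10.0])})
    out = peptide_ratio_and_p(m, "s1", "s2")
    assert out["log10_ratio"].iloc[0] == pytest.approx(1.0)


def test_opposite_direction_peptide_gets_p_one():
    m = _two_sample_matched({
        "P1": ([100.0, 110.0, 120.0], [10.0, 11.0, 12.0]),   # up
        "P2": ([90.0, 100.0, 105.0], [11.0, 10.0, 12.0]),    # up
        "P3": ([5.0, 6.0, 5.5], [50.0, 55.0, 60.0]),         # down, opposes
    })
    out = peptide_ratio_and_p(m, "s1", "s2").set_index("peptide_id")
    assert out.loc["P3", "p_one_tailed"] == 1.0
    assert out.loc["P1", "p_one_tailed"] < 1.0
    assert out.loc["P2", "p_one_tailed"] < 1.0


def test_concordant_peptides_have_no_forced_p_one():
    m = _two_sample_matched({
        f"P{i}": ([100.0, 105.0, 110.0], [10.0, 12.0, 11.0]) for i in range(3)
    })
    out = peptide_ratio_and_p(m, "s1", "s2")
    assert (out["p_one_tailed"] < 1.0).all()


def test_one_sided_p_matches_scipy_oracle():
    s1, s2 = [100.0, 110.0, 120.0], [10.0, 11.0, 12.0]
    m = _two_sample_matched({"P1": (s1, s2)})
    out = peptide_ratio_and_p(m, "s1", "s2")
    ref = stats.ttest_ind(np.log10(s1), np.log10(s2), equal_var=True,
                          alternative="greater").pvalue
    assert out["p_one_tailed"].iloc[0] == pytest.approx(ref, rel=1e-12)


def test_peptide_in_one_sample_excluded():
    m = _two_sample_matched({"P1": ([100.0, 100.0], [10.0, 10.0])})
    m = m[~((m["peptide_id"] == "P1") & (m["sample_id"] == "s2"))]
    out = peptide_ratio_and_p(m, "s1", "s2")
    assert len(out) == 0


# -- rollup -----------------------------------------------------------------

def _ratios(rows):
    return pd.DataFrame(rows, columns=["peptide_id", "locus_id",
                                       "log10_ratio", "p_one_tailed"])


def test_fisher_identity_single_p():
    table = _ratios([(f"P{i}", "L1", 0.5, 0.05) for i in range(1)])
    prot = protein_rollup(table, min_peptides=1)
    assert prot["chi_square"].iloc[0] == pytest.approx(-2 * math.log(0.05))
    assert prot["combined_p"].iloc[0] == pytest.approx(0.05, abs=1e-12)


def test_fisher_two_p_closed_form():
    table = _ratios([("P1", "L1", 0.5, 0.1), ("P2", "L1", 0.5, 0.1)])
    prot = protein_rollup(table, min_peptides=2)
    chi2 = -2 * (math.log(0.1) + math.log(0.1))
    closed = (1 + chi2 / 2) * math.exp(-chi2 / 2)  # chi-square sf, df=4
    assert prot["chi_square"].iloc[0] == pytest.approx(chi2)
    assert prot["df"].iloc[0] == 4
    assert prot["combined_p"].iloc[0] == pytest.approx(closed, abs=1e-12)


def test_all_p_one_gives_combined_one():
    table = _ratios([(f"P{i}", "L1", 0.0, 1.0) for i in range(4)])
    prot = protein_rollup(table)
    assert prot["chi_square"].iloc[0] == pytest.approx(0.0)
    assert prot["combined_p"].iloc[0] == pytest.approx(1.0)


def test_rollup_requires_three_peptides():
    table = _ratios([("P1", "L1", 0.5, 0.1), ("P2", "L1", 0.5, 0.1),
                     ("P3", "L2", 0.5, 0.1)])
    assert len(protein_rollup(table)) == 0


def test_identical_peptide_ratios_roll_up_exactly():
    r = np.log10(2.7)
    table = _ratios([(f"P{i}", "L1", r, 0.05) for i in range(5)])
    prot = protein_rollup(table)
    assert prot["log10_ratio"].iloc[0] == r  # exact, no averaging error
    assert prot["fold"].iloc[0] == pytest.approx(2.7)


def test_filter_up_proteins_boundary_inclusive():
    prot = pd.DataFrame({"locus_id": ["a", "b"],
                         "log10_ratio": [np.log10(1.5), np.log10(1.49)]})
    out = filter_up_proteins(prot)
    assert list(out["locus_id"]) == ["a"]
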