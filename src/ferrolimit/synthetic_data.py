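"""Synthetic transcriptome + proteome generator with known ground truth.

The generator emulates the iron-limitation study design: 18 microarray
chips (2 treatments x 3 biological replicates x days 17/18/28) carrying
four planted expression programs (exponential growth, stationary phase,
early iron stress, late iron stress), and 4 proteomics samples
(2 treatments x days 18/28) x 3 technical replicates of LC-MS features
drawn from an AMT-tag library.  Iron-limited protein abundances are
globally suppressed by ``proteome_suppression`` except for a strongly
induced iron-transporter marker protein; protein fold changes are drawn
independently of the mRNA folds (except the marker), planting the
transcript-protein decoupling the integration stage measures.

All noise is multiplicative lognormal on the log10 scale.  Identical
configs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel_io import (
    AmtTag,
    ExpressionMatrix,
    FeatureObservation,
    ChipMeta,
    ValidationError,
)
from .radial_layout import sample_label

CHIP_DAYS = (17, 18, 28)
PROTEOME_DAYS = (18, 28)
N_BIOLOGICAL_REPLICATES = 3
N_TECHNICAL_REPLICATES = 3


@dataclass(frozen=True)
class Regulon:
    """An expression program: member loci and the planted fold change per
    (treatment, day) condition (conditions not listed have fold 1)."""

    members: tuple[str, ...]
    folds: tuple[tuple[tuple[str, int], float], ...]

    def fold_for(self, locus: str, treatment: str, day: int) -> float:
        if locus not in self.members:
            return 1.0
        for (t, d), f in self.folds:
            if t == treatment and d == day:
                return f
        return 1.0


def make_regulon(members, folds: dict) -> Regulon:
    return Regulon(tuple(members), tuple(sorted(folds.items())))


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    The headline analogues mirror the study: a 16-fold induced marker
    transcript, a ~27-fold induced marker protein, and a 59% global
    proteome suppression under iron limitation.
    """

    n_genes: int = 2000
    n_proteins: int = 250
    seed: int = 0
    # transcriptome
    baseline_log10_mean: float = 2.5   # log10 fluorescence units
    baseline_log10_sd: float = 0.4
    noise_sd: float = 0.1              # multiplicative lognormal, log10 scale
    marker_mrna_fold: float = 16.0
    regulons: dict[str, Regulon] | None = None  # default_regulons() if None
    # proteome
    proteome_suppression: float = 0.59
    marker_protein_fold: float = 27.0
    protein_fold_sd: float = 0.15      # decoupling scatter, log10 units
    peptides_per_protein: int = 6
    detected_fraction: float = 0.9
    peptide_log10_mean: float = 6.0    # log10 abundance (isotopic-profile area)
    peptide_log10_sd: float = 0.5
    replicate_scale_sd: float = 0.05   # per technical replicate offset, log10
    ppm_jitter_sd: float = 1.0         # ppm
    net_jitter_sd: float = 0.0002      # NET units
    decoy_fraction: float = 0.05       # fraction of features outside all windows
    mass_range: tuple[float, float] = (800.0, 3500.0)
    net_range: tuple[float, float] = (0.02, 0.98)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 <= self.proteome_suppression < 1:
            raise ValidationError("proteome_suppression must lie in [0, 1)")
        if not 0 <= self.detected_fraction <= 1:
            raise ValidationError("detected_fraction must lie in [0, 1]")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValidationError("decoy_fraction must lie in [0, 1]")
        for name in ("baseline_log10_sd", "noise_sd", "protein_fold_sd",
                     "peptide_log10_sd", "replicate_scale_sd",
                     "ppm_jitter_sd", "net_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.peptides_per_protein < 1:
            raise ValidationError("peptides_per_protein must be >= 1")
        if not self.n_proteins <= self.n_genes:
            raise ValidationError("n_proteins cannot exceed n_genes")


@dataclass
class GroundTruth:
    """Planted truth: per-gene mRNA folds per day, per-protein abundance
    folds per day, the peptide-to-protein map, and decoy bookkeeping."""

    mrna: pd.DataFrame | None = None      # locus_id, day, fold_limited, fold_replete, ratio
    protein: pd.DataFrame | None = None   # locus_id, day, fold
    peptide_map: pd.DataFrame | None = None  # peptide_id, locus_id
    coupled_marker: str | None = None
    n_real_features: int = 0
    n_decoy_features: int = 0


def default_locus_ids(n_genes: int) -> list[str]:
    return [f"SYN_{i:04d}" for i in range(1, n_genes + 1)]


MARKER_LOCUS = "SYN_0001"


def default_regulons(loci: list[str], marker_mrna_fold: float = 16.0) -> dict[str, Regulon]:
    """The four study-design programs over the default locus list.

    Program members sit inside the first ``n_proteins`` loci so the
    proteome half of the simulation exercises mRNA/protein decoupling on
    regulated transcripts.  The marker locus leads the early-iron program.
    """
    if len(loci) < 210:
        raise ValidationError("default regulons need at least 210 loci")
    lim, rep = "iron_limited", "iron_replete"
    return {
        "exponential": make_regulon(
            loci[10:60],
            {(lim, 17): 3.0, (rep, 17): 3.0, (rep, 18): 3.0},
        ),
        "stationary": make_regulon(loci[60:110], {(rep, 28): 3.0}),
        "early_iron": make_regulon(
            [loci[0]] + loci[110:159],
            {(lim, 18): 4.0},
        ),
        "late_iron": make_regulon(loci[160:210], {(lim, 28): 4.0}),
    }


def _mrna_fold(config: SimulationConfig, regulons, locus: str, treatment: str, day: int) -> float:
    fold = 1.0
    for name, reg in regulons.items():
        f = reg.fold_for(locus, treatment, day)
        if locus == MARKER_LOCUS and name == "early_iron" and f != 1.0:
            f = config.marker_mrna_fold
        fold *= f
    return fold


def simulate_transcriptome(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """18-chip fluorescence matrix with planted programs and ground truth."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    loci = default_locus_ids(config.n_genes)
    regulons = config.regulons if config.regulons is not None else default_regulons(
        loci, config.marker_mrna_fold)
    known = set(loci)
    for name, reg in regulons.items():
        unknown = set(reg.members) - known
        if unknown:
            raise ValidationError(
                f"regulon {name!r} references unknown loci: {sorted(unknown)[:3]}"
            )

    base = rng.normal(config.baseline_log10_mean, config.baseline_log10_sd,
                      size=config.n_genes)
    chips: list[ChipMeta] = []
    columns = {}
    truth_rows = []
    fold_cache: dict[tuple[str, int], np.ndarray] = {}
    for treatment in ("iron_limited", "iron_replete"):
        for day in CHIP_DAYS:
            fold_cache[(treatment, day)] = np.array([
                _mrna_fold(config, regulons, locus, treatment, day) for locus in loci
            ])
    for day in CHIP_DAYS:
        lim = fold_cache[("iron_limited", day)]
        rep = fold_cache[("iron_replete", day)]
        for locus, fl, fr in zip(loci, lim, rep):
            truth_rows.append((locus, day, fl, fr, fl / fr))
    for treatment in ("iron_limited", "iron_replete"):
        for day in CHIP_DAYS:
            folds = fold_cache[(treatment, day)]
            for rep_i in range(1, N_BIOLOGICAL_REPLICATES + 1):
                chip_id = f"{'lim' if treatment == 'iron_limited' else 'rep'}_d{day}_r{rep_i}"
                noise = rng.normal(0.0, config.noise_sd, size=config.n_genes) \
                    if config.noise_sd > 0 else 0.0
                columns[chip_id] = 10.0 ** (base + np.log10(folds) + noise)
                chips.append(ChipMeta(chip_id, treatment, day, rep_i))
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=loci), chips)
    truth = GroundTruth(
        mrna=pd.DataFrame(truth_rows, columns=[
            "locus_id", "day", "fold_limited", "fold_replete", "ratio"]),
        coupled_marker=MARKER_LOCUS,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def proteome_sample_ids() -> list[str]:
    return [sample_label(t, d)
            for d in PROTEOME_DAYS
            for t in ("iron_limited", "iron_replete")]


def _inside_any_window(mass, net, t_mass_sorted, t_net_sorted_by_mass,
                       ppm_tol=6.0, net_tol=0.001, margin=2.0):
    """True if (mass, net) falls within ``margin`` times the matching
    windows of any tag; used to reject decoy placements."""
    eps = margin * ppm_tol * 1e-6
    lo = np.searchsorted(t_mass_sorted, mass / (1.0 + eps), side="left")
    hi = np.searchsorted(t_mass_sorted, mass / (1.0 - eps), side="right")
    for j in range(lo, hi):
        if abs(mass - t_mass_sorted[j]) <= eps * t_mass_sorted[j] and \
                abs(net - t_net_sorted_by_mass[j]) <= margin * net_tol:
            return True
    return False


def simulate_proteome(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[AmtTag], list[FeatureObservation], GroundTruth]:
    """AMT tags + LC-MS features for 4 samples x 3 technical replicates.

    Decoy features are guaranteed to fall outside twice the default
    matching windows of every tag, so they can never be matched at the
    standard +/-6 ppm / +/-0.001 NET tolerances.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2]))
    loci = default_locus_ids(config.n_genes)
    protein_loci = loci[: config.n_proteins]

    # planted per-protein folds (limited / replete), independent of mRNA
    # except the coupled marker
    truth_rows = []
    fold_by = {}
    for locus in protein_loci:
        for day in PROTEOME_DAYS:
            if locus == MARKER_LOCUS:
                fold = config.marker_protein_fold
            else:
                scatter = (rng.normal(0.0, config.protein_fold_sd)
                           if config.protein_fold_sd > 0 else 0.0)
                fold = (1.0 - config.proteome_suppression) * 10.0 ** scatter
            fold_by[(locus, day)] = fold
            truth_rows.append((locus, day, fold))

    # AMT tag library
    tags: list[AmtTag] = []
    pep_base: dict[str, float] = {}
    for locus in protein_loci:
        for j in range(1, config.peptides_per_protein + 1):
            pid = f"{locus}_p{j}"
            tags.append(AmtTag(
                peptide_id=pid,
                locus_id=locus,
                mono_mass=float(rng.uniform(*config.mass_range)),
                net=float(rng.uniform(*config.net_range)),
                f_score=float(rng.normal(7.0, 2.0)),
            ))
            pep_base[pid] = float(rng.normal(config.peptide_log10_mean,
                                             config.peptide_log10_sd))

    sample_ids = proteome_sample_ids()
    rep_offset = {
        (s, r): (float(rng.normal(0.0, config.replicate_scale_sd))
                 if config.replicate_scale_sd > 0 else 0.0)
        for s in sample_ids for r in range(1, N_TECHNICAL_REPLICATES + 1)
    }

    features: list[FeatureObservation] = []
    for tag in tags:
        base = pep_base[tag.peptide_id]
        for sample_id in sample_ids:
            limited = sample_id.startswith("limited")
            day = int(sample_id.rsplit("day", 1)[1])
            log_fold = np.log10(fold_by[(tag.locus_id, day)]) if limited else 0.0
            for rep in range(1, N_TECHNICAL_REPLICATES + 1):
                if rng.random() >= config.detected_fraction:
                    continue
                noise = (rng.normal(0.0, config.noise_sd)
                         if config.noise_sd > 0 else 0.0)
                log_ab = base + log_fold + rep_offset[(sample_id, rep)] + noise
                mass = tag.mono_mass * (1.0 + (
                    rng.normal(0.0, config.ppm_jitter_sd) * 1e-6
                    if config.ppm_jitter_sd > 0 else 0.0))
                net = min(1.0, max(0.0, tag.net + (
                    rng.normal(0.0, config.net_jitter_sd)
                    if config.net_jitter_sd > 0 else 0.0)))
                features.append(FeatureObservation(
                    mass=float(mass), net=float(net),
                    abundance=float(10.0 ** log_ab),
                    sample_id=sample_id, technical_replicate=rep,
                ))

    n_real = len(features)
    if config.decoy_fraction >= 1.0:
        n_decoy, features = n_real, []
    else:
        n_decoy = round(n_real * config.decoy_fraction / (1.0 - config.decoy_fraction))
    t_order = np.argsort([t.mono_mass for t in tags])
    t_mass = np.array([t.mono_mass for t in tags])[t_order]
    t_net = np.array([t.net for t in tags])[t_order]
    made = 0
    while made < n_decoy:
        mass = float(rng.uniform(*config.mass_range))
        net = float(rng.uniform(0.0, 1.0))
        if _inside_any_window(mass, net, t_mass, t_net):
            continue
        features.append(FeatureObservation(
            mass=mass, net=net,
            abundance=float(10.0 ** rng.normal(config.peptide_log10_mean,
                                               config.peptide_log10_sd)),
            sample_id=sample_ids[int(rng.integers(len(sample_ids)))],
            technical_replicate=int(rng.integers(1, N_TECHNICAL_REPLICATES + 1)),
        ))
        made += 1

    out = GroundTruth(
        mrna=truth.mrna,
        protein=pd.DataFrame(truth_rows, columns=["locus_id", "day", "fold"]),
        peptide_map=pd.DataFrame(
            [(t.peptide_id, t.locus_id) for t in tags],
            columns=["peptide_id", "locus_id"]),
        coupled_marker=truth.coupled_marker or MARKER_LOCUS,
        n_real_features=n_real if config.decoy_fraction < 1.0 else 0,
        n_decoy_features=n_decoy,
    )
    return tags, features, out


def simulate_study(config: SimulationConfig):
    """Transcriptome + proteome in one call.

    Returns (ExpressionMatrix, tags, features, GroundTruth).
    """
    matrix, truth = simulate_transcriptome(config)
    tags, features, truth = simulate_proteome(config, truth)
    return matrix, tags, features, truth
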