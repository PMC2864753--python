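"""Typed tables and tab-separated I/O shared by every pipeline stage.

Every on-disk artifact is plain TSV with a mandatory header row, decimal
points and no thousands separators.  A missing observation is encoded by
row *absence*, never by a zero: the replicate-presence filter downstream
counts rows, so a zero placeholder would corrupt it.

``locus_id`` is the join key between the transcriptome and the proteome;
``peptide_id`` joins AMT-tag library entries to matched LC-MS features.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("iron_limited", "iron_replete")


class ValidationError(ValueError):
    """A table or record violates one of the documented invariants."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated locus (e.g. ``SAR11_1238`` / *sfuC*)."""

    locus_id: str
    gene_symbol: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be a non-empty string")


@dataclass(frozen=True)
class ChipMeta:
    """Metadata for one microarray chip.

    The study design is 2 treatments x 3 biological replicates x 3 days
    (17, 18, 28) = 18 chips, but any consistent design is accepted.
    """

    chip_id: str
    treatment: str
    day: int
    biological_replicate: int

    def __post_init__(self) -> None:
        if not self.chip_id:
            raise ValidationError("chip_id must be non-empty")
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"chip {self.chip_id!r}: treatment must be one of {TREATMENTS}, "
                f"got {self.treatment!r}"
            )
        if self.biological_replicate < 1:
            raise ValidationError(
                f"chip {self.chip_id!r}: biological_replicate must be >= 1"
            )


@dataclass(frozen=True)
class AmtTag:
    """One accurate-mass-and-time tag: a peptide identified by its
    monoisotopic mass and normalized elution time (NET, in [0, 1]),
    carrying its parent locus and maximum PeptideProphet F-score."""

    peptide_id: str
    locus_id: str
    mono_mass: float
    net: float
    f_score: float

    def __post_init__(self) -> None:
        if not self.peptide_id:
            raise ValidationError("peptide_id must be non-empty")
        if not self.mono_mass > 0:
            raise ValidationError(
                f"tag {self.peptide_id!r}: mono_mass must be > 0, got {self.mono_mass}"
            )
        if not 0.0 <= self.net <= 1.0:
            raise ValidationError(
                f"tag {self.peptide_id!r}: net must lie in [0, 1], got {self.net}"
            )


@dataclass(frozen=True)
class FeatureObservation:
    """One deisotoped LC-MS feature: mass, NET and the abundance measured
    as area under the isotopic profile, in one (sample, technical
    replicate) run."""

    mass: float
    net: float
    abundance: float
    sample_id: str
    technical_replicate: int

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"feature mass must be > 0, got {self.mass}")
        if not 0.0 <= self.net <= 1.0:
            raise ValidationError(f"feature net must lie in [0, 1], got {self.net}")
        if not self.abundance > 0:
            raise ValidationError(
                f"feature abundance must be > 0, got {self.abundance}"
            )
        if self.technical_replicate < 1:
            raise ValidationError("technical_replicate must be >= 1")


class ExpressionMatrix:
    """Gene x chip fluorescence with chip metadata.

    ``values`` is a genes-by-chips DataFrame (locus_id index, chip_id
    columns); ``chips`` the matching :class:`ChipMeta` sequence in column
    order.  All fluorescence values are finite and >= 0; gene and chip
    identifiers are unique.
    """

    def __init__(self, values: pd.DataFrame, chips: Sequence[ChipMeta]):
        values = values.copy()
        chip_by_id = {c.chip_id: c for c in chips}
        if len(chip_by_id) != len(chips):
            raise ValidationError("duplicate chip_id in chip metadata")
        for col in values.columns:
            if col not in chip_by_id:
                raise ValidationError(f"chip {col!r} missing from chip metadata")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene row {dup!r}")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if arr.size and (arr < 0).any():
            raise ValidationError("negative fluorescence value encountered")
        seen = set()
        for c in chips:
            key = (c.treatment, c.day, c.biological_replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate (treatment, day, biological_replicate) = {key}"
                )
            seen.add(key)
        values = values.astype(float)
        values.index.name = "locus_id"
        self.values = values
        # keep chips in column order, restricted to present columns
        self.chips: tuple[ChipMeta, ...] = tuple(
            chip_by_id[col] for col in values.columns
        )

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def chip_ids(self) -> list[str]:
        return list(self.values.columns)

    def chip_meta(self, chip_id: str) -> ChipMeta:
        for c in self.chips:
            if c.chip_id == chip_id:
                return c
        raise KeyError(chip_id)

    def select_chips(self, treatment: str | None = None, day: int | None = None) -> list[str]:
        """Chip ids matching the given treatment and/or day, in column order."""
        out = []
        for c in self.chips:
            if treatment is not None and c.treatment != treatment:
                continue
            if day is not None and c.day != day:
                continue
            out.append(c.chip_id)
        return out

    @property
    def days(self) -> list[int]:
        return sorted({c.day for c in self.chips})

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.chips)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.values.shape[0]} genes x "
            f"{self.values.shape[1]} chips)"
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SEP = "\t"


def read_chip_table(path: str | Path) -> list[ChipMeta]:
    df = pd.read_csv(path, sep=_SEP, dtype={"chip_id": str, "treatment": str})
    required = {"chip_id", "treatment", "day", "biological_replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"chip table {path}: missing columns {sorted(missing)}")
    return [
        ChipMeta(
            chip_id=row.chip_id,
            treatment=row.treatment,
            day=int(row.day),
            biological_replicate=int(row.biological_replicate),
        )
        for row in df.itertuples()
    ]


def read_expression_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read ``expression.tsv`` (locus_id + one column per chip) plus
    ``chips.tsv`` metadata, preserving row and column order."""
    df = pd.read_csv(path, sep=_SEP, float_precision="round_trip")
    if df.columns[0] != "locus_id":
        raise ValidationError(
            f"expression table {path}: first column must be 'locus_id', "
            f"got {df.columns[0]!r}"
        )
    df = df.set_index("locus_id")
    chips = read_chip_table(metadata_path)
    return ExpressionMatrix(df, chips)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    out = matrix.values.copy()
    out.index.name = "locus_id"
    out.to_csv(path, sep=_SEP)
    meta = pd.DataFrame([dataclasses.asdict(c) for c in matrix.chips])
    meta.to_csv(metadata_path, sep=_SEP, index=False)


def read_tag_library(path: str | Path) -> list[AmtTag]:
    df = pd.read_csv(path, sep=_SEP, float_precision="round_trip",
                     dtype={"peptide_id": str, "locus_id": str})
    required = {"peptide_id", "locus_id", "mono_mass", "net", "f_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"tag library {path}: missing columns {sorted(missing)}")
    return [
        AmtTag(
            peptide_id=row.peptide_id,
            locus_id=row.locus_id,
            mono_mass=float(row.mono_mass),
            net=float(row.net),
            f_score=float(row.f_score),
        )
        for row in df.itertuples()
    ]


def read_features(path: str | Path) -> list[FeatureObservation]:
    df = pd.read_csv(path, sep=_SEP, float_precision="round_trip",
                     dtype={"sample_id": str})
    required = {"mass", "net", "abundance", "sample_id", "technical_replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"feature table {path}: missing columns {sorted(missing)}")
    return [
        FeatureObservation(
            mass=float(row.mass),
            net=float(row.net),
            abundance=float(row.abundance),
            sample_id=row.sample_id,
            technical_replicate=int(row.technical_replicate),
        )
        for row in df.itertuples()
    ]


def tags_frame(tags: Iterable[AmtTag] | pd.DataFrame) -> pd.DataFrame:
    """AMT tags as a DataFrame (idempotent on DataFrame input)."""
    if isinstance(tags, pd.DataFrame):
        return tags
    return pd.DataFrame([dataclasses.asdict(t) for t in tags], columns=[
        "peptide_id", "locus_id", "mono_mass", "net", "f_score"])


def features_frame(features: Iterable[FeatureObservation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame([dataclasses.asdict(f) for f in features], columns=[
        "mass", "net", "abundance", "sample_id", "technical_replicate"])


def write_table(table, path: str | Path) -> None:
    """Write any typed table (DataFrame or iterable of dataclass records)
    as TSV with a header."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame([dataclasses.asdict(rec) for rec in table])
    table.to_csv(path, sep=_SEP, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP, float_precision="round_trip")
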