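"""Domain types, tabular readers/writers, configuration and logging.

All tables are tab-separated UTF-8 with a mandatory header row; the first
column is always the row identifier.  Orthogroup gene-count tables follow the
OrthoFinder ``Orthogroups.GeneCount.tsv`` dialect (first column ``Orthogroup``,
optional trailing ``Total`` column, one integer column per species).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("salinomics")


class Habitat(str, Enum):
    """Habitat class of a species in the comparative panel."""

    FRESHWATER = "freshwater"
    SALTWATER = "saltwater"
    OUTGROUP = "outgroup"


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesMetadata:
    """Species identifiers with their habitat assignments.

    ``table`` is indexed by unique ``species_id`` and has columns
    ``habitat`` (one of :class:`Habitat`) and optional ``display_name``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species_id: {dups}")
        bad = [h for h in self.table["habitat"] if h not in set(Habitat)]
        if bad:
            allowed = ", ".join(h.value for h in Habitat)
            raise ValidationError(f"unknown habitat {bad!r}; allowed: {allowed}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.table.index)

    def habitat_of(self, species_id: str) -> Habitat:
        try:
            return Habitat(self.table.loc[species_id, "habitat"])
        except KeyError:
            raise ValidationError(f"unknown species id: {species_id!r}") from None

    def species_in(self, habitat: Habitat) -> list[str]:
        mask = self.table["habitat"] == habitat
        return list(self.table.index[mask])


@dataclass(frozen=True)
class OrthogroupCounts:
    """Integer gene-copy counts per orthogroup (rows) and species (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate family ids in count table")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate species ids in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("orthogroup counts must be integers")
        if (arr < 0).any():
            raise ValidationError("orthogroup counts must be nonnegative")

    @property
    def family_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Binary species x family matrix; 1 marks at least one member gene."""

    values: pd.DataFrame  # species rows, family columns

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("presence-absence values must be 0 or 1")

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Nonnegative abundance matrix (genes x samples), FPKM-like units."""

    values: pd.DataFrame
    species_tag: str

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


TRAIT_COLUMNS = ("severity", "duration", "damage", "mem25_specific")


@dataclass(frozen=True)
class SampleTraits:
    """Per-sample traits: stress severity (salinity, g/L), stress duration
    (hours), damage state (1 when the alga is outside its preferred
    salinity), and the focal-species-specific indicator."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"traits table missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in traits table")
        for col in ("damage", "mem25_specific"):
            if not self.table[col].isin((0, 1)).all():
                raise ValidationError(f"trait {col!r} must be binary 0/1")
        if (self.table["severity"] < 0).any():
            raise ValidationError("severity must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class GeneOrthogroupMap:
    """gene -> orthogroup membership, one orthogroup per gene."""

    table: pd.DataFrame  # columns gene_id, species_id, orthogroup_id

    def __post_init__(self) -> None:
        needed = {"gene_id", "species_id", "orthogroup_id"}
        missing = needed - set(self.table.columns)
        if missing:
            raise ValidationError(f"gene map missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValidationError(
                f"gene mapped to more than one orthogroup: {dups.tolist()[:5]}"
            )

    def for_species(self, species_tag: str) -> pd.DataFrame:
        return self.table[self.table["species_id"] == species_tag]


@dataclass(frozen=True)
class MetaboliteMatrix:
    """Positive metabolite abundances (metabolites x samples) with a
    condition label per sample (e.g. control vs salt stress)."""

    values: pd.DataFrame
    conditions: pd.Series  # indexed by sample_id

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise ValidationError("metabolite abundances must be positive")
        if set(self.values.columns) != set(self.conditions.index):
            raise ValidationError("condition labels do not match sample ids")

    def samples_in(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    Defaults mirror the published analysis: 60% presence cutoff, 5-fold CV,
    feature batches of 50, soft-threshold grid around beta=7 with scale-free
    fit R^2 > 0.9, module-trait significance at |r| >= 0.75 and p <= 0.005,
    transcript-metabolite edges at PCC > 0.90 and p < 0.001, and metabolite
    differential abundance at |log2FC| >= 1 and p <= 0.05.
    """

    cutoff: float = 0.6
    cv_folds: int = 5
    batch_size: int = 50
    soft_power_grid: list[int] = field(default_factory=lambda: list(range(1, 13)))
    scale_free_r2_min: float = 0.9
    module_min_size: int = 30
    module_cut_height: float = 0.99
    module_trait_r_min: float = 0.75
    module_trait_p_max: float = 0.005
    pcc_min: float = 0.90
    pccp_max: float = 0.001
    da_log2fc_min: float = 1.0
    da_p_max: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.cutoff <= 1:
            raise ValidationError("cutoff must lie in (0.5, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        for name in ("module_trait_r_min", "pcc_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("module_trait_p_max", "pccp_max", "da_p_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Read a ``key: value`` config file; keyword overrides win."""
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key: value'")
            key, _, val = line.partition(":")
            values[key.strip()] = val.strip()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        parsed: dict = {}
        for key, val in values.items():
            if key not in fields:
                raise ValidationError(f"unknown config key: {key!r}")
            if key == "soft_power_grid":
                parsed[key] = [int(x) for x in val.replace(",", " ").split()]
            elif fields[key].type in ("int", int):
                parsed[key] = int(val)
            else:
                parsed[key] = float(val)
        parsed.update(overrides)
        cfg = cls(**parsed)
        logger.info("resolved config: %s", dataclasses.asdict(cfg))
        return cfg


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_orthogroup_counts(path: str | Path) -> OrthogroupCounts:
    """Parse an ``Orthogroups.GeneCount.tsv``-style table.

    A trailing ``Total`` column, if present, is dropped (and logged).
    Non-integer cells raise a parse error naming the offending cell.
    """
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    if len(df.columns) and df.columns[-1] == "Total":
        logger.info("dropping trailing 'Total' column from %s", path)
        df = df.iloc[:, :-1]
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            out[col] = df[col].astype(np.int64)
        except (TypeError, ValueError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           | (pd.to_numeric(df[col], errors="coerce") % 1 != 0)]
            row = bad[0] if len(bad) else "?"
            raise ValidationError(
                f"non-integer count at (row {row!r}, col {col!r}) in {path}"
            ) from None
        if (pd.to_numeric(df[col]) % 1 != 0).any():
            bad = df.index[pd.to_numeric(df[col]) % 1 != 0][0]
            raise ValidationError(
                f"non-integer count at (row {bad!r}, col {col!r}) in {path}"
            )
    return OrthogroupCounts(out)


def write_orthogroup_counts(oc: OrthogroupCounts, path: str | Path) -> None:
    df = oc.counts.copy()
    df.index.name = "Orthogroup"
    df.to_csv(path, sep="\t")


def to_presence_absence(counts: OrthogroupCounts) -> PresenceAbsenceMatrix:
    """Binarize copy counts: 1 iff at least one copy; species x families."""
    binary = (counts.counts.to_numpy() > 0).astype(np.int8)
    return PresenceAbsenceMatrix(
        pd.DataFrame(binary.T, index=counts.species_ids, columns=counts.family_ids)
    )


def read_species_metadata(path: str | Path) -> SpeciesMetadata:
    df = _read_tsv(path)
    if "species_id" not in df.columns or "habitat" not in df.columns:
        raise ValidationError(f"{path}: metadata needs species_id and habitat columns")
    df = df.set_index("species_id")
    allowed = {h.value for h in Habitat}
    bad = sorted(set(df["habitat"]) - allowed)
    if bad:
        raise ValidationError(
            f"unknown habitat value(s) {bad}; allowed: {sorted(allowed)}"
        )
    df["habitat"] = df["habitat"].map(Habitat)
    return SpeciesMetadata(df)


def write_species_metadata(meta: SpeciesMetadata, path: str | Path) -> None:
    df = meta.table.copy()
    df["habitat"] = [h.value for h in df["habitat"]]
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def read_expression(path: str | Path, species_tag: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.astype(float), species_tag=species_tag)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_traits(path: str | Path) -> SampleTraits:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("damage", "mem25_specific"):
        if col in df.columns and not df[col].isin((0, 1)).all():
            raise ValidationError(f"trait {col!r} must be binary 0/1 in {path}")
    return SampleTraits(df.astype(float))


def write_traits(traits: SampleTraits, path: str | Path) -> None:
    df = traits.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_map(path: str | Path) -> GeneOrthogroupMap:
    return GeneOrthogroupMap(_read_tsv(path))


def write_gene_map(gmap: GeneOrthogroupMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_metabolites(path: str | Path) -> MetaboliteMatrix:
    """Read a metabolite table; the reserved row id ``_condition`` carries
    the per-sample condition labels, all other rows are abundances."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "_condition" not in df.index:
        raise ValidationError(f"{path}: missing '_condition' row with sample labels")
    conditions = df.loc["_condition"].astype(str)
    values = df.drop(index="_condition").astype(float)
    return MetaboliteMatrix(values, conditions)


def write_metabolites(mm: MetaboliteMatrix, path: str | Path) -> None:
    cond = mm.conditions.reindex(mm.values.columns).astype(str).to_frame("_condition").T
    df = pd.concat([cond, mm.values])
    df.index.name = "metabolite_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_presence_absence(pam: PresenceAbsenceMatrix, path: str | Path) -> None:
    df = pam.values.copy()
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def setup_logging(level: int = logging.INFO) -> None:
    """Structured stderr logging; idempotent."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
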