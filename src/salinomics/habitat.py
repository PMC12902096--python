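"""Cutoff-based habitat-featured gene families, association statistics,
species membership profiling, and PCA ordination.

A family is *saltwater-featured* at cutoff ``c`` when it is present in more
than a fraction ``c`` of saltwater species AND absent in more than ``c`` of
freshwater species (strict inequalities), and freshwater-featured by the
mirrored rule.  Outgroup species never enter the fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    Habitat,
    PresenceAbsenceMatrix,
    SpeciesMetadata,
    ValidationError,
)


@dataclass(frozen=True)
class FamilyFractions:
    family_id: str
    frac_salt: float
    frac_fresh: float


@dataclass(frozen=True)
class FeaturedFamilySet:
    cutoff: float
    salt_featured: frozenset[str]
    fresh_featured: frozenset[str]

    def __post_init__(self) -> None:
        if self.salt_featured & self.fresh_featured:
            raise ValidationError("featured sets must be disjoint")


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    v_ci95: tuple[float, float]
    table: np.ndarray  # 2x2 integer counts


@dataclass(frozen=True)
class OrdinationResult:
    scores: pd.DataFrame  # species x component
    explained_fraction: np.ndarray


def _habitat_split(
    pam: PresenceAbsenceMatrix, meta: SpeciesMetadata
) -> tuple[list[str], list[str]]:
    in_matrix = set(pam.species_ids)
    salt = [s for s in meta.species_in(Habitat.SALTWATER) if s in in_matrix]
    fresh = [s for s in meta.species_in(Habitat.FRESHWATER) if s in in_matrix]
    if not salt or not fresh:
        raise ValidationError(
            "need at least one saltwater and one freshwater species in the matrix"
        )
    return salt, fresh


def habitat_fractions(
    pam: PresenceAbsenceMatrix, meta: SpeciesMetadata
) -> list[FamilyFractions]:
    """Per-family presence fractions within each habitat (outgroups excluded)."""
    salt, fresh = _habitat_split(pam, meta)
    fs = pam.values.loc[salt].mean(axis=0)
    ff = pam.values.loc[fresh].mean(axis=0)
    return [
        FamilyFractions(fam, float(fs[fam]), float(ff[fam]))
        for fam in pam.family_ids
    ]


def classify_featured(
    fracs: list[FamilyFractions], cutoff: float
) -> FeaturedFamilySet:
    """Apply the presence/absence cutoff rule with strict inequalities."""
    if not 0.5 < cutoff <= 1:
        raise ValidationError("cutoff must lie in (0.5, 1]")
    salt, fresh = set(), set()
    for f in fracs:
        if f.frac_salt > cutoff and (1.0 - f.frac_fresh) > cutoff:
            salt.add(f.family_id)
        elif f.frac_fresh > cutoff and (1.0 - f.frac_salt) > cutoff:
            fresh.add(f.family_id)
    return FeaturedFamilySet(cutoff, frozenset(salt), frozenset(fresh))


def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float, float]:
    """Pearson chi-square (df=1), its p-value, and Cramer's V for a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("expected a 2x2 table")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    expected = np.outer(row, col) / n
    if (expected == 0).any():
        raise ValidationError(
            "a zero expected cell count: use an exact test (not implemented here)"
        )
    diff = np.abs(t - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    chi2 = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    v = float(np.sqrt(chi2 / n))  # min(r-1, c-1) = 1
    return chi2, p, v


def _featured_table(
    pam: PresenceAbsenceMatrix,
    salt_sp: list[str],
    fresh_sp: list[str],
    families: list[str],
) -> np.ndarray:
    """2x2 habitat x presence counts pooled over the featured families."""
    sub = pam.values.loc[salt_sp + fresh_sp, families].to_numpy()
    n_salt = len(salt_sp)
    present_salt = int(sub[:n_salt].sum())
    present_fresh = int(sub[n_salt:].sum())
    total_salt = n_salt * len(families)
    total_fresh = len(fresh_sp) * len(families)
    return np.array(
        [
            [present_salt, total_salt - present_salt],
            [present_fresh, total_fresh - present_fresh],
        ]
    )


def association_test(
    pam: PresenceAbsenceMatrix,
    meta: SpeciesMetadata,
    featured: FeaturedFamilySet,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    yates: bool = False,
    table: np.ndarray | None = None,
) -> AssociationResult:
    """Habitat x presence association over the featured families.

    The default 2x2 table pools presence calls over all featured families:
    rows are saltwater/freshwater species, columns present/absent.  Callers
    may supply their own ``table`` instead.  The 95% CI for Cramer's V is a
    seeded percentile bootstrap resampling species within habitat.
    """
    families = sorted(featured.salt_featured | featured.fresh_featured)
    if not families:
        raise ValidationError("no featured families to test")
    salt_sp, fresh_sp = _habitat_split(pam, meta)

    if table is None:
        table = _featured_table(pam, salt_sp, fresh_sp, families)
    chi2, p, v = chi2_2x2(table, yates=yates)

    rng = np.random.default_rng(seed)
    vs = []
    for _ in range(bootstrap_reps):
        bs = [salt_sp[i] for i in rng.integers(0, len(salt_sp), len(salt_sp))]
        bf = [fresh_sp[i] for i in rng.integers(0, len(fresh_sp), len(fresh_sp))]
        bt = _featured_table(pam, bs, bf, families)
        try:
            vs.append(chi2_2x2(bt, yates=yates)[2])
        except ValidationError:  # degenerate resample
            continue
    if vs:
        lo, hi = np.percentile(vs, [2.5, 97.5])
        ci = (float(max(lo, 0.0)), float(min(hi, 1.0)))
    else:
        ci = (0.0, 1.0)
    return AssociationResult(chi2, 1, p, v, ci, np.asarray(table))


def pca_species(
    pam_featured: PresenceAbsenceMatrix, n_components: int = 3
) -> OrdinationResult:
    """Mean-centered PCA of species over (featured) family columns via SVD.

    No scaling beyond column mean-centering is applied, so the ordination
    makes no distributional assumption about the binary data.
    """
    x = pam_featured.values.to_numpy(float)
    if x.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 species")
    if n_components > min(x.shape):
        raise ValidationError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    explained = var[:n_components] / total if total > 0 else np.zeros(n_components)
    scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=pam_featured.species_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return OrdinationResult(scores, explained)


def membership_profile(
    pam: PresenceAbsenceMatrix,
    featured: FeaturedFamilySet,
    species_id: str,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """How many featured families a species carries.

    Returns ``((salt_housed, n_salt_featured), (fresh_housed, n_fresh_featured))``.
    """
    if species_id not in set(pam.species_ids):
        raise ValidationError(f"unknown species id: {species_id!r}")
    row = pam.values.loc[species_id]
    in_matrix = set(pam.family_ids)
    salt = sorted(featured.salt_featured & in_matrix)
    fresh = sorted(featured.fresh_featured & in_matrix)
    return (
        (int(row[salt].sum()), len(featured.salt_featured)),
        (int(row[fresh].sum()), len(featured.fresh_featured)),
    )
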