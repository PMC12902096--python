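"""Transcript-metabolite correlation network, metabolite differential
abundance, rule-based salt-sensitive candidate triage, and association
summary-statistic helpers.

The transcript-metabolite network correlates per-entity log2 fold-change
profiles across conditions and keeps edges with ``PCC > 0.90`` and
``p < 0.001`` (strict, one-sided in sign: strong negative correlations are
excluded by design).  Metabolite differential abundance uses the inclusive
rule ``|log2FC| >= 1`` and ``p <= 0.05`` with a Welch t-test on log2
abundances.  Triage combines expression contrasts, module annotations and
copy-number comparisons into three conjunctive candidate rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    MetaboliteMatrix,
    OrthogroupCounts,
    ValidationError,
    logger,
)
from .network import pearson_with_p


@dataclass(frozen=True)
class FoldChangeProfile:
    entity_id: str
    kind: str  # "orthogroup" | "metabolite"
    log2fc: np.ndarray  # over a shared condition axis


@dataclass(frozen=True)
class CorrelationEdge:
    orthogroup_id: str
    metabolite_id: str
    pcc: float
    p: float


@dataclass(frozen=True)
class DAResult:
    metabolite_id: str
    log2fc: float
    p: float
    significant: bool


@dataclass(frozen=True)
class TriageCandidate:
    orthogroup_id: str
    strategy: int
    evidence: dict


@dataclass(frozen=True)
class AssociationSummary:
    beta: float
    se: float
    df: int
    t: float
    p: float
    ci95: tuple[float, float]


# ---------------------------------------------------------------------------
# Metabolite differential abundance
# ---------------------------------------------------------------------------


def metabolite_da(
    mm: MetaboliteMatrix,
    group_a: str,
    group_b: str,
    log2fc_min: float = 1.0,
    p_max: float = 0.05,
) -> list[DAResult]:
    """Two-group differential abundance on log2 metabolite levels.

    ``log2fc = log2(mean_b / mean_a)`` on the raw scale; the p-value is a
    two-sided Welch t-test on log2 abundances.  Significance uses the
    inclusive bounds ``|log2fc| >= log2fc_min`` and ``p <= p_max``.
    """
    sa = mm.samples_in(group_a)
    sb = mm.samples_in(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError("need >= 2 replicates per condition")
    a = mm.values[sa].to_numpy(float)
    b = mm.values[sb].to_numpy(float)
    if (a <= 0).any() or (b <= 0).any():
        raise ValidationError("nonpositive abundance: log fold change undefined")
    lfc = np.log2(b.mean(axis=1) / a.mean(axis=1))
    tt = stats.ttest_ind(np.log2(b), np.log2(a), axis=1, equal_var=False)
    out = []
    for i, met in enumerate(mm.values.index):
        p = float(tt.pvalue[i])
        if not np.isfinite(p):  # zero variance in both groups
            p = 1.0 if lfc[i] == 0 else 0.0
        sig = bool(abs(lfc[i]) >= log2fc_min and p <= p_max)
        out.append(DAResult(met, float(lfc[i]), p, sig))
    return out


# ---------------------------------------------------------------------------
# Transcript-metabolite correlation network
# ---------------------------------------------------------------------------


def transcript_metabolite_network(
    gene_profiles: list[FoldChangeProfile],
    metab_profiles: list[FoldChangeProfile],
    pcc_min: float = 0.90,
    pccp_max: float = 0.001,
) -> list[CorrelationEdge]:
    """All-pairs Pearson correlation of log2FC profiles, filtered by cutoff.

    Edges require ``pcc > pcc_min`` and ``p < pccp_max`` (both strict); the
    list is sorted by descending correlation.  Constant profiles are skipped
    with a warning.
    """
    if not gene_profiles or not metab_profiles:
        return []
    n_cond = len(gene_profiles[0].log2fc)
    if n_cond < 3:
        raise ValidationError("need >= 3 shared conditions")
    for prof in list(gene_profiles) + list(metab_profiles):
        if len(prof.log2fc) != n_cond:
            raise ValidationError(
                f"profile {prof.entity_id!r} does not share the condition axis"
            )
    edges = []
    for g in gene_profiles:
        gx = np.asarray(g.log2fc, float)
        if gx.std() == 0:
            logger.warning("skipping constant profile %s", g.entity_id)
            continue
        for m in metab_profiles:
            mx = np.asarray(m.log2fc, float)
            if mx.std() == 0:
                continue
            r, p = pearson_with_p(gx, mx)
            if r > pcc_min and p < pccp_max:
                edges.append(CorrelationEdge(g.entity_id, m.entity_id, r, p))
    edges.sort(key=lambda e: (-e.pcc, e.orthogroup_id, e.metabolite_id))
    return edges


# ---------------------------------------------------------------------------
# Candidate triage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModuleAnnotation:
    """Per-module habitat association and focal-species specificity."""

    module: str
    freshwater_associated: bool
    saltwater_associated: bool
    focal_specific: bool


def triage_candidates(
    cross_species_expr: pd.DataFrame,
    module_of: pd.Series,
    annotations: dict[str, ModuleAnnotation],
    counts: OrthogroupCounts,
    focal_species: str,
    freshwater_species: list[str],
    expansion_comparator: str = "majority",
) -> list[TriageCandidate]:
    """Apply the three salt-sensitive candidate selection rules.

    ``cross_species_expr`` must carry per-orthogroup mean expression columns
    ``focal_mean``, ``fresh_mean`` (cross-species contrast) and
    ``focal_high``, ``focal_low`` (salinity contrast within the focal
    species).  The rules are conjunctions:

    1. freshwater expression > focal expression, in a freshwater-associated
       module that is not focal-specific;
    2. focal expression lower under high than low salinity, in a
       saltwater-associated, focal-specific module;
    3. copy number expanded in freshwater species relative to the focal
       species (majority or mean comparator), in a freshwater-associated
       module that is not focal-specific.
    """
    if expansion_comparator not in ("majority", "mean"):
        raise ValidationError("expansion_comparator must be 'majority' or 'mean'")
    needed = {"focal_mean", "fresh_mean", "focal_high", "focal_low"}
    missing = needed - set(cross_species_expr.columns)
    if missing:
        raise ValidationError(f"expression table missing columns: {sorted(missing)}")

    cand: list[TriageCandidate] = []
    cmat = counts.counts
    for og in cross_species_expr.index:
        module = module_of.get(og)
        if module is None or module == "grey":
            continue
        if module not in annotations:
            raise ValidationError(f"module {module!r} has no annotation")
        ann = annotations[module]
        row = cross_species_expr.loc[og]

        if (
            row["fresh_mean"] > row["focal_mean"]
            and ann.freshwater_associated
            and not ann.focal_specific
        ):
            cand.append(
                TriageCandidate(
                    og, 1,
                    dict(module=module, fresh_mean=float(row["fresh_mean"]),
                         focal_mean=float(row["focal_mean"])),
                )
            )

        if (
            row["focal_high"] < row["focal_low"]
            and ann.saltwater_associated
            and ann.focal_specific
        ):
            cand.append(
                TriageCandidate(
                    og, 2,
                    dict(module=module, focal_high=float(row["focal_high"]),
                         focal_low=float(row["focal_low"])),
                )
            )

        if og in cmat.index and focal_species in cmat.columns:
            focal_copies = int(cmat.loc[og, focal_species])
            fresh_copies = cmat.loc[og, freshwater_species].astype(int)
            if expansion_comparator == "majority":
                expanded = (fresh_copies > focal_copies).mean() > 0.5
            else:
                expanded = fresh_copies.mean() > focal_copies
            if expanded and ann.freshwater_associated and not ann.focal_specific:
                cand.append(
                    TriageCandidate(
                        og, 3,
                        dict(module=module, focal_copies=focal_copies,
                             fresh_copies=fresh_copies.to_dict()),
                    )
                )
    return cand


# ---------------------------------------------------------------------------
# Association summary statistics and multiple testing
# ---------------------------------------------------------------------------


def wald_stats(beta: float, se: float, df: int) -> AssociationSummary:
    """Wald t, two-sided p and 95% CI from an effect estimate and its SE."""
    if se <= 0:
        raise ValidationError("standard error must be positive")
    if df < 1:
        raise ValidationError("df must be >= 1")
    t = beta / se
    p = float(2 * stats.t.sf(abs(t), df=df))
    crit = float(stats.t.ppf(0.975, df=df))
    ci = (beta - crit * se, beta + crit * se)
    return AssociationSummary(beta, se, df, float(t), p, ci)


def multiple_testing(
    p: np.ndarray, method: str = "bh", m_override: int | None = None
) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = m_override if m_override is not None else len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty_like(p)
        adj[order] = np.minimum(ranked, 1.0)
        return adj
    raise ValidationError("method must be 'bonferroni' or 'bh'")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m
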