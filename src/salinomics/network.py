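"""Cross-species metagene aggregation and weighted co-expression modules.

Each orthogroup shared by all contributing species becomes a *metagene*
whose per-sample expression is the sum of its member genes, letting the two
species be compared on one axis despite different gene copy numbers.  A
weighted network is built from ``|Pearson correlation|^beta`` adjacencies
with the soft-threshold power ``beta`` chosen by scale-free topology fit;
modules are cut from average-linkage clustering of topological-overlap
dissimilarity, summarized by eigengenes, and correlated with sample traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .core_io import (
    ExpressionMatrix,
    GeneOrthogroupMap,
    SampleTraits,
    ValidationError,
    logger,
)

GREY = "grey"


@dataclass(frozen=True)
class MetageneMatrix:
    """Orthogroup x sample expression with per-species member-gene counts."""

    values: pd.DataFrame  # orthogroups x samples
    provenance: pd.DataFrame  # orthogroups x species, member gene counts

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CoexpressionNetwork:
    power: int
    adjacency: np.ndarray
    tom: np.ndarray
    scale_free_r2: float


@dataclass
class ModuleSet:
    labels: pd.Series  # orthogroup -> module id ("grey" = unassigned)
    eigengenes: pd.DataFrame  # module x sample
    trait_correlations: pd.DataFrame | None = None  # module, trait, r, p, significant

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_metagenes(
    exprs: list[ExpressionMatrix], gmap: GeneOrthogroupMap
) -> MetageneMatrix:
    """Sum member genes per orthogroup; keep orthogroups shared by all species."""
    if not exprs:
        raise ValidationError("no expression matrices given")
    all_samples: list[str] = []
    per_species: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.Series] = {}
    for expr in exprs:
        overlap = set(all_samples) & set(expr.sample_ids)
        if overlap:
            raise ValidationError(f"duplicate sample ids across species: {sorted(overlap)[:5]}")
        all_samples.extend(expr.sample_ids)
        mapping = gmap.for_species(expr.species_tag)
        mapping = mapping[mapping["gene_id"].isin(expr.values.index)]
        if mapping.empty:
            raise ValidationError(
                f"no mapped genes for species {expr.species_tag!r}"
            )
        grouped = (
            expr.values.loc[mapping["gene_id"]]
            .groupby(mapping.set_index("gene_id")["orthogroup_id"])
            .sum()
        )
        per_species[expr.species_tag] = grouped
        counts[expr.species_tag] = mapping.groupby("orthogroup_id").size()

    shared = None
    for sp, df in per_species.items():
        ogs = set(df.index)
        shared = ogs if shared is None else shared & ogs
    dropped = set().union(*(set(df.index) for df in per_species.values())) - shared
    if dropped:
        logger.warning(
            "dropping %d orthogroups not shared by all species", len(dropped)
        )
    shared = sorted(shared)
    if not shared:
        raise ValidationError("no orthogroups shared by all species")

    values = pd.concat([per_species[sp].loc[shared] for sp in per_species], axis=1)
    prov = pd.DataFrame(
        {sp: counts[sp].reindex(shared).fillna(0).astype(int) for sp in per_species}
    )
    return MetageneMatrix(values[all_samples], prov)


# ---------------------------------------------------------------------------
# Soft threshold and adjacency
# ---------------------------------------------------------------------------


def _correlation(values: np.ndarray) -> np.ndarray:
    return np.corrcoef(values)


def drop_constant_rows(mm: MetageneMatrix) -> MetageneMatrix:
    sd = mm.values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("removing %d constant metagene rows", int((~keep).sum()))
    return MetageneMatrix(mm.values.loc[keep], mm.provenance.loc[keep.index[keep]])


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(frequency) on log10(mean connectivity) by bins."""
    k = k[k > 0]
    if len(k) < 2 or np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2)


def adjacency_matrix(
    values: np.ndarray, power: int, signed: bool = False
) -> np.ndarray:
    cor = _correlation(values)
    if signed:
        adj = ((1 + cor) / 2) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def pick_soft_threshold(
    mm: MetageneMatrix,
    power_grid: list[int] | None = None,
    r2_min: float = 0.9,
    signed: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest power whose scale-free fit index exceeds ``r2_min``.

    If no power passes, the power maximizing the index is returned and the
    fit table's ``passed`` column flags the shortfall.
    """
    if power_grid is None:
        power_grid = list(range(1, 13))
    if mm.values.shape[1] < 4:
        raise ValidationError("need at least 4 samples for the soft-threshold fit")
    mm = drop_constant_rows(mm)
    rows = []
    for beta in power_grid:
        adj = adjacency_matrix(mm.values.to_numpy(float), beta, signed=signed)
        k = adj.sum(axis=1) - 1.0  # exclude self
        fit = scale_free_fit(k)
        rows.append(dict(power=beta, fit_index=fit, mean_k=float(k.mean()),
                         passed=bool(np.isfinite(fit) and fit > r2_min)))
    table = pd.DataFrame(rows)
    passing = table[table["passed"]]
    if len(passing):
        power = int(passing["power"].iloc[0])
    else:
        finite = table.dropna(subset=["fit_index"])
        if finite.empty:
            logger.warning("degenerate scale-free fit on all powers; using smallest")
            power = int(table["power"].iloc[0])
        else:
            power = int(finite.loc[finite["fit_index"].idxmax(), "power"])
            logger.warning(
                "no power reached fit index %.2f; using maximizer %d", r2_min, power
            )
    return power, table


# ---------------------------------------------------------------------------
# Topological overlap and modules
# ---------------------------------------------------------------------------


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValidationError("adjacency entries must lie in [0, 1]")
    n = a.shape[0]
    d = np.diag(a).copy()
    k = a.sum(axis=1) - d
    # l_ij over u != i,j: subtract the u=i and u=j terms of (A^2)_ij
    l = a @ a - d[:, None] * a - a * d[None, :]
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[denom <= 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    ids: list[str],
    min_size: int = 30,
    cut_height: float = 0.99,
) -> pd.Series:
    """Average-linkage clustering of 1-TOM with a static branch cut.

    Clusters smaller than ``min_size`` fall into the unassigned ``grey``
    label.  Modules are named M1, M2, ... by decreasing size (ties by first
    member position), so labels are deterministic.
    """
    if min_size < 2:
        raise ValidationError("min_size must be >= 2")
    dissim = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(dissim, 0.0)
    link = average(squareform(dissim, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(GREY, index=pd.Index(ids, name="orthogroup_id"), dtype=object)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_size]
    # order by size desc, then first occurrence
    first_pos = {c: int(np.argmax(raw == c)) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for mi, c in enumerate(keep, start=1):
        labels.iloc[np.nonzero(raw == c)[0]] = f"M{mi}"
    return labels


def module_eigengene(mm: MetageneMatrix, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized member rows.

    The eigengene sign is oriented so that its correlation with the module's
    mean member profile is positive.  A size-1 module's eigengene is the
    standardized row itself.
    """
    modules = [m for m in labels.unique() if m != GREY]
    if not modules:
        raise ValidationError("no non-grey modules")
    modules.sort(key=lambda m: int(m[1:]) if m[1:].isdigit() else m)
    egs = {}
    values = mm.values
    for m in modules:
        members = labels.index[labels == m]
        x = values.loc[members].to_numpy(float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        if z.shape[0] == 1:
            eig = z[0]
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(eig, mean_profile) < 0:
            eig = -eig
        egs[m] = eig
    return pd.DataFrame(egs, index=values.columns).T


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided Student-t p-value (n-2 df)."""
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def module_trait(
    eigengenes: pd.DataFrame,
    traits: SampleTraits,
    r_min: float = 0.75,
    p_max: float = 0.005,
) -> pd.DataFrame:
    """Pearson correlation of every (module eigengene, trait) pair.

    A pair is significant iff ``|r| >= r_min`` and ``p <= p_max`` (inclusive
    bounds).  Constant traits yield NaN and are never significant.
    """
    samples = list(eigengenes.columns)
    missing = set(samples) - set(traits.sample_ids)
    if missing:
        raise ValidationError(f"samples without trait rows: {sorted(missing)[:5]}")
    tt = traits.table.loc[samples]
    rows = []
    for module in eigengenes.index:
        eg = eigengenes.loc[module].to_numpy(float)
        for trait in tt.columns:
            r, p = pearson_with_p(eg, tt[trait].to_numpy(float))
            sig = bool(np.isfinite(r) and abs(r) >= r_min and p <= p_max)
            rows.append(dict(module=module, trait=trait, r=r, p=p, significant=sig))
    return pd.DataFrame(rows)


def build_network(
    mm: MetageneMatrix,
    power_grid: list[int] | None = None,
    r2_min: float = 0.9,
    signed: bool = False,
    log_transform: bool = False,
) -> CoexpressionNetwork:
    """Soft-threshold selection, adjacency and TOM in one step."""
    mm = drop_constant_rows(mm)
    if log_transform:
        mm = MetageneMatrix(np.log2(mm.values + 1), mm.provenance)
        mm = drop_constant_rows(mm)
    power, table = pick_soft_threshold(mm, power_grid, r2_min, signed=signed)
    adj = adjacency_matrix(mm.values.to_numpy(float), power, signed=signed)
    fit = float(table.loc[table["power"] == power, "fit_index"].iloc[0])
    return CoexpressionNetwork(power, adj, tom_similarity(adj), fit)
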