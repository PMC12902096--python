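"""Synthetic data generators with planted, recoverable structure.

Three generators emulate the statistical structure the downstream analyses
assume: a species x gene-family presence-absence matrix with planted
habitat-discriminating families, a two-species 24-sample expression design
with planted trait-correlated metagene modules, and a metabolite table with
planted fold changes.  Every generator is fully deterministic under its
seed; a single root seed fans out to independent substreams so that adding
one generator call never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ExpressionMatrix,
    GeneOrthogroupMap,
    Habitat,
    MetaboliteMatrix,
    OrthogroupCounts,
    SampleTraits,
    SpeciesMetadata,
    ValidationError,
)

# Substream labels for deriving independent per-generator seeds from one root.
_STREAMS = {"presence": 1, "expression": 2, "metabolites": 3}


def substream_seed(root_seed: int, stream: str) -> int:
    """Derive a stable per-generator seed below 2**31 from a root seed."""
    if stream not in _STREAMS:
        raise ValidationError(
            f"unknown stream {stream!r}; expected one of {sorted(_STREAMS)}"
        )
    ss = np.random.SeedSequence([int(root_seed), _STREAMS[stream]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PlantedTruth:
    """Ground truth of the planted structure, for recovery scoring."""

    planted_salt_families: set[str] = field(default_factory=set)
    planted_fresh_families: set[str] = field(default_factory=set)
    # module id -> (metagene id set, linked trait name)
    planted_modules: dict[str, tuple[set[str], str]] = field(default_factory=dict)
    # metabolite id -> true log2 fold change
    planted_da_metabolites: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Presence-absence matrix
# ---------------------------------------------------------------------------


def simulate_presence_absence(
    n_salt: int = 20,
    n_fresh: int = 20,
    n_families: int = 2000,
    n_planted_salt: int = 10,
    n_planted_fresh: int = 20,
    p_hi: float = 0.9,
    p_lo: float = 0.05,
    p_bg: float = 0.3,
    copy_lambda: float = 1.0,
    seed: int = 0,
) -> tuple[OrthogroupCounts, SpeciesMetadata, PlantedTruth]:
    """Simulate an orthogroup count table with habitat-discriminating families.

    A planted saltwater family is present with probability ``p_hi`` in each
    saltwater species and ``p_lo`` in each freshwater species (mirrored for
    freshwater-planted families); background families are present with
    probability ``p_bg`` everywhere.  Present entries receive a copy number
    of 1 + Poisson(``copy_lambda``) so presence always implies >= 1 copy.
    """
    for name, p in (("p_hi", p_hi), ("p_lo", p_lo), ("p_bg", p_bg)):
        if not 0 <= p <= 1:
            raise ValidationError(f"{name} must lie in [0, 1], got {p}")
    if not p_lo < p_hi:
        raise ValidationError("require p_lo < p_hi")
    if min(n_salt, n_fresh, n_families) <= 0:
        raise ValidationError("dimensions must be positive")
    if n_planted_salt + n_planted_fresh > n_families:
        raise ValidationError("planted families exceed n_families")

    rng = np.random.default_rng(seed)
    species = [f"salt{i:02d}" for i in range(n_salt)] + [
        f"fresh{i:02d}" for i in range(n_fresh)
    ]
    habitats = [Habitat.SALTWATER] * n_salt + [Habitat.FRESHWATER] * n_fresh
    families = [f"OG{i:07d}" for i in range(n_families)]

    n_sp = n_salt + n_fresh
    prob = np.full((n_families, n_sp), p_bg)
    salt_cols = np.arange(n_sp) < n_salt
    prob[:n_planted_salt, salt_cols] = p_hi
    prob[:n_planted_salt, ~salt_cols] = p_lo
    sl = slice(n_planted_salt, n_planted_salt + n_planted_fresh)
    prob[sl, ~salt_cols] = p_hi
    prob[sl, salt_cols] = p_lo

    present = rng.random((n_families, n_sp)) < prob
    copies = np.where(present, 1 + rng.poisson(copy_lambda, (n_families, n_sp)), 0)

    counts = OrthogroupCounts(
        pd.DataFrame(copies.astype(np.int64), index=families, columns=species)
    )
    meta = SpeciesMetadata(
        pd.DataFrame({"habitat": habitats}, index=pd.Index(species, name="species_id"))
    )
    truth = PlantedTruth(
        planted_salt_families=set(families[:n_planted_salt]),
        planted_fresh_families=set(families[sl]),
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted co-expression modules
# ---------------------------------------------------------------------------

#: The 24-sample design: 2 species x 2 salinities x 2 timepoints x replicates.
#: Severities are salinity levels in g/L (the euryhaline strain is stressed
#: at high salinity, the freshwater strain at moderate salinity).
_DESIGN = [
    # (species, stress, severity g/L)
    ("MEM25", 0, 70.0),
    ("MEM25", 1, 105.0),
    ("FACHB9", 0, 0.0),
    ("FACHB9", 1, 35.0),
]
_DURATIONS = (3.0, 24.0)


def _design_samples(samples_per_cell: int):
    rows = []
    for sp, stress, severity in _DESIGN:
        for dur in _DURATIONS:
            for rep in range(samples_per_cell):
                sid = f"{sp}_{'hi' if stress else 'lo'}_{int(dur)}h_r{rep + 1}"
                rows.append(
                    dict(
                        sample_id=sid,
                        species=sp,
                        severity=severity,
                        duration=dur,
                        damage=float(stress),
                        mem25_specific=float(stress and sp == "MEM25"),
                    )
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_expression(
    n_metagenes: int = 300,
    samples_per_cell: int = 3,
    module_specs: list[tuple[int, str, float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[
    list[ExpressionMatrix], GeneOrthogroupMap, SampleTraits, PlantedTruth
]:
    """Simulate two-species expression with planted trait-linked modules.

    Metagene profiles follow the factor model ``x = loading * f_trait + eps``
    with ``eps ~ N(0, noise_sd^2)`` and ``f_trait`` the standardized trait
    vector over the 24-sample design; background metagenes are pure noise.
    Besides the four sample traits, a module may be linked to the derived
    factor ``fresh_species`` (the freshwater-strain indicator), and a ``-``
    prefix on any factor name plants the anti-correlated profile.  Profiles
    are mapped to nonnegative FPKM-like abundances by an affine shift
    (correlation-based downstream stages are shift-invariant).  Each
    orthogroup's per-species genes split its metagene value with fixed
    random proportions, so summing member genes recovers it exactly; copy
    numbers per species are random in {1, 2, 3} so aggregation and
    copy-number comparisons are exercised.
    """
    if module_specs is None:
        # Default planted factors are the mutually orthogonal axes of the
        # balanced factorial design (strain, timepoint, stress indicator);
        # severity is a linear mix of strain and stress and would make the
        # planted module boundaries themselves ill-defined.
        module_specs = [
            (40, "fresh_species", 0.9),
            (40, "duration", 0.9),
            (40, "damage", 0.9),
        ]
    if not module_specs:
        raise ValidationError("module_specs must be nonempty")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if sum(size for size, _, _ in module_specs) > n_metagenes:
        raise ValidationError("module sizes exceed n_metagenes")

    rng = np.random.default_rng(seed)
    design = _design_samples(samples_per_cell)
    n_samples = len(design)

    factors = {}
    for trait in ("severity", "duration", "damage", "mem25_specific"):
        v = design[trait].to_numpy(float)
        sd = v.std()
        factors[trait] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    fresh = (design["species"] != "MEM25").to_numpy(float)
    factors["fresh_species"] = (fresh - fresh.mean()) / fresh.std()

    metagenes = [f"OG{i:05d}" for i in range(n_metagenes)]
    latent = np.empty((n_metagenes, n_samples))
    truth = PlantedTruth()
    row = 0
    for mi, (size, trait, loading) in enumerate(module_specs):
        if not 0 < loading <= 1:
            raise ValidationError("loadings must lie in (0, 1]")
        sign = -1.0 if trait.startswith("-") else 1.0
        base_trait = trait.lstrip("-")
        if base_trait not in factors:
            raise ValidationError(f"unknown trait {base_trait!r}")
        block = sign * loading * factors[base_trait][None, :] + rng.normal(
            0.0, noise_sd, (size, n_samples)
        )
        latent[row : row + size] = block
        truth.planted_modules[f"planted{mi + 1}"] = (
            set(metagenes[row : row + size]),
            trait,
        )
        row += size
    n_bg = n_metagenes - row
    # background: unit-variance noise so planted and background metagenes
    # have comparable scale
    latent[row:] = rng.normal(0.0, 1.0, (n_bg, n_samples))

    # affine map to FPKM-like abundances, clipped at zero
    abundance = np.clip(20.0 + 5.0 * latent, 0.0, None)

    # split each metagene across 1-3 gene copies per species with fixed weights
    exprs: list[ExpressionMatrix] = []
    map_rows = []
    species_tags = sorted(design["species"].unique())
    for sp in species_tags:
        cols = design.index[design["species"] == sp]
        sp_values = pd.DataFrame(
            abundance[:, design["species"].to_numpy() == sp],
            index=metagenes,
            columns=cols,
        )
        gene_rows = {}
        for gi, og in enumerate(metagenes):
            n_copies = int(rng.choice((1, 2, 3), p=(0.6, 0.3, 0.1)))
            w = rng.dirichlet(np.ones(n_copies)) if n_copies > 1 else np.array([1.0])
            for c in range(n_copies):
                gid = f"{sp}_g{gi:05d}_{c}"
                gene_rows[gid] = sp_values.loc[og].to_numpy() * w[c]
                map_rows.append(
                    dict(gene_id=gid, species_id=sp, orthogroup_id=og)
                )
        exprs.append(
            ExpressionMatrix(
                pd.DataFrame.from_dict(gene_rows, orient="index", columns=cols),
                species_tag=sp,
            )
        )

    gmap = GeneOrthogroupMap(pd.DataFrame(map_rows))
    traits = SampleTraits(
        design[["severity", "duration", "damage", "mem25_specific"]].copy()
    )
    return exprs, gmap, traits, truth


# ---------------------------------------------------------------------------
# Metabolite abundances with planted fold changes
# ---------------------------------------------------------------------------


def simulate_metabolites(
    n_metab: int = 451,
    n_da: int = 150,
    true_log2fc_range: tuple[float, float] = (1.0, 4.0),
    replicates: int = 3,
    cv_noise: float = 0.1,
    seed: int = 0,
    conditions: tuple[str, str] = ("control", "salt"),
) -> tuple[MetaboliteMatrix, PlantedTruth]:
    """Simulate a two-condition metabolite table with planted DA compounds.

    Differentially abundant metabolites get a true |log2FC| drawn uniformly
    from ``true_log2fc_range`` with random sign; replicate noise is
    lognormal with coefficient of variation ``cv_noise``.
    """
    lo, hi = true_log2fc_range
    if lo > hi:
        raise ValidationError("true_log2fc_range must be ordered (lo, hi)")
    if n_da > n_metab:
        raise ValidationError("n_da exceeds n_metab")
    if replicates < 2:
        raise ValidationError("need >= 2 replicates per condition")

    rng = np.random.default_rng(seed)
    ids = [f"met{i:04d}" for i in range(n_metab)]
    base = rng.lognormal(mean=8.0, sigma=1.0, size=n_metab)
    lfc = np.zeros(n_metab)
    lfc[:n_da] = rng.uniform(lo, hi, n_da) * rng.choice((-1.0, 1.0), n_da)

    # lognormal noise with CV = cv_noise, mean-corrected to 1
    if cv_noise > 0:
        sigma = np.sqrt(np.log1p(cv_noise**2))
        noise = lambda shape: rng.lognormal(-(sigma**2) / 2, sigma, shape)  # noqa: E731
    else:
        noise = lambda shape: np.ones(shape)  # noqa: E731

    group_a = base[:, None] * noise((n_metab, replicates))
    group_b = (base * 2.0**lfc)[:, None] * noise((n_metab, replicates))

    cols_a = [f"{conditions[0]}_r{i + 1}" for i in range(replicates)]
    cols_b = [f"{conditions[1]}_r{i + 1}" for i in range(replicates)]
    values = pd.DataFrame(
        np.hstack([group_a, group_b]), index=ids, columns=cols_a + cols_b
    )
    cond = pd.Series(
        [conditions[0]] * replicates + [conditions[1]] * replicates,
        index=cols_a + cols_b,
    )
    truth = PlantedTruth(
        planted_da_metabolites={ids[i]: float(lfc[i]) for i in range(n_da)}
    )
    return MetaboliteMatrix(values, cond), truth
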