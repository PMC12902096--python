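"""End-to-end orchestration: simulate -> featured -> mlselect -> coexpress
-> integrate, under one config and one root seed, with a machine-readable
run manifest (config echo, per-stage output digests and timings)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    AnalysisConfig,
    Habitat,
    OrthogroupCounts,
    SampleTraits,
    ValidationError,
    logger,
    read_expression,
    read_gene_map,
    read_metabolites,
    read_orthogroup_counts,
    read_species_metadata,
    read_traits,
    to_presence_absence,
    write_expression,
    write_gene_map,
    write_metabolites,
    write_orthogroup_counts,
    write_species_metadata,
    write_traits,
)
from . import habitat as hb
from . import integrate as it
from . import ml
from . import network as nw
from . import synthetic as syn

STAGES = ("simulate", "featured", "mlselect", "coexpress", "integrate")


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the root seed."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compact_registry() -> list[tuple[ml.ModelSpec | None, ml.ModelSpec]]:
    """Small default registry for end-to-end runs: importance/sparsity
    selectors paired with linear final stages (so weight categorization
    is always available), plus one classifier-only baseline."""
    selectors = [
        ml.ModelSpec("selector", "random_forest"),
        ml.ModelSpec("selector", "lasso"),
        ml.ModelSpec("selector", "elastic_net", {"alpha": 0.6}),
    ]
    classifiers = [
        ml.ModelSpec("classifier", "elastic_net", {"alpha": 0.6}),
        ml.ModelSpec("classifier", "lasso"),
        ml.ModelSpec("classifier", "svm_linear"),
    ]
    return ml.build_registry(
        selectors=selectors,
        classifiers=classifiers,
        include_classifier_only=False,
    ) + [(None, ml.ModelSpec("classifier", "elastic_net", {"alpha": 0.6}))]


def derive_module_annotations(
    eigengenes: pd.DataFrame,
    traits: SampleTraits,
    fresh_indicator: pd.Series,
    r_min: float = 0.75,
    p_max: float = 0.005,
) -> dict[str, it.ModuleAnnotation]:
    """Annotate modules by eigengene correlation with the freshwater-strain
    indicator (signed: r >= r_min freshwater-, r <= -r_min saltwater-
    associated) and with the focal-specific trait (positive r only)."""
    ann = {}
    mem = traits.table.loc[list(eigengenes.columns), "mem25_specific"].to_numpy(float)
    fresh = fresh_indicator.loc[list(eigengenes.columns)].to_numpy(float)
    for module in eigengenes.index:
        eg = eigengenes.loc[module].to_numpy(float)
        rf, pf = nw.pearson_with_p(eg, fresh)
        rm, pm = nw.pearson_with_p(eg, mem)
        ann[module] = it.ModuleAnnotation(
            module=module,
            freshwater_associated=bool(np.isfinite(rf) and rf >= r_min and pf <= p_max),
            saltwater_associated=bool(np.isfinite(rf) and rf <= -r_min and pf <= p_max),
            focal_specific=bool(np.isfinite(rm) and rm >= r_min and pm <= p_max),
        )
    return ann


#: module plan used by the pipeline's default simulation: one module tracking
#: the freshwater strain, one tracking stress duration, one tracking damage
PIPELINE_MODULE_SPECS = [
    (40, "fresh_species", 0.9),
    (40, "duration", 0.9),
    (40, "damage", 0.9),
]


def run_pipeline(
    config: AnalysisConfig,
    workdir: str | Path,
    skip: set[str] | frozenset[str] = frozenset(),
    registry: list | None = None,
    focal_species: str = "MEM25",
) -> dict:
    """Execute the synthetic end-to-end pipeline and write a manifest.

    Stages read their inputs from ``workdir`` (written by earlier stages),
    so a skipped stage simply reuses files already present.  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def record(stage: str, t0: float, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }

    for stage in STAGES:
        if stage in skip:
            manifest["stages"][stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                outputs = _stage_simulate(config, wd)
            elif stage == "featured":
                outputs = _stage_featured(config, wd)
            elif stage == "mlselect":
                outputs = _stage_mlselect(config, wd, registry)
            elif stage == "coexpress":
                outputs = _stage_coexpress(config, wd)
            else:
                outputs = _stage_integrate(config, wd, focal_species)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, wd)
            raise ValidationError(f"stage {stage!r} failed: {exc}") from exc
        record(stage, t0, outputs)
    _write_manifest(manifest, wd)
    return manifest


def _write_manifest(manifest: dict, wd: Path) -> None:
    (wd / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(config: AnalysisConfig, wd: Path) -> list[Path]:
    counts, meta, truth_pa = syn.simulate_presence_absence(
        seed=syn.substream_seed(config.seed, "presence")
    )
    exprs, gmap, traits, truth_ex = syn.simulate_expression(
        module_specs=list(PIPELINE_MODULE_SPECS),
        seed=syn.substream_seed(config.seed, "expression"),
    )
    mets, truth_met = syn.simulate_metabolites(
        seed=syn.substream_seed(config.seed, "metabolites")
    )
    outputs = []

    def out(name: str) -> Path:
        p = wd / name
        outputs.append(p)
        return p

    write_orthogroup_counts(counts, out("counts.tsv"))
    write_species_metadata(meta, out("species_metadata.tsv"))
    for expr in exprs:
        write_expression(expr, out(f"expression_{expr.species_tag}.tsv"))
    write_gene_map(gmap, out("gene_map.tsv"))
    write_traits(traits, out("sample_traits.tsv"))
    write_metabolites(mets, out("metabolites.tsv"))
    truth = {
        "planted_salt_families": sorted(truth_pa.planted_salt_families),
        "planted_fresh_families": sorted(truth_pa.planted_fresh_families),
        "planted_modules": {
            m: {"metagenes": sorted(ids), "trait": trait}
            for m, (ids, trait) in truth_ex.planted_modules.items()
        },
        "planted_da_metabolites": truth_met.planted_da_metabolites,
    }
    out("truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outputs


def _stage_featured(config: AnalysisConfig, wd: Path) -> list[Path]:
    counts = read_orthogroup_counts(wd / "counts.tsv")
    meta = read_species_metadata(wd / "species_metadata.tsv")
    pam = to_presence_absence(counts)
    fracs = hb.habitat_fractions(pam, meta)
    featured = hb.classify_featured(fracs, config.cutoff)
    assoc = hb.association_test(
        pam, meta, featured,
        bootstrap_reps=config.bootstrap_reps,
        seed=stage_seed(config.seed, "featured-bootstrap"),
    )
    feat_families = sorted(featured.salt_featured | featured.fresh_featured)
    ord_res = hb.pca_species(
        hb.PresenceAbsenceMatrix(pam.values[feat_families]),
        n_components=min(3, len(pam.species_ids), len(feat_families)),
    )

    rows = []
    for f in fracs:
        cls = (
            "saltwater" if f.family_id in featured.salt_featured
            else "freshwater" if f.family_id in featured.fresh_featured
            else "none"
        )
        rows.append(dict(family_id=f.family_id, classification=cls,
                         frac_salt=f.frac_salt, frac_fresh=f.frac_fresh))
    out1 = wd / "featured_families.tsv"
    pd.DataFrame(rows).to_csv(out1, sep="\t", index=False, float_format="%.10g")

    out2 = wd / "association.json"
    out2.write_text(json.dumps({
        "chi2": assoc.chi2, "df": assoc.df, "p_value": assoc.p_value,
        "cramers_v": assoc.cramers_v, "v_ci95": list(assoc.v_ci95),
        "table": assoc.table.tolist(),
        "n_salt_featured": len(featured.salt_featured),
        "n_fresh_featured": len(featured.fresh_featured),
        "cutoff": featured.cutoff,
    }, indent=2, sort_keys=True))

    out3 = wd / "ordination.tsv"
    scores = ord_res.scores.copy()
    scores.index.name = "species_id"
    scores.to_csv(out3, sep="\t", float_format="%.10g")
    out4 = wd / "ordination_explained.tsv"
    pd.DataFrame({
        "component": [f"PC{i+1}" for i in range(len(ord_res.explained_fraction))],
        "explained_fraction": ord_res.explained_fraction,
    }).to_csv(out4, sep="\t", index=False, float_format="%.10g")
    return [out1, out2, out3, out4]


def _stage_mlselect(
    config: AnalysisConfig, wd: Path, registry: list | None
) -> list[Path]:
    counts = read_orthogroup_counts(wd / "counts.tsv")
    meta = read_species_metadata(wd / "species_metadata.tsv")
    pam = to_presence_absence(counts)
    if registry is None:
        registry = compact_registry()
    ml_config = dataclasses.replace(config, seed=stage_seed(config.seed, "mlselect"))
    best, results = ml.run_combination_search(pam, meta, registry, ml_config)
    groups = ml.categorize_by_weight(best)

    out1 = wd / "ml_leaderboard.tsv"
    ml.leaderboard(results).to_csv(out1, sep="\t", index=False, float_format="%.10g")

    rows = []
    for fam in best.selected_families:
        w = best.weights[fam]
        grp = ("saltwater" if fam in groups.salt_group
               else "freshwater" if fam in groups.fresh_group else "none")
        rows.append(dict(family_id=fam, weight=w, group=grp))
    out2 = wd / "ml_selected_families.tsv"
    pd.DataFrame(rows).to_csv(out2, sep="\t", index=False, float_format="%.10g")

    out3 = wd / "ml_manifest.json"
    out3.write_text(json.dumps({
        "seed": ml_config.seed,
        "cv_folds": config.cv_folds,
        "batch_size": config.batch_size,
        "registry_size": len(registry),
        "best": {
            "selector": best.selector.label if best.selector else "none",
            "classifier": best.classifier.label,
            "cv_accuracy": best.cv_accuracy,
            "fold_accuracies": best.fold_accuracies.tolist(),
            "n_features": best.n_features_used,
        },
    }, indent=2, sort_keys=True))
    return [out1, out2, out3]


def _expression_inputs(wd: Path) -> list:
    exprs = []
    for p in sorted(wd.glob("expression_*.tsv")):
        tag = p.stem.replace("expression_", "")
        exprs.append(read_expression(p, species_tag=tag))
    if not exprs:
        raise ValidationError(f"no expression_*.tsv found in {wd}")
    return exprs


def _stage_coexpress(config: AnalysisConfig, wd: Path) -> list[Path]:
    exprs = _expression_inputs(wd)
    gmap = read_gene_map(wd / "gene_map.tsv")
    traits = read_traits(wd / "sample_traits.tsv")
    mm = nw.aggregate_metagenes(exprs, gmap)
    net = nw.build_network(
        mm, power_grid=config.soft_power_grid, r2_min=config.scale_free_r2_min
    )
    mm2 = nw.drop_constant_rows(mm)
    labels = nw.detect_modules(
        net.tom, mm2.orthogroup_ids,
        min_size=config.module_min_size, cut_height=config.module_cut_height,
    )
    eigen = nw.module_eigengene(mm2, labels)
    mt = nw.module_trait(
        eigen, traits,
        r_min=config.module_trait_r_min, p_max=config.module_trait_p_max,
    )

    out1 = wd / "modules.tsv"
    labels.to_frame("module").to_csv(out1, sep="\t")
    out2 = wd / "eigengenes.tsv"
    eigen.rename_axis("module").to_csv(out2, sep="\t", float_format="%.10g")
    out3 = wd / "module_trait.tsv"
    mt.to_csv(out3, sep="\t", index=False, float_format="%.10g")
    out4 = wd / "soft_threshold_fit.tsv"
    _, table = nw.pick_soft_threshold(
        mm2, config.soft_power_grid, config.scale_free_r2_min
    )
    table.to_csv(out4, sep="\t", index=False, float_format="%.10g")
    return [out1, out2, out3, out4]


def _stage_integrate(
    config: AnalysisConfig, wd: Path, focal_species: str
) -> list[Path]:
    mets = read_metabolites(wd / "metabolites.tsv")
    conditions = sorted(mets.conditions.unique())
    if len(conditions) != 2:
        raise ValidationError("integrate stage expects exactly 2 metabolite conditions")
    da = it.metabolite_da(
        mets, conditions[0], conditions[1],
        log2fc_min=config.da_log2fc_min, p_max=config.da_p_max,
    )
    out1 = wd / "metabolite_da.tsv"
    pd.DataFrame([dataclasses.asdict(d) for d in da]).to_csv(
        out1, sep="\t", index=False, float_format="%.10g"
    )

    exprs = _expression_inputs(wd)
    gmap = read_gene_map(wd / "gene_map.tsv")
    traits = read_traits(wd / "sample_traits.tsv")
    mm = nw.aggregate_metagenes(exprs, gmap)

    sample_species = {}
    for expr in exprs:
        for s in expr.sample_ids:
            sample_species[s] = expr.species_tag
    species = pd.Series(sample_species).loc[mm.sample_ids]
    tt = traits.table.loc[mm.sample_ids]

    # transcript log2FC profiles: focal-species high vs low salinity per
    # replicate at the late timepoint (matching the metabolome sampling)
    focal = species == focal_species
    late = tt["duration"] == tt["duration"].max()
    hi = list(tt.index[focal & late & (tt["damage"] == 1)])
    lo = list(tt.index[focal & late & (tt["damage"] == 0)])
    n_pairs = min(len(hi), len(lo))
    gene_profiles = []
    vals = mm.values
    for og in mm.orthogroup_ids:
        lfc = np.log2((vals.loc[og, hi[:n_pairs]].to_numpy() + 1.0)
                      / (vals.loc[og, lo[:n_pairs]].to_numpy() + 1.0))
        gene_profiles.append(it.FoldChangeProfile(og, "orthogroup", lfc))
    met_a = mets.samples_in(conditions[0])[:n_pairs]
    met_b = mets.samples_in(conditions[1])[:n_pairs]
    metab_profiles = []
    for met in mets.values.index:
        lfc = np.log2(mets.values.loc[met, met_b].to_numpy()
                      / mets.values.loc[met, met_a].to_numpy())
        metab_profiles.append(it.FoldChangeProfile(met, "metabolite", lfc))
    edges = it.transcript_metabolite_network(
        gene_profiles, metab_profiles,
        pcc_min=config.pcc_min, pccp_max=config.pccp_max,
    )
    out2 = wd / "network_edges.tsv"
    pd.DataFrame(
        [dataclasses.asdict(e) for e in edges],
        columns=["orthogroup_id", "metabolite_id", "pcc", "p"],
    ).to_csv(out2, sep="\t", index=False, float_format="%.10g")

    # triage: module annotations from the coexpress stage
    labels = pd.read_csv(wd / "modules.tsv", sep="\t", index_col=0)["module"]
    eigen = pd.read_csv(wd / "eigengenes.tsv", sep="\t", index_col=0)
    fresh_indicator = (species != focal_species).astype(float)
    ann = derive_module_annotations(
        eigen, traits, fresh_indicator,
        r_min=config.module_trait_r_min, p_max=config.module_trait_p_max,
    )
    expr_table = pd.DataFrame({
        "focal_mean": vals.loc[:, species[species == focal_species].index].mean(axis=1),
        "fresh_mean": vals.loc[:, species[species != focal_species].index].mean(axis=1),
        "focal_high": vals.loc[:, tt.index[focal & (tt["damage"] == 1)]].mean(axis=1),
        "focal_low": vals.loc[:, tt.index[focal & (tt["damage"] == 0)]].mean(axis=1),
    })
    prov_counts = OrthogroupCounts(mm.provenance.astype(np.int64))
    fresh_species = sorted(set(species[species != focal_species]))
    cands = it.triage_candidates(
        expr_table, labels, ann, prov_counts,
        focal_species=focal_species, freshwater_species=fresh_species,
    )
    out3 = wd / "triage.tsv"
    pd.DataFrame(
        [dict(orthogroup_id=c.orthogroup_id, strategy=c.strategy,
              evidence=json.dumps(c.evidence, sort_keys=True))
         for c in cands],
        columns=["orthogroup_id", "strategy", "evidence"],
    ).to_csv(out3, sep="\t", index=False)
    return [out1, out2, out3]


def render_report(wd: str | Path) -> str:
    """Plain-text summary of a finished run directory."""
    wd = Path(wd)
    lines = ["salinomics run summary", "======================"]
    assoc_p = wd / "association.json"
    if assoc_p.exists():
        a = json.loads(assoc_p.read_text())
        lines += [
            f"featured families (cutoff {a['cutoff']}): "
            f"{a['n_salt_featured']} saltwater / {a['n_fresh_featured']} freshwater",
            f"habitat association: chi2(df=1) = {a['chi2']:.1f}, "
            f"p = {a['p_value']:.3g}, Cramer's V = {a['cramers_v']:.2f} "
            f"(95% CI [{a['v_ci95'][0]:.2f}, {a['v_ci95'][1]:.2f}])",
        ]
    mlm = wd / "ml_manifest.json"
    if mlm.exists():
        m = json.loads(mlm.read_text())["best"]
        lines.append(
            f"best model combination: {m['selector']} + {m['classifier']} "
            f"(CV accuracy {m['cv_accuracy']:.3f}, {m['n_features']} families)"
        )
    mt_p = wd / "module_trait.tsv"
    if mt_p.exists():
        mt = pd.read_csv(mt_p, sep="\t")
        n_mod = mt["module"].nunique()
        sig = mt[mt["significant"]]
        lines.append(
            f"co-expression: {n_mod} modules, "
            f"{len(sig)} significant module-trait links"
        )
    da_p = wd / "metabolite_da.tsv"
    if da_p.exists():
        da = pd.read_csv(da_p, sep="\t")
        lines.append(
            f"metabolites: {int(da['significant'].sum())} of {len(da)} "
            "differentially abundant"
        )
    tri_p = wd / "triage.tsv"
    if tri_p.exists():
        tri = pd.read_csv(tri_p, sep="\t")
        per = tri.groupby("strategy").size().to_dict() if len(tri) else {}
        lines.append(
            f"triage: {tri['orthogroup_id'].nunique() if len(tri) else 0} "
            f"candidate orthogroups (per strategy: {per})"
        )
    return "\n".join(lines) + "\n"
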