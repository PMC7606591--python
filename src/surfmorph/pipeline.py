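"""End-to-end analysis orchestration.

A run is described by a flat YAML config (see :class:`RunConfig`), proceeds
through the fixed stage order — load/synthesize data, surface smoothing,
step-up age-model selection, group and age-by-group contrasts for CT/SA/CV,
RFT cluster-corrected masks at each cluster threshold, CT/SA overlap with
chi-square and simulation null, CV decomposition, global statistics — and
writes a report bundle with a manifest recording the config hash and seeds.
Everything downstream of the global seed is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import glm, overlap, rft, surface
from .errors import ConfigError

log = logging.getLogger("surfmorph")

FEATURES = ("CT", "SA", "CV")


@dataclass
class RunConfig:
    """Validated run configuration.

    Either ``synthetic`` is set (icosphere template plus generator options)
    or explicit ``mesh_paths`` / ``measure_paths`` / ``cohort_path`` point at
    files on disk.
    """

    # synthetic-generation block
    synthetic: dict | None = None
    # file inputs
    mesh_paths: dict[str, str] = dc_field(default_factory=dict)
    cohort_path: str | None = None
    measure_paths: dict = dc_field(default_factory=dict)
    # model block
    smoothing_fwhm_mm: float = 10.0
    model_selection: bool = True
    age_order: int = 2
    include_iq: bool = True
    with_interactions: bool = True
    # inference block
    forming_p: float = 0.001
    cluster_alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    # overlap block
    overlap_alpha: float = 0.05
    overlap_sims: int = 5000
    overlap_universe_vertices: int | None = None
    # run block
    seed: int = 0
    out_dir: str = "surfmorph_out"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            if not self.mesh_paths or self.cohort_path is None:
                raise ConfigError(
                    "config needs either a 'synthetic' block or "
                    "mesh_paths + cohort_path + measure_paths"
                )
            for p in [self.cohort_path, *self.mesh_paths.values()]:
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        if not all(0 < a < 1 for a in self.cluster_alphas):
            raise ConfigError("cluster_alphas must lie in (0, 1)")
        if not 0 < self.forming_p < 1:
            raise ConfigError("forming_p must lie in (0, 1)")
        if self.smoothing_fwhm_mm < 0:
            raise ConfigError("smoothing_fwhm_mm must be >= 0")

    def to_dict(self) -> dict:
        d = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            d[name] = list(v) if isinstance(v, tuple) else v
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    config: RunConfig
    meshes: dict[str, surface.Mesh]
    cohort: pd.DataFrame
    selection: dict[str, glm.SelectionReport]
    adopted_order: int
    stat_maps: dict  # (feature, hemi, contrast) -> StatMap
    cluster_tables: pd.DataFrame
    masks: dict  # (feature, hemi, alpha) -> SignedMask
    overlap_tables: dict[str, overlap.OverlapTable]
    decomposition_tables: dict[str, overlap.DecompositionTable]
    null_overlap: overlap.NullOverlapResult | None
    global_table: pd.DataFrame
    truth: dict | None = None
    provenance: dict = dc_field(default_factory=dict)


def _threshold_label(alpha: float) -> str:
    return f"p<{alpha:g}"


def _load_or_synthesize(config: RunConfig):
    """Stage 1: meshes, cohort and raw (unsmoothed) measure matrices."""
    if config.synthetic is not None:
        s = dict(config.synthetic)
        subdiv = s.pop("icosphere_subdivisions", 3)
        radius = s.pop("icosphere_radius_mm", 20.0)
        hemis = s.pop("hemispheres", ["left", "right"])
        n_case = s.pop("n_case", 62)
        n_control = s.pop("n_control", 57)
        effects_raw = s.pop("effects", {})
        overlap_frac = s.pop("overlap_fraction", None)
        noise_fwhm = s.pop("noise_fwhm_mm", 10.0)
        gen_kwargs = s
        cohort = cohort_mod.generate_cohort(n_case, n_control,
                                            seed=config.seed)
        meshes, measures, truth = {}, {}, {}
        for i, h in enumerate(hemis):
            mesh = surface.make_icosphere(subdiv, radius, hemisphere=h)
            meshes[h] = mesh
            if overlap_frac is not None:
                effects = cohort_mod.plant_overlap_scenario(
                    mesh, overlap_frac, seed=config.seed + 11 * i + 1)
            else:
                effects = [cohort_mod.EffectSpec(**e)
                           for e in effects_raw.get(h, [])]
            ct, sa, cv, tr = cohort_mod.generate_measures(
                mesh, cohort, effects, noise_fwhm_mm=noise_fwhm,
                seed=config.seed + 97 * i + 13, **gen_kwargs)
            measures[h] = {"CT": ct, "SA": sa, "CV": cv}
            truth[h] = tr
        return meshes, cohort, measures, truth

    meshes = {h: surface.read_surface(p, hemisphere=h)
              for h, p in config.mesh_paths.items()}
    cohort = cohort_mod.read_cohort(config.cohort_path)
    measures = {}
    for h, mesh in meshes.items():
        measures[h] = {}
        for feat in FEATURES:
            paths = config.measure_paths.get(h, {}).get(feat)
            if paths is None:
                raise ConfigError(f"missing measure paths for {h}/{feat}")
            fields = [surface.read_vertex_field(p, mesh.n_vertices).values
                      for p in paths]
            if len(fields) != len(cohort):
                raise ConfigError(
                    f"{h}/{feat}: {len(fields)} files for "
                    f"{len(cohort)} subjects"
                )
            measures[h][feat] = np.vstack(fields)
    return meshes, cohort, measures, None


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute all stages; deterministic given ``config.seed``."""
    logging.basicConfig(level=config.log_level)
    stage = "load"
    try:
        meshes, cohort, measures, truth = _load_or_synthesize(config)
        hemis = list(meshes)
        log.info("loaded %d hemispheres, %d subjects", len(hemis), len(cohort))

        stage = "smooth"
        if config.smoothing_fwhm_mm > 0:
            for h, mesh in meshes.items():
                smoother = surface.SurfaceSmoother(mesh,
                                                   config.smoothing_fwhm_mm)
                for feat in FEATURES:
                    measures[h][feat] = smoother.apply(measures[h][feat])

        stage = "model-selection"
        selection: dict[str, glm.SelectionReport] = {}
        adopted = config.age_order
        if config.model_selection:
            orders = []
            for h, mesh in meshes.items():
                rep = glm.stepup_select(measures[h]["CT"], cohort, mesh,
                                        cluster_alpha=0.05,
                                        forming_p=config.forming_p,
                                        include_iq=config.include_iq)
                selection[h] = rep
                orders.append(rep.adopted_order)
            adopted = max(orders)
            log.info("step-up selection adopted age order %d", adopted)

        stage = "contrasts"
        design = glm.build_design(cohort, age_order=adopted,
                                  with_interactions=config.with_interactions,
                                  include_iq=config.include_iq)
        contrasts = ["group", "age_x_group"]
        if adopted >= 2:
            contrasts.append("age2_x_group")
        stat_maps, fits, smooths = {}, {}, {}
        for h, mesh in meshes.items():
            for feat in FEATURES:
                fit = glm.fit_ols(measures[h][feat], design)
                fits[(feat, h)] = fit
                smooths[(feat, h)] = rft.estimate_smoothness(fit, mesh)
                for con in contrasts:
                    stat_maps[(feat, h, con)] = glm.contrast_t(fit, con)

        stage = "rft-masks"
        masks = {}
        cluster_rows = []
        for feat in FEATURES:
            search = sum(smooths[(feat, h)].total_resels for h in hemis)
            euler = sum(meshes[h].euler_characteristic() for h in hemis)
            for h, mesh in meshes.items():
                stat = stat_maps[(feat, h, "group")]
                for alpha in config.cluster_alphas:
                    masks[(feat, h, alpha)] = rft.significant_mask(
                        stat, mesh, smooths[(feat, h)], alpha,
                        config.forming_p, search_resels=search,
                        euler_char=euler,
                        provenance=dict(feature=feat, hemisphere=h))
                for tail in ("positive", "negative"):
                    cs = rft.extract_clusters(stat, mesh, config.forming_p,
                                              tail, smooths[(feat, h)])
                    cs = rft.cluster_pvalues(cs, smooths[(feat, h)], stat.df,
                                             stat.kind, search_resels=search,
                                             euler_char=euler)
                    frame = rft.clusters_to_frame(cs, h)
                    frame.insert(0, "feature", feat)
                    cluster_rows.append(frame)
        cluster_rows = [f for f in cluster_rows if not f.empty]
        cluster_tables = (pd.concat(cluster_rows, ignore_index=True)
                          if cluster_rows else pd.DataFrame())

        stage = "overlap"
        overlap_tables = {}
        decomp_tables = {}
        observed_pct = None
        for alpha in config.cluster_alphas:
            label = _threshold_label(alpha)
            ct_m = {h: masks[("CT", h, alpha)] for h in hemis}
            sa_m = {h: masks[("SA", h, alpha)] for h in hemis}
            cv_m = {h: masks[("CV", h, alpha)] for h in hemis}
            tab = overlap.classify_overlap(ct_m, sa_m, label)
            counts = tab.counts["combined"]
            if int(counts["total"]):
                stat, dfc, p = overlap.chi2_equal_distribution(
                    [counts[c] for c in overlap.OVERLAP_CATEGORIES])
                tab.percentages.attrs["chi2"] = (stat, dfc, p)
            overlap_tables[label] = tab
            decomp_tables[label] = overlap.decompose_cv(cv_m, ct_m, sa_m,
                                                        label)
            if alpha == config.overlap_alpha and int(counts["total"]):
                observed_pct = float(tab.percentages.loc["ct_and_sa",
                                                         "combined"])

        stage = "overlap-null"
        n_universe = config.overlap_universe_vertices or \
            sum(m.n_vertices for m in meshes.values())
        null_res = overlap.simulate_overlap_null(
            n_universe, config.overlap_alpha, config.overlap_sims,
            seed=config.seed + 7919,
            observed_overlap_pct=observed_pct)

        stage = "global-stats"
        global_table = glm.global_stats(cohort)

        bundle = ResultBundle(
            config=config, meshes=meshes, cohort=cohort,
            selection=selection, adopted_order=adopted,
            stat_maps=stat_maps, cluster_tables=cluster_tables, masks=masks,
            overlap_tables=overlap_tables,
            decomposition_tables=decomp_tables,
            null_overlap=null_res, global_table=global_table, truth=truth,
            provenance=dict(config_hash=config.digest(), seed=config.seed,
                            adopted_order=adopted),
        )
        return bundle
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def subgroup_contrast(config: RunConfig,
                      subgroup_column: str = "psychosis_prodromal",
                      ) -> ResultBundle:
    """Re-run the contrasts within the case group, with the subgroup flag
    replacing the case/control factor."""
    meshes, cohort, measures, truth = _load_or_synthesize(config)
    if subgroup_column not in cohort.columns:
        raise ConfigError(f"subgroup column {subgroup_column!r} not in cohort")
    cases = cohort[cohort["group"] == "case"].reset_index(drop=True)
    levels = [l for l in cases[subgroup_column].unique() if l != "n/a"]
    if len(levels) < 2:
        raise ConfigError(
            f"subgroup column {subgroup_column!r} needs >= 2 levels in cases"
        )
    counts = cases[subgroup_column].value_counts()
    small = counts[counts < 3]
    if not small.empty:
        raise ConfigError(
            f"subgroup level(s) with < 3 subjects: {small.index.tolist()}"
        )
    idx = cohort.index[cohort["group"] == "case"].to_numpy()
    design = glm.build_design(cases, age_order=config.age_order,
                              with_interactions=config.with_interactions,
                              include_iq=config.include_iq,
                              group_column=subgroup_column, case_level="yes")
    stat_maps, masks = {}, {}
    cluster_rows = []
    if config.smoothing_fwhm_mm > 0:
        for h, mesh in meshes.items():
            smoother = surface.SurfaceSmoother(mesh, config.smoothing_fwhm_mm)
            for feat in FEATURES:
                measures[h][feat] = smoother.apply(measures[h][feat])
    hemis = list(meshes)
    smooths = {}
    for h, mesh in meshes.items():
        for feat in FEATURES:
            fit = glm.fit_ols(measures[h][feat][idx], design)
            smooths[(feat, h)] = rft.estimate_smoothness(fit, mesh)
            stat_maps[(feat, h, "group")] = glm.contrast_t(fit, "group")
    for feat in FEATURES:
        search = sum(smooths[(feat, h)].total_resels for h in hemis)
        euler = sum(meshes[h].euler_characteristic() for h in hemis)
        for h, mesh in meshes.items():
            stat = stat_maps[(feat, h, "group")]
            for alpha in config.cluster_alphas:
                masks[(feat, h, alpha)] = rft.significant_mask(
                    stat, mesh, smooths[(feat, h)], alpha, config.forming_p,
                    search_resels=search, euler_char=euler,
                    provenance=dict(feature=feat, hemisphere=h,
                                    contrast=subgroup_column))
    return ResultBundle(
        config=config, meshes=meshes, cohort=cases, selection={},
        adopted_order=config.age_order, stat_maps=stat_maps,
        cluster_tables=(pd.concat(cluster_rows, ignore_index=True)
                        if cluster_rows else pd.DataFrame()),
        masks=masks, overlap_tables={}, decomposition_tables={},
        null_overlap=None, global_table=pd.DataFrame(), truth=truth,
        provenance=dict(config_hash=config.digest(), seed=config.seed,
                        contrast=subgroup_column),
    )


# ---------------------------------------------------------------------------
# report writing


def write_reports(bundle: ResultBundle, outdir, force: bool = False) -> None:
    """Write cluster CSVs, masks, overlap/decomposition reports and a
    checksummed manifest."""
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True/--force"
        )
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    def save_text(text: str, name: str) -> None:
        p = out / name
        p.write_text(text)
        written.append(p)

    if not bundle.cluster_tables.empty:
        save_df(bundle.cluster_tables, "clusters.csv")
    if not bundle.global_table.empty:
        save_df(bundle.global_table, "global_stats.csv")
    for (feat, h, alpha), mask in bundle.masks.items():
        name = f"mask_{feat}_{h}_a{alpha:g}.curv".replace("0.", "")
        surface.write_vertex_field(
            surface.VertexField(mask.values.astype(float), "mask"),
            out / name)
        written.append(out / name)
    if bundle.overlap_tables:
        frames = [overlap.overlap_to_csv(t)
                  for t in bundle.overlap_tables.values()]
        save_df(pd.concat(frames, ignore_index=True), "overlap.csv")
    if bundle.decomposition_tables:
        frames = [overlap.decomposition_to_csv(t)
                  for t in bundle.decomposition_tables.values()]
        save_df(pd.concat(frames, ignore_index=True), "decomposition.csv")
    if bundle.overlap_tables or bundle.decomposition_tables:
        save_text(overlap.render_tables(bundle.overlap_tables or None,
                                        bundle.decomposition_tables or None),
                  "tables.txt")
    if bundle.null_overlap is not None:
        nr = bundle.null_overlap
        save_text(json.dumps(dict(
            n_sims=nr.n_sims, alpha=nr.alpha,
            observed_overlap_pct=nr.observed_overlap_pct,
            mean_null_pct=nr.mean_null_pct, p_value=nr.p_value), indent=2),
            "overlap_null.json")
    if bundle.selection:
        sel = {h: dict(adopted_order=r.adopted_order,
                       steps=[dict(orders=list(s.orders),
                                   significant=s.significant,
                                   n_clusters=len(s.clusters))
                              for s in r.steps])
               for h, r in bundle.selection.items()}
        save_text(json.dumps(sel, indent=2), "model_selection.json")

    manifest = dict(
        config=bundle.config.to_dict(),
        provenance=bundle.provenance,
        files={p.name: hashlib.sha256(p.read_bytes()).hexdigest()
               for p in written},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
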