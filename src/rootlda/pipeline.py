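"""End-to-end orchestration: cohort -> traits -> shape -> LDA -> inference.

The pipeline runs the full analysis in order — generate or ingest root
systems, compute traits, pairwise shape distances and MDS coordinates,
standardize the 16-variable table, correlation screening, Mahalanobis
group-distance maps, the three discriminant analyses (NUpE, nitrate, and
four-group), zeta^2 subset selection, loading bootstrap, the six block-
permutation tests, and the LD1 percentile exemplars — writing numeric
CSV/JSON outputs (the contract) and figures (best effort) under one
output directory.  Runs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discrim, plots, rsml, select_resample, shape, traits
from .rootgen import default_demo_spec, generate_cohort, group_code_for
from .traits import GEOM_NAMES, META_COLUMNS, TRAIT_NAMES, VARIABLE_NAMES, TraitTable

__all__ = ["PipelineConfig", "RunReport", "read_trait_csv", "run_pipeline"]

log = logging.getLogger("rootlda")

_CODE_TO_NUPE = {0: ("low", "low"), 1: ("low", "high"), 2: ("high", "low"), 3: ("high", "high")}

# canonical name <- squashed-lowercase aliases (external tables included)
_ALIASES: dict[str, str] = {}
for canon, extra in {
    "TotalLength": ["totallength"],
    "AvgSeminalTipAngle": ["averageseminaltipangle", "avgseminaltipangle"],
    "AvgSeminalEmergAngle": ["averageseminalemergenceangle", "avgseminalemergangle",
                             "avgseminalemergenceangle"],
    "AvgSeminalLength": ["averagelengthseminalroots", "avgseminallength",
                         "averageseminallength"],
    "AvgLateralLength": ["averagelengthlateralroots", "avglaterallength",
                         "averagelaterallength"],
    "LateralCount": ["lateralrootcount", "lateralcount"],
    "SeminalCount": ["seminalrootcount", "seminalcount"],
    "ConvexHullArea": ["convexhull", "convexhullarea", "areaofconvexhull"],
    "MaxWidth": ["maximumwidth", "maxwidth"],
    "MaxDepth": ["maximumdepth", "maxdepth"],
    "WidthDepthRatio": ["widthdepthratio", "widthtodepthratio"],
    "plant_id": ["plantid", "id", "plant"],
    "line": ["line", "wheatline", "accession"],
    "nupe_class": ["nupeclass", "nupe"],
    "nitrate": ["nitrate", "nitratelevel", "medium"],
    "group_code": ["groupcode", "group", "code"],
    **{g: [g.lower()] for g in GEOM_NAMES},
}.items():
    for a in extra:
        _ALIASES[a] = canon


def _squash(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", name.lower())


def read_trait_csv(path: str | Path, require_geom: bool = True) -> TraitTable:
    """Read a trait table CSV, mapping external headers to canonical names.

    The file must provide the 11 architecture traits (plus Geom1-Geom5
    unless ``require_geom`` is False) and enough metadata to place each
    plant in a group: either nupe_class and nitrate, or a 0-3 group code.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns={c: _ALIASES.get(_squash(str(c)), c) for c in df.columns})
    wanted = list(VARIABLE_NAMES) if require_geom else list(TRAIT_NAMES)
    missing = [v for v in wanted if v not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing variable columns: {missing}")

    if "group_code" in df.columns and ("nupe_class" not in df.columns
                                       or "nitrate" not in df.columns):
        codes = df["group_code"].astype(int)
        df["nupe_class"] = [_CODE_TO_NUPE[c][0] for c in codes]
        df["nitrate"] = [_CODE_TO_NUPE[c][1] for c in codes]
    if "nupe_class" not in df.columns or "nitrate" not in df.columns:
        raise ValueError(
            f"{path.name}: need metadata columns nupe_class+nitrate or group_code"
        )
    df["group_code"] = [group_code_for(a, b) for a, b in zip(df["nupe_class"], df["nitrate"])]
    if "plant_id" not in df.columns:
        df["plant_id"] = [f"plant_{i:04d}" for i in range(len(df))]
    df["plant_id"] = df["plant_id"].astype(str)
    if "line" not in df.columns:
        df["line"] = "unknown"

    for v in wanted:
        col = pd.to_numeric(df[v], errors="coerce")
        if col.isna().any():
            rows = df.index[col.isna()].tolist()[:5]
            raise ValueError(f"{path.name}: non-numeric cells in column {v!r}, rows {rows}")
        df[v] = col
    table = TraitTable(data=df[list(META_COLUMNS) + wanted], variables=tuple(wanted))
    counts = df.groupby(["line", "nitrate"]).size()
    log.info("read %s: N=%d plants, %d line x nitrate cells", path.name, len(df), len(counts))
    return table


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (defaults follow the study)."""

    source: str = "synthetic"  # "synthetic" | "rsml" | "csv"
    input_path: str | None = None  # rsml dir or trait csv
    n_per_cell: int = 17  # synthetic source only
    resample_m: int = 50
    mds_dims: int = 5
    analyses: tuple[str, ...] = ("nupe-2group", "nitrate-2group", "four-group")
    subset_sizes: tuple[int, ...] | None = None  # default 1..p-1
    best_subset_size: int = 9
    n_bootstrap: int = 1000
    n_permutations: int = 10000
    seed: int = 0
    confidence_level: float = 0.99
    correlation_threshold: float = 0.5
    out_dir: str = "rootlda_out"
    write_rsml: bool = False
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mds_dims < 1:
            raise ValueError("mds_dims must be >= 1")
        if self.n_bootstrap < 1 or self.n_permutations < 1:
            raise ValueError("n_bootstrap and n_permutations must be >= 1")
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("analyses", "subset_sizes"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["analyses"] = list(d["analyses"])
        if d["subset_sizes"] is not None:
            d["subset_sizes"] = list(d["subset_sizes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @property
    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Provenance and outputs of one pipeline run."""

    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.seed,
             "stages_completed": self.stages_completed,
             "outputs": self.outputs, "summary": self.summary},
            indent=2, default=str))


_ANALYSIS_LABELS = {
    "nupe-2group": "nupe_class",
    "nitrate-2group": "nitrate",
    "four-group": "group_code",
}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all requested stages; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash, seed=config.seed)
    config.to_yaml(out / "config.yaml")
    report.outputs["config"] = str(out / "config.yaml")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                res = fn()
            except Exception as e:
                report.save(out / "report.json")
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            report.stages_completed.append(name)
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return res

        return wrap

    cohort = None
    if config.source == "csv":
        table = stage("ingest")(lambda: read_trait_csv(config.input_path))
    else:
        if config.source == "synthetic":
            spec = default_demo_spec(rng_seed=config.seed, n_per_cell=config.n_per_cell)
            cohort = stage("generate")(lambda: generate_cohort(spec))
            if config.write_rsml:
                paths = rsml.write_cohort(cohort, out / "rsml")
                report.outputs["rsml_dir"] = str(out / "rsml")
                report.summary["n_rsml_files"] = len(paths)
        elif config.source == "rsml":
            cohort = stage("ingest")(lambda: rsml.read_cohort(config.input_path))
        else:
            raise ValueError(f"unknown source {config.source!r}")

        params = shape.DistanceParams(m=config.resample_m)
        D = stage("distances")(lambda: shape.distance_matrix(cohort, params))
        D.to_csv(out / "distances.csv")
        report.outputs["distances"] = str(out / "distances.csv")
        emb = stage("embed")(lambda: shape.classical_mds(D, k=config.mds_dims))
        report.summary["mds_eigenvalues"] = emb.eigenvalues.tolist()
        report.summary["mds_positive_mass_fraction"] = emb.positive_mass_fraction
        table = stage("traits")(lambda: traits.build_trait_table(cohort, emb))
        if config.make_plots:
            report.outputs["overlay"] = str(
                stage("overlay_plot")(lambda: plots.overlay_plot(cohort, out / "fig_overlay.png"))
            )

    table.to_csv(out / "traits_raw.csv")
    report.outputs["traits_raw"] = str(out / "traits_raw.csv")
    ztable = stage("standardize")(lambda: traits.standardize(table))
    ztable.to_csv(out / "traits_scaled.csv")
    report.outputs["traits_scaled"] = str(out / "traits_scaled.csv")
    report.summary["n_plants"] = ztable.n_plants
    report.summary["n_variables"] = len(ztable.variables)

    keep, corr = stage("correlations")(
        lambda: traits.correlated_subset(ztable, config.correlation_threshold)
    )
    corr.to_csv(out / "correlations.csv")
    report.outputs["correlations"] = str(out / "correlations.csv")
    report.summary["correlated_variables"] = keep
    if config.make_plots and keep:
        report.outputs["fig_correlations"] = str(
            stage("correlation_panel")(
                lambda: plots.correlation_panel(corr, keep, out / "fig_correlations.png"))
        )

    X = ztable.values
    names = list(ztable.variables)
    codes = ztable.meta("group_code").astype(int)

    maps = {}
    for ordering in ("line-pairs", "nitrate-blocks"):
        gmap = stage(f"mahalanobis[{ordering}]")(
            lambda o=ordering: discrim.group_distance_map(ztable, ordering=o)
        )
        gmap.to_frame().to_csv(out / f"mahalanobis_{ordering}.csv")
        report.outputs[f"mahalanobis_{ordering}"] = str(out / f"mahalanobis_{ordering}.csv")
        if config.make_plots:
            plots.distance_heatmap(gmap, out / f"fig_mahalanobis_{ordering}.png")
        maps[ordering] = gmap

    pca_res = stage("pca")(lambda: discrim.pca(X, k=min(3, X.shape[1])))
    report.summary["pca_eigenvalues"] = pca_res.eigenvalues.tolist()

    models = {}
    for analysis in config.analyses:
        label_col = _ANALYSIS_LABELS[analysis]
        labels = ztable.meta(label_col)
        ref = ztable.meta("nupe_class") if analysis == "four-group" else labels
        model = stage(f"lda[{analysis}]")(
            lambda l=labels, r=ref: discrim.fit_lda(X, l, orientation_ref=r,
                                                    variable_names=names)
        )
        models[analysis] = model
        model.loadings_frame().to_csv(out / f"lda_{analysis}_loadings.csv")
        sdf = pd.DataFrame(model.scores_,
                           columns=[f"LD{i + 1}" for i in range(model.scores_.shape[1])])
        sdf.insert(0, "plant_id", ztable.plant_ids)
        sdf["group_code"] = codes
        sdf.to_csv(out / f"lda_{analysis}_scores.csv", index=False)
        (out / f"lda_{analysis}_model.json").write_text(json.dumps(model.to_dict(), indent=2))
        report.outputs[f"lda_{analysis}"] = str(out / f"lda_{analysis}_model.json")
        if config.make_plots:
            plots.score_density_plot(model.scores_, codes,
                                     out / f"fig_lda_{analysis}_densities.png")
            plots.loadings_plot(model.loadings_frame(),
                                out / f"fig_lda_{analysis}_loadings.png")

    sizes = (tuple(config.subset_sizes) if config.subset_sizes is not None
             else tuple(range(1, len(names))))
    sel = stage("select")(
        lambda: select_resample.Zeta2SubsetSelector(sizes=sizes, variable_names=names)
        .fit(X, codes)
    )
    subsets_json = [
        {"size": s.size, "zeta2": s.zeta2, "hotelling_lawley": s.hotelling_lawley,
         "r": s.r, "subset": list(s.subset)}
        for s in sel.best_subsets_
    ]
    (out / "best_subsets.json").write_text(json.dumps(subsets_json, indent=2))
    report.outputs["best_subsets"] = str(out / "best_subsets.json")

    by_size = {s.size: s for s in sel.best_subsets_}
    q = config.best_subset_size
    if q not in by_size:
        q = max(by_size)
    best = by_size[q]
    best_idx = tuple(names.index(v) for v in best.subset)
    report.summary["best_subset"] = {"size": q, "variables": list(best.subset),
                                     "zeta2": best.zeta2}

    Xb = X[:, list(best_idx)]
    bnames = list(best.subset)
    model_best = stage("lda[best-subset]")(
        lambda: discrim.fit_lda(Xb, codes, orientation_ref=ztable.meta("nupe_class"),
                                variable_names=bnames)
    )
    model_best.loadings_frame().to_csv(out / "lda_best_subset_loadings.csv")
    report.outputs["lda_best_subset"] = str(out / "lda_best_subset_loadings.csv")

    if "four-group" in models:
        for tag, model in (("all_vars", models["four-group"]), ("best_subset", model_best)):
            if model.scores_.shape[1] < 2:
                continue
            for dims in ((0, 1), (0, 2)) if model.scores_.shape[1] >= 3 else ((0, 1),):
                ell = stage(f"confidence[{tag}{dims}]")(
                    lambda m=model, d=dims: discrim.mean_confidence_regions(
                        m, codes, level=config.confidence_level, dims=d)
                )
                if config.make_plots:
                    plots.confidence_region_plot(
                        ell, out / f"fig_confidence_{tag}_LD{dims[0]+1}_LD{dims[1]+1}.png",
                        dims=(f"LD{dims[0]+1}", f"LD{dims[1]+1}"))

    boot = stage("bootstrap")(
        lambda: select_resample.bootstrap_loadings(
            Xb, codes, B=config.n_bootstrap, seed=config.seed, variable_names=bnames)
    )
    boot.table().to_csv(out / "bootstrap_loadings.csv")
    report.outputs["bootstrap_loadings"] = str(out / "bootstrap_loadings.csv")
    report.summary["bootstrap_max_p"] = float(boot.p_values.max())

    perm_results = []
    for i, scheme in enumerate(sorted(select_resample.PERMUTATION_SCHEMES)):
        res = stage(f"permute[{scheme}]")(
            lambda s=scheme, k=i: select_resample.permutation_test(
                X, codes, scheme=s, n_perm=config.n_permutations,
                seed=config.seed + 1 + k, subset=best_idx, variable_names=names)
        )
        perm_results.append(res)
    (out / "permutation_tests.json").write_text(json.dumps(
        [{"scheme": r.scheme, "observed_zeta2": r.observed, "p_value": r.p_value,
          "n_permutations": r.n_permutations} for r in perm_results], indent=2))
    report.outputs["permutation_tests"] = str(out / "permutation_tests.json")
    report.summary["permutation_p_values"] = {r.scheme: r.p_value for r in perm_results}
    if config.make_plots:
        plots.permutation_histograms(perm_results, out / "fig_permutations.png")

    exemplars = stage("exemplars")(
        lambda: discrim.percentile_exemplars(model_best.scores_[:, 0], ztable.plant_ids)
    )
    (out / "exemplars.json").write_text(json.dumps(
        [{"percentile": q_, "ld1_value": v, "plant_ids": ids} for q_, v, ids in exemplars],
        indent=2))
    report.outputs["exemplars"] = str(out / "exemplars.json")
    if config.make_plots and cohort is not None:
        plots.exemplar_strip(exemplars, cohort, out / "fig_exemplars.png")

    report.save(out / "report.json")
    report.outputs["report"] = str(out / "report.json")
    return report
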