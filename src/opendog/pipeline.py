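"""Configuration-driven end-to-end orchestration.

simulate (or load) -> QC/time-match -> feature extraction -> multivariate
analysis -> artifacts + a machine-readable run report.  All randomness flows
from one master seed through named per-stage substreams, so an identical
config and seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
import warnings
import dataclasses
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import features as F
from . import multivariate as M
from . import synthetic as S
from . import track_geo as T

log = logging.getLogger("opendog")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisOptions:
    n_boot: int = 5000
    n_components: int = 4
    k_clusters: int = 4
    k_axes: int = 2
    rotation: str = "varimax"
    dfa_space: str = "raw"          # "raw" or "pca"
    estimation_groups: tuple[str, str] | None = None  # default: two largest
    salience_threshold: float = 0.5


@dataclass
class PipelineConfig:
    input_mode: str = "simulate"     # simulate | csv_dir | gpx_dir
    manifest: str | None = None      # for csv_dir / gpx_dir modes
    seed: int = 0
    out_dir: str = "opendog_out"
    cohort: S.CohortSpec = field(default_factory=S.CohortSpec)
    feature_config: F.FeatureConfig = field(default_factory=F.FeatureConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for key in ("input_mode", "manifest", "seed", "out_dir"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "feature_config" in raw:
            cfg.feature_config = F.FeatureConfig(**{
                k: tuple(v) if k == "divider_scales" else v
                for k, v in raw["feature_config"].items()})
        if "analysis" in raw:
            a = dict(raw["analysis"])
            if "estimation_groups" in a and a["estimation_groups"] is not None:
                a["estimation_groups"] = tuple(a["estimation_groups"])
            cfg.analysis = AnalysisOptions(**a)
        if "cohort" in raw:
            c = dict(raw["cohort"])
            handler = S.HandlerSpec(**c.pop("handler", {}))
            archetypes = c.pop("archetypes", None)
            if archetypes is None:
                arch_spec = tuple((a, 4) for a in S.DEFAULT_ARCHETYPES)
            else:
                arch_spec = tuple(
                    (S.ArchetypeParams(**{k: v for k, v in d.items()
                                          if k != "n_dogs"}), d.get("n_dogs", 4))
                    for d in archetypes)
            cfg.cohort = S.CohortSpec(archetypes=arch_spec, handler=handler, **c)
        if "seed" in raw:
            cfg.cohort = dataclasses.replace(cfg.cohort,
                                             master_seed=int(raw["seed"]))
        return cfg


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def load_manifest_dyads(manifest: str | Path, fmt: str
                        ) -> list[tuple[T.DyadTrack, str, str]]:
    """Read (dyad, dog_id, group_label) triples from a manifest CSV.

    Manifest columns: run_id, dog_id, group_label, dog_path, handler_path;
    paths are resolved relative to the manifest location.
    """
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    needed = {"run_id", "dog_id", "group_label", "dog_path", "handler_path"}
    if not needed.issubset(df.columns):
        raise PipelineError("load", f"manifest missing columns "
                                    f"{sorted(needed - set(df.columns))}")
    out = []
    for row in df.itertuples(index=False):
        for p in (row.dog_path, row.handler_path):
            if not (manifest.parent / p).exists():
                raise PipelineError("load", f"missing track file: {p}")
        dog = T.read_track(manifest.parent / row.dog_path, fmt,
                           actor="dog", run_id=str(row.run_id))
        handler = T.read_track(manifest.parent / row.handler_path, fmt,
                               actor="handler", run_id=str(row.run_id))
        dog, _ = T.qc_track(dog, T.DEFAULT_MAX_SPEED_DOG)
        handler, _ = T.qc_track(handler, T.DEFAULT_MAX_SPEED_HANDLER)
        out.append((T.time_match(dog, handler), str(row.dog_id),
                    str(row.group_label)))
    return out


def extract_feature_table(dyads: list[tuple[T.DyadTrack, str, str]],
                          config: F.FeatureConfig) -> pd.DataFrame:
    """Run feature extraction over dyads into the runs x features table."""
    rows = []
    for dyad, dog_id, group in dyads:
        fv = F.extract_features(dyad, config, dog_id=dog_id,
                                group_label=group)
        rows.append({"run_id": fv.run_id, "dog_id": fv.dog_id,
                     "group_label": fv.group_label, **fv.values})
    table = pd.DataFrame(rows, columns=list(M.META_COLUMNS) +
                         list(F.FEATURE_NAMES))
    return table


def analyze_feature_table(table: pd.DataFrame, opts: AnalysisOptions,
                          seed: int, out_dir: Path | None = None
                          ) -> dict[str, Any]:
    """The statistics stack over a feature table; optionally writes artifacts.

    Returns a dict with all in-memory results plus a JSON-ready summary.
    """
    files: list[str] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        if out_dir is not None:
            path = out_dir / name
            df.to_csv(path, **kw)
            files.append(name)

    std = M.log_standardize(table)
    save(std, "features_standardized.csv", index=False)

    corr = M.correlation_screen(std)
    save(corr.rho, "correlation_rho.csv")
    save(corr.p, "correlation_p.csv")
    if corr.p_adjusted is not None:
        save(corr.p_adjusted, "correlation_p_bh.csv")

    # estimation: per-feature median difference between two groups
    groups = list(table["group_label"].value_counts().index)
    if opts.estimation_groups is not None:
        ga, gb = opts.estimation_groups
    elif len(groups) >= 2:
        ga, gb = sorted(groups[:2])
    else:
        ga = gb = None
    estimation: list[M.EstimationResult] = []
    if ga is not None and ga != gb:
        ss = np.random.SeedSequence((seed, 101))
        feat_seeds = ss.generate_state(len(F.FEATURE_NAMES)) % (2 ** 31)
        for fs, feat in zip(feat_seeds, F.FEATURE_NAMES):
            a = table.loc[table.group_label == ga, feat].dropna()
            b = table.loc[table.group_label == gb, feat].dropna()
            if len(a) < 3 or len(b) < 3:
                continue
            estimation.append(M.bootstrap_median_diff(
                a, b, n_boot=opts.n_boot, seed=int(fs), feature=feat))
        est_df = pd.DataFrame([asdict(e) for e in estimation])
        if len(est_df):
            save(est_df, "estimation_median_diff.csv", index=False)

    dfa_table = std
    if opts.dfa_space == "pca":
        pre = M.pca_rotated(std, n_components=opts.n_components,
                            rotation=None)
        dfa_table = pd.concat(
            [std[list(M.META_COLUMNS)].reset_index(drop=True),
             pre.scores.reset_index(drop=True)], axis=1)
    dfa = M.discriminant_analysis(dfa_table, table["group_label"])
    save(dfa.canonical_axes, "dfa_axes.csv")
    save(pd.concat([table[list(M.META_COLUMNS)].reset_index(drop=True),
                    dfa.scores.reset_index(drop=True)], axis=1),
         "dfa_scores.csv", index=False)

    pca = M.pca_rotated(std, n_components=opts.n_components,
                        rotation=opts.rotation)
    save(pca.loadings, "pca_loadings.csv")
    save(pca.rotated_loadings, "pca_rotated_loadings.csv")
    axis_labels = M.label_axes(pca, opts.salience_threshold)

    # two-way clustering on per-dog mean rotated scores, each axis kept on
    # its natural scale (sd = sqrt of its variance share) so that dog-dog
    # distances reflect the data metric rather than whitened axes
    weighted = pca.rotated_scores * np.sqrt(pca.rotated_variance_pct / 100.0)
    rs = pd.concat([table[["dog_id"]].reset_index(drop=True),
                    weighted.reset_index(drop=True)], axis=1)
    dog_scores = rs.groupby("dog_id").mean()
    save(dog_scores, "dog_scores.csv")
    clusters = M.two_way_ward(dog_scores, k=opts.k_clusters,
                              k_axes=opts.k_axes,
                              axis_profiles=pca.rotated_loadings)
    save(clusters.assignments.to_frame(), "clusters_dogs.csv")
    if clusters.axis_assignments is not None:
        save(clusters.axis_assignments.to_frame(), "clusters_axes.csv")
    if out_dir is not None:
        newick = M.linkage_to_newick(clusters.linkage,
                                     list(dog_scores.index))
        (out_dir / "dendrogram_dogs.nwk").write_text(newick + "\n")
        files.append("dendrogram_dogs.nwk")
        if clusters.axis_linkage is not None:
            (out_dir / "dendrogram_axes.nwk").write_text(
                M.linkage_to_newick(clusters.axis_linkage,
                                    list(dog_scores.columns)) + "\n")
            files.append("dendrogram_axes.nwk")

    return {
        "standardized": std, "correlation": corr, "estimation": estimation,
        "dfa": dfa, "pca": pca, "axis_labels": axis_labels,
        "dog_scores": dog_scores, "clusters": clusters, "files": files,
        "summary": {
            "n_runs": int(len(table)),
            "n_dogs": int(table["dog_id"].nunique()),
            "wilks_lambda": dfa.wilks_lambda,
            "wilks_p": dfa.p_value,
            "dfa_regularized": dfa.regularized,
            "pc_variance_pct": [float(v) for v in pca.variance_pct],
            "rotated_variance_pct": [float(v)
                                     for v in pca.rotated_variance_pct],
            "axis_labels": axis_labels,
            "cluster_sizes": clusters.assignments.value_counts()
                                     .sort_index().tolist(),
        },
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the JSON-ready run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "input_mode": config.input_mode,
        "stages": {}, "files": [], "warnings": [],
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- acquire dyads -------------------------------------------------
        if config.input_mode == "simulate":
            log.info("simulating cohort (seed %d)", config.cohort.master_seed)
            cohort = S.simulate_cohort(config.cohort)
            dyads = [(r.dyad, r.dog_id, r.archetype) for r in cohort]
            manifest = pd.DataFrame(
                [{"run_id": r.dyad.run_id, "dog_id": r.dog_id,
                  "group_label": r.archetype, "run_index": r.run_index,
                  "seed": r.seed} for r in cohort])
            manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
            report["files"].append("cohort_manifest.csv")
            report["stages"]["simulate"] = {"n_dyads": len(dyads)}
        elif config.input_mode in ("csv_dir", "gpx_dir"):
            if not config.manifest:
                raise PipelineError("load", "manifest required for file input")
            fmt = "csv" if config.input_mode == "csv_dir" else "gpx"
            try:
                dyads = load_manifest_dyads(config.manifest, fmt)
            except T.TrackError as e:
                raise PipelineError("load", str(e)) from e
            report["stages"]["load"] = {"n_dyads": len(dyads)}
        else:
            raise PipelineError("config",
                                f"unknown input mode {config.input_mode!r}")

        # --- features ------------------------------------------------------
        try:
            table = extract_feature_table(dyads, config.feature_config)
        except F.FeatureError as e:
            raise PipelineError("features", str(e)) from e
        table.to_csv(out_dir / "feature_table.csv", index=False)
        report["files"].append("feature_table.csv")
        report["stages"]["features"] = {
            "n_runs": len(table),
            "n_missing_values": int(table[list(F.FEATURE_NAMES)]
                                    .isna().sum().sum())}

        # --- analysis ------------------------------------------------------
        try:
            results = analyze_feature_table(table, config.analysis,
                                            config.seed, out_dir)
        except M.AnalysisError as e:
            raise PipelineError("analysis", str(e)) from e
        report["files"].extend(results["files"])
        report["stages"]["analysis"] = results["summary"]

        report["warnings"] = sorted({str(w.message) for w in caught})

    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["files"].append("run_report.json")
    return report
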