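"""Configuration-driven orchestration of the full analysis.

Stages: ``simulate`` (synthetic cohort), ``beamform``/``connect`` (sensor
mode only), ``graph`` (quadrant global measures per subject and band),
``stats`` (group comparison with FDR and feature selection), ``nbs``
(subnetwork detection) and ``classify`` (repeated Naive-Bayes CV).  All
randomness derives from one root seed with per-stage substreams; every
output file is recorded in a manifest with content hashes, so a rerun of
the same configuration yields identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, nbs, stats, synthetic
from .atlas import AtlasTable, default_atlas
from .bands import BAND_ORDER, get_band
from .beamformer import VirtualElectrodeSet, beamform
from .connectivity import connectivity_matrix
from .graph import extract_quadrant, global_measures, proportional_threshold

STAGES = ("simulate", "beamform", "connect", "graph", "stats", "nbs", "classify")


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    stages: tuple[str, ...] = ("simulate", "graph", "stats", "nbs", "classify")
    seed: int = 0
    outdir: str = "hemimeg_out"
    # cohort
    mode: str = "adjacency"  # "sensor" runs the beamform/connect stages too
    groups: tuple[tuple[str, int], ...] = (("HC", 22), ("LP", 25), ("RP", 16))
    effect_delta: float = 0.10
    between_subject_sd: float = 0.05
    n_rois: int = 246
    bands: tuple[str, ...] = BAND_ORDER
    # graph
    density: float = 0.10
    # nbs
    nbs_threshold: float = 3.45
    nbs_permutations: int = 5000
    nbs_alpha: float = 0.05
    nbs_direction: str = "both"
    nbs_band: str = "theta"
    # classifier
    cv_folds: int = 10
    cv_repeats: int = 100
    select_alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.nbs_permutations < 100:
            raise ValueError("nbs_permutations must be at least 100")
        if self.nbs_threshold <= 0:
            raise ValueError("nbs_threshold must be positive")


_TUPLE_FIELDS = {"stages", "bands"}


def validate_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file, apply defaults, reject unknown keys."""
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    raw.update(overrides)
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k in _TUPLE_FIELDS & set(raw):
        raw[k] = tuple(raw[k])
    if "groups" in raw:
        raw["groups"] = tuple((str(a), int(b)) for a, b in raw["groups"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def global_feature_table(
    cohort: synthetic.Cohort,
    atlas: AtlasTable,
    bands: tuple[str, ...] | None = None,
    density: float = 0.10,
) -> pd.DataFrame:
    """GE/CPL/T per band and hemisphere quadrant for every subject.

    Feature columns are named ``<measure>_<band>_<side>``.
    """
    bands = bands or tuple(cohort.spec.bands)
    rows = []
    for s in cohort.subjects:
        row: dict = {"subject_id": s.subject_id, "label": s.group}
        for band in bands:
            adj = s.matrices[band]
            for side in ("left", "right"):
                quad = extract_quadrant(adj, atlas, side)
                g = proportional_threshold(quad, density)
                gm = global_measures(g, network=f"{side}_intra", band=band)
                row[f"ge_{band}_{side}"] = gm.ge
                row[f"cpl_{band}_{side}"] = gm.cpl
                row[f"t_{band}_{side}"] = gm.transitivity
        rows.append(row)
    return pd.DataFrame(rows)


def select_features(
    features: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Features significantly different between two groups at BH-FDR < alpha."""
    comp = stats.compare_feature_table(features, group_a, group_b)
    selected = comp.loc[comp["p_fdr"] < alpha, "feature"].tolist()
    return selected, comp


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = default_atlas()
    seeds = np.random.SeedSequence(config.seed).spawn(len(STAGES))
    stage_seed = {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(STAGES, seeds)
    }
    manifest: dict = {"config": asdict(config), "outputs": {}, "timing": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["outputs"].setdefault(stage, {})
        for p in paths:
            manifest["outputs"][stage][str(p.relative_to(outdir))] = _sha256(p)

    cohort = None
    features = None

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        if config.mode == "sensor":
            spec = synthetic.sensor_cohort_spec(
                seed=stage_seed["simulate"],
                groups=config.groups,
                n_rois=config.n_rois,
            )
        else:
            spec = synthetic.default_cohort_spec(
                seed=stage_seed["simulate"],
                delta=config.effect_delta,
                groups=config.groups,
                bands=config.bands,
            )
        cohort = synthetic.generate_cohort(spec)
        cohort.save(outdir / "cohort")
        record("simulate", outdir / "cohort" / "manifest.json")
        manifest["timing"]["simulate"] = time.perf_counter() - t0

    if "beamform" in config.stages:
        if cohort is None:
            cohort = _load_cohort(outdir)
        t0 = time.perf_counter()
        _, lfs, _ = synthetic.sensor_geometry(cohort.spec.seed, cohort.spec.n_rois)
        paths = []
        for s in cohort.subjects:
            if s.sensors is None:
                raise FileNotFoundError(
                    f"missing artifact: sensor data for {s.subject_id} "
                    "(beamform needs a sensor-mode cohort)"
                )
            ve = beamform(s.sensors, lfs)
            p = outdir / "cohort" / s.subject_id / f"{s.subject_id}_ve.h5"
            ve.save(p)
            paths.append(p)
        record("beamform", *paths)
        manifest["timing"]["beamform"] = time.perf_counter() - t0

    if "connect" in config.stages:
        if cohort is None:
            cohort = _load_cohort(outdir)
        t0 = time.perf_counter()
        paths = []
        for s in cohort.subjects:
            vpath = outdir / "cohort" / s.subject_id / f"{s.subject_id}_ve.h5"
            if not vpath.exists():
                raise FileNotFoundError(
                    f"missing artifact: {vpath.name} required by stage "
                    "'connect' (run the beamform stage first)"
                )
            ve = VirtualElectrodeSet.load(vpath)
            s.matrices = {}
            for band in cohort.spec.bands:
                cm = connectivity_matrix(ve, get_band(band))
                p = outdir / "cohort" / s.subject_id / f"{s.subject_id}_{band}.tsv"
                cm.save(p)
                s.matrices[band] = cm.matrix
                paths.append(p)
        record("connect", *paths)
        manifest["timing"]["connect"] = time.perf_counter() - t0

    if "graph" in config.stages:
        if cohort is None:
            cohort = _load_cohort(outdir)
        t0 = time.perf_counter()
        features = global_feature_table(
            cohort, atlas, config.bands, config.density
        )
        fpath = outdir / "global_measures.tsv"
        features.to_csv(fpath, sep="\t", index=False)
        record("graph", fpath)
        manifest["timing"]["graph"] = time.perf_counter() - t0

    if "stats" in config.stages:
        features = _require_features(features, outdir, "stats")
        t0 = time.perf_counter()
        selected, comp = select_features(
            features, "LP", "RP", config.select_alpha
        )
        spath = outdir / "feature_comparison.tsv"
        comp.to_csv(spath, sep="\t", index=False)
        jpath = outdir / "selected_features.json"
        jpath.write_text(json.dumps({"selected": selected}, indent=2))
        record("stats", spath, jpath)
        manifest["timing"]["stats"] = time.perf_counter() - t0

    if "nbs" in config.stages:
        if cohort is None:
            cohort = _load_cohort(outdir)
        t0 = time.perf_counter()
        cfg = nbs.NBSConfig(
            primary_threshold=config.nbs_threshold,
            n_permutations=config.nbs_permutations,
            alpha=config.nbs_alpha,
            direction=config.nbs_direction,
            seed=stage_seed["nbs"],
        )
        res = nbs.nbs_test(
            cohort.matrices("LP", config.nbs_band),
            cohort.matrices("RP", config.nbs_band),
            cfg,
        )
        epath = outdir / "nbs_edges.tsv"
        jpath = outdir / "nbs_summary.json"
        nbs.save_result(res, epath, jpath)
        record("nbs", epath, jpath)
        manifest["timing"]["nbs"] = time.perf_counter() - t0

    if "classify" in config.stages:
        features = _require_features(features, outdir, "classify")
        t0 = time.perf_counter()
        sel_path = Path(config.outdir) / "selected_features.json"
        if sel_path.exists():
            selected = json.loads(sel_path.read_text())["selected"]
        else:
            selected, _ = select_features(features, "LP", "RP", config.select_alpha)
        pat = features[features["label"].isin(["LP", "RP"])]
        cols = ["subject_id", "label"] + (
            selected or [c for c in pat.columns if c not in ("subject_id", "label")]
        )
        report = classify.nb_crossvalidate(
            pat[cols],
            n_folds=config.cv_folds,
            n_repeats=config.cv_repeats,
            seed=stage_seed["classify"],
        )
        cpath = outdir / "classifier_report.json"
        cpath.write_text(json.dumps(report.to_dict(), indent=2))
        record("classify", cpath)
        manifest["timing"]["classify"] = time.perf_counter() - t0

    mpath = outdir / "run_manifest.json"
    stable = {k: v for k, v in manifest.items() if k != "timing"}
    mpath.write_text(json.dumps(stable, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(mpath)
    return manifest


def _load_cohort(outdir: Path) -> synthetic.Cohort:
    cdir = outdir / "cohort"
    if not (cdir / "manifest.json").exists():
        raise FileNotFoundError(
            "missing artifact: cohort/manifest.json (run the simulate stage first)"
        )
    return synthetic.Cohort.load(cdir)


def _require_features(features, outdir: Path, stage: str) -> pd.DataFrame:
    if features is not None:
        return features
    fpath = outdir / "global_measures.tsv"
    if not fpath.exists():
        raise FileNotFoundError(
            f"missing artifact: global_measures.tsv required by stage "
            f"'{stage}' (run the graph stage first)"
        )
    return pd.read_csv(fpath, sep="\t")
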