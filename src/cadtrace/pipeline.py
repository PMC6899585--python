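"""End-to-end orchestration: config validation, stages, and the run ledger.

The pipeline mirrors the analysis ladder of a stable-isotope-assisted
untargeted metabolomics study: simulate (or load) aligned dual-mode feature
matrices, select differential features by OPLS-DA + S-plot, annotate and test
pathway enrichment, subtract control-detected features, and trace 15N
isotopologue pairs.  Both chromatographic modes are processed independently
and merged in the report.  Every stage appends its feature counts and the
thresholds actually applied to a run report, and the whole run is
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import annotation_enrichment as ae
from . import feature_core as fc
from . import isotope_tracing as it
from . import multivariate as mv
from . import specific_features as sf
from . import synthetic_data as sd

STAGES = ("simulate", "multivariate", "enrich", "specific", "trace", "report")


class ConfigError(ValueError):
    pass


class StageDependencyError(RuntimeError):
    pass


#: Config schema: block -> {key: default}.  Unknown blocks or keys are rejected.
_SCHEMA: dict[str, dict[str, Any]] = {
    "seed": None,            # scalar
    "output_dir": None,      # scalar
    "paths": {"library": None},
    "scenario": {"design": "tracing", "panel": "default", "replicates": 3,
                 "noise_cv": None, "p_cad": 0.6, "p_lys": 0.935,
                 "n_background": 480, "n_differential": 20},
    "scaling": {"mode": "unit_variance"},
    "selection": {"p1_cutoff": 0.02, "pcorr_cutoff": 0.02},
    "multivariate": {"folds": 7, "max_orthogonal": 5},
    "annotation": {"ppm_tolerance": 10.0},
    "enrichment": {"alpha": 0.05, "background": "annotated_features"},
    "specificity": {"min_case_replicates": None, "max_control_detections": 0},
    "pair_search": {"delta_mass": sd.DELTA_15N, "ppm_tolerance": 5.0,
                    "rt_tolerance": 0.1},
    "classification": {"min_enrichment_pct": 5.0, "asymmetry_tolerance": 0.5,
                       "full_band": [0.75, 1.25], "half_band": [0.35, 0.65],
                       "correction": "normalize"},
    "classes": {"control_genotype": "Col-0", "case_genotypes": None},
}


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str
    blocks: dict[str, dict[str, Any]]

    def __getitem__(self, block: str) -> dict[str, Any]:
        return self.blocks[block]


def load_config(source: str | dict) -> PipelineConfig:
    """Validate a config mapping (or YAML file path) against the schema."""
    if isinstance(source, str):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key in raw:
        if key not in _SCHEMA:
            raise ConfigError(f"unknown config key {key!r}")
    for block, defaults in _SCHEMA.items():
        if not isinstance(defaults, dict):
            continue
        given = raw.get(block, {})
        if given is None:
            given = {}
        if not isinstance(given, dict):
            raise ConfigError(f"config block {block!r} must be a mapping")
        for key in given:
            if key not in defaults:
                raise ConfigError(f"unknown key {block}.{key}")
    seed = raw.get("seed")
    if seed is None:
        raise ConfigError("config requires a seed")
    output_dir = raw.get("output_dir")
    if not output_dir:
        raise ConfigError("config requires output_dir")
    blocks = {}
    for block, defaults in _SCHEMA.items():
        if not isinstance(defaults, dict):
            continue
        merged = dict(defaults)
        merged.update(raw.get(block) or {})
        blocks[block] = merged
    return PipelineConfig(int(seed), str(output_dir), blocks)


# -- helpers ---------------------------------------------------------------


def _out(config: PipelineConfig, name: str) -> str:
    os.makedirs(config.output_dir, exist_ok=True)
    return os.path.join(config.output_dir, name)


def _require(config: PipelineConfig, *names: str) -> list[str]:
    paths = [os.path.join(config.output_dir, n) for n in names]
    missing = [p for p in paths if not os.path.exists(p)]
    if missing:
        raise StageDependencyError(
            "missing required input artifact(s): " + ", ".join(missing)
            + " — run the producing stage first")
    return paths


def _append_report(config: PipelineConfig, stage: str,
                   counts: dict[str, Any], settings: dict[str, Any]) -> None:
    path = _out(config, "run_report.jsonl")
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps({"stage": stage, "counts": counts,
                             "settings": settings}, sort_keys=True) + "\n")


def _load_matrices(config: PipelineConfig) -> dict[str, fc.FeatureMatrix]:
    matrices = {}
    for mode in fc.MODES:
        name = f"matrix_{mode}.tsv"
        path = os.path.join(config.output_dir, name)
        if os.path.exists(path):
            _require(config, "samples.tsv")
            matrices[mode] = fc.read_matrix(path, _out(config, "samples.tsv"))
    if not matrices:
        raise StageDependencyError(
            "no feature matrices found in output_dir — run the simulate stage "
            "or place matrix_RP.tsv / matrix_HI.tsv plus samples.tsv there")
    return matrices


def _class_vector(matrix: fc.FeatureMatrix, control: str,
                  case: list[str] | None) -> np.ndarray:
    genotypes = matrix.genotypes()
    if control not in genotypes:
        raise ConfigError(f"control genotype {control!r} not in matrix")
    case = case or [g for g in genotypes if g != control]
    return np.array([1.0 if s.genotype in case else -1.0 for s in matrix.samples])


# -- stages ----------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> dict[str, Any]:
    cfg = config["scenario"]
    seed = config.seed
    if cfg["design"] == "tracing":
        noise = 0.1 if cfg["noise_cv"] is None else float(cfg["noise_cv"])
        scenario = sd.tracing_scenario(seed, p_cad=float(cfg["p_cad"]),
                                       noise_cv=noise, p_lys=float(cfg["p_lys"]))
    elif cfg["design"] == "profiling":
        noise = 0.2 if cfg["noise_cv"] is None else float(cfg["noise_cv"])
        scenario = sd.profiling_scenario(seed, noise_cv=noise)
    else:
        raise ConfigError(f"unknown scenario design {cfg['design']!r}")
    if cfg["panel"] == "default":
        panel = sd.default_panel()
    elif cfg["panel"] == "benchmark":
        panel = sd.benchmark_panel(int(cfg["n_differential"]),
                                   int(cfg["n_background"]), seed=seed)
    else:
        raise ConfigError(f"unknown panel {cfg['panel']!r}")
    matrices, truth = sd.simulate_feature_tables(scenario, panel)
    counts = {}
    for mode, matrix in matrices.items():
        fc.write_matrix(matrix, _out(config, f"matrix_{mode}.tsv"))
        counts[f"features_{mode}"] = matrix.n_features
    any_matrix = next(iter(matrices.values()))
    fc.write_sample_meta(any_matrix.samples, _out(config, "samples.tsv"))
    sd.write_ground_truth(truth, _out(config, "ground_truth.tsv"))
    settings = {"design": cfg["design"], "panel": cfg["panel"], "seed": seed,
                "noise_cv": scenario.noise_cv, "p_cad": scenario.p_cad,
                "p_lys": scenario.p_lys,
                "thresholds": dict(scenario.detection_threshold)}
    _append_report(config, "simulate", counts, settings)
    return counts


def stage_multivariate(config: PipelineConfig) -> dict[str, Any]:
    matrices = _load_matrices(config)
    scaling = config["scaling"]["mode"]
    params = mv.SelectionParams(float(config["selection"]["p1_cutoff"]),
                                float(config["selection"]["pcorr_cutoff"]))
    control = config["classes"]["control_genotype"]
    case = config["classes"]["case_genotypes"]
    counts: dict[str, Any] = {}
    summary_lines = []
    for mode, matrix in sorted(matrices.items()):
        data = mv.scaled_from_matrix(matrix, scaling)
        y = _class_vector(matrix, control, case)
        model = mv.fit_oplsda_auto(data, y, folds=int(config["multivariate"]["folds"]),
                                   seed=config.seed,
                                   max_orthogonal=int(config["multivariate"]["max_orthogonal"]))
        points = mv.splot(model, data)
        case_pts, control_pts = mv.select_differential(points, params)
        rows = [{"feature_id": p.feature.render(), "p1": p.p1, "pcorr": p.pcorr,
                 "assigned_class": "case"} for p in case_pts]
        rows += [{"feature_id": p.feature.render(), "p1": p.p1, "pcorr": p.pcorr,
                  "assigned_class": "control"} for p in control_pts]
        pd.DataFrame(rows, columns=["feature_id", "p1", "pcorr", "assigned_class"]) \
            .to_csv(_out(config, f"selection_{mode}.tsv"), sep="\t", index=False)
        counts[f"input_features_{mode}"] = matrix.n_features
        counts[f"differential_case_{mode}"] = len(case_pts)
        counts[f"differential_control_{mode}"] = len(control_pts)
        for key, value in model.summary().items():
            summary_lines.append(f"{mode}\t{key}\t{value:.6g}")
    with open(_out(config, "model_summary.tsv"), "w", encoding="utf-8") as fh:
        fh.write("mode\tquantity\tvalue\n")
        fh.write("\n".join(summary_lines) + "\n")
    settings = {"scaling": scaling, "p1_cutoff": params.p1_cutoff,
                "pcorr_cutoff": params.pcorr_cutoff}
    _append_report(config, "multivariate", counts, settings)
    return counts


def stage_enrich(config: PipelineConfig) -> dict[str, Any]:
    matrices = _load_matrices(config)
    _require(config, *[f"selection_{m}.tsv" for m in matrices])
    lib_path = config["paths"]["library"]
    library = (ae.CompoundLibrary.from_tsv(lib_path) if lib_path
               else ae.CompoundLibrary.bundled())
    params = ae.AnnotationParams(float(config["annotation"]["ppm_tolerance"]))
    alpha = float(config["enrichment"]["alpha"])
    catalogue = library.pathway_catalogue()
    counts: dict[str, Any] = {}
    for mode, matrix in sorted(matrices.items()):
        sel = pd.read_csv(_out(config, f"selection_{mode}.tsv"), sep="\t")
        case_ids = [fc.FeatureID.parse(f) for f in
                    sel.loc[sel.assigned_class == "case", "feature_id"]]
        case_annotations = ae.annotate(case_ids, library, params)
        if config["enrichment"]["background"] == "library_compounds":
            background = {r.compound_id for r in library.records}
        else:
            all_annotations = ae.annotate(matrix.features, library, params)
            background = ae.annotated_compound_set(all_annotations)
        differential = ae.annotated_compound_set(case_annotations) & background
        results = ae.fisher_enrichment(differential, background, catalogue, alpha)
        ae.enrichment_table(results).to_csv(
            _out(config, f"enrichment_{mode}.tsv"), sep="\t", index=False)
        counts[f"differential_features_{mode}"] = len(case_ids)
        counts[f"annotated_differential_{mode}"] = len(case_annotations)
        counts[f"annotated_compounds_{mode}"] = len(differential)
        counts[f"significant_pathways_{mode}"] = sum(r.significant for r in results)
    settings = {"ppm_tolerance": params.ppm_tolerance, "alpha": alpha,
                "background": config["enrichment"]["background"]}
    _append_report(config, "enrich", counts, settings)
    return counts


def stage_specific(config: PipelineConfig) -> dict[str, Any]:
    matrices = _load_matrices(config)
    control = config["classes"]["control_genotype"]
    spec_cfg = config["specificity"]
    params = sf.SpecificityParams(
        spec_cfg["min_case_replicates"] and int(spec_cfg["min_case_replicates"]),
        int(spec_cfg["max_control_detections"]))
    counts: dict[str, Any] = {}
    for mode, matrix in sorted(matrices.items()):
        case = config["classes"]["case_genotypes"] or \
            [g for g in matrix.genotypes() if g != control]
        features = sf.find_specific(matrix, case, control, params)
        sf.specificity_table(matrix, features).to_csv(
            _out(config, f"specific_{mode}.tsv"), sep="\t", index=False)
        counts[f"input_features_{mode}"] = matrix.n_features
        counts[f"specific_features_{mode}"] = len(features)
    settings = {"min_case_replicates": spec_cfg["min_case_replicates"],
                "max_control_detections": spec_cfg["max_control_detections"],
                "thresholds": {m: matrices[m].thresholds[m] for m in matrices}}
    _append_report(config, "specific", counts, settings)
    return counts


def stage_trace(config: PipelineConfig) -> dict[str, Any]:
    matrices = _load_matrices(config)
    ps_cfg = config["pair_search"]
    params = it.PairSearchParams(float(ps_cfg["delta_mass"]),
                                 float(ps_cfg["ppm_tolerance"]),
                                 float(ps_cfg["rt_tolerance"]))
    cl_cfg = config["classification"]
    thresholds = it.ClassificationThresholds(
        float(cl_cfg["min_enrichment_pct"]), float(cl_cfg["asymmetry_tolerance"]),
        tuple(cl_cfg["full_band"]), tuple(cl_cfg["half_band"]))
    cadaverine_mz = sd.protonated_mz("C5H14N2")
    counts: dict[str, Any] = {}
    for mode, matrix in sorted(matrices.items()):
        treatments = {s.treatment for s in matrix.samples}
        if not {"AL", "EL", "NL"} <= treatments:
            raise StageDependencyError(
                f"matrix for mode {mode} lacks AL/EL/NL feeding treatments; "
                "the trace stage needs a tracing-design matrix")
        pairs = it.find_isotopolog_pairs(matrix, params)
        records = it.enrichment_records(matrix, pairs,
                                        correction=cl_cfg["correction"])
        it.enrichment_table(records).to_csv(
            _out(config, f"tracing_{mode}.tsv"), sep="\t", index=False)
        reference = it.find_reference_pair(pairs, cadaverine_mz)
        classifications = it.classify_all(records, reference.light, thresholds)
        it.classification_table(classifications).to_csv(
            _out(config, f"classification_{mode}.tsv"), sep="\t", index=False)
        counts[f"input_features_{mode}"] = matrix.n_features
        counts[f"isotopolog_pairs_{mode}"] = len(pairs)
        counts[f"labeled_both_treatments_{mode}"] = sum(
            c.label_class in ("both_nitrogens",
                              "one_nitrogen_via_symmetric_intermediate")
            for c in classifications)
    settings = {"delta_mass": params.delta_mass, "ppm": params.ppm_tolerance,
                "rt_tolerance": params.rt_tolerance,
                "min_enrichment_pct": thresholds.min_enrichment_pct,
                "correction": cl_cfg["correction"]}
    _append_report(config, "trace", counts, settings)
    return counts


def stage_report(config: PipelineConfig) -> dict[str, Any]:
    """Aggregate the per-stage counts into a stage-ledger table."""
    path = _require(config, "run_report.jsonl")[0]
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            entry = json.loads(line)
            for key, value in sorted(entry["counts"].items()):
                rows.append({"stage": entry["stage"], "quantity": key,
                             "value": value})
    df = pd.DataFrame(rows)
    df.to_csv(_out(config, "stage_ledger.tsv"), sep="\t", index=False)
    return {"ledger_rows": len(df)}


_STAGE_FUNCTIONS: dict[str, Callable[[PipelineConfig], dict[str, Any]]] = {
    "simulate": stage_simulate,
    "multivariate": stage_multivariate,
    "enrich": stage_enrich,
    "specific": stage_specific,
    "trace": stage_trace,
    "report": stage_report,
}


def run_stage(name: str, config: PipelineConfig) -> dict[str, Any]:
    if name not in _STAGE_FUNCTIONS:
        raise ConfigError(f"unknown stage {name!r}; expected one of {STAGES}")
    return _STAGE_FUNCTIONS[name](config)


def run_all(config: PipelineConfig, stages: tuple[str, ...] | None = None
            ) -> dict[str, dict[str, Any]]:
    """Run stages in order; the default set matches the scenario design."""
    if stages is None:
        design = config["scenario"]["design"]
        stages = (("simulate", "trace", "report") if design == "tracing"
                  else ("simulate", "multivariate", "enrich", "specific", "report"))
    return {name: run_stage(name, config) for name in stages}
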