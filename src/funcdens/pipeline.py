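"""Stage drivers tying the modules into runnable analyses.

Each stage reads plain-text inputs, writes plain-text outputs plus a JSON
manifest (config digest, input digests, seed) sufficient to re-run it
exactly.  Manifests contain no timestamps or absolute paths, so a rerun
with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classification, modeling
from .functional_density import DEFAULT_SCALE, build_density_features
from .structure_features import neighbor_feature_table
from .structures import StructureModel, distance_map, load_structure, map_variants
from .synthetic import GenerativeConfig, end_to_end_fixture
from .variants import NormalizedVariant, process_variant_table, read_variant_table

logger = logging.getLogger(__name__)

__all__ = ["run_simulate", "run_features", "run_fit", "run_classify"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_digest(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _write_manifest(out_dir: Path, stage: str, config: Mapping,
                    inputs: Mapping[str, Path], outputs: Mapping[str, Path]) -> Path:
    manifest = {
        "stage": stage,
        "config": config,
        "config_digest": _config_digest(config),
        "inputs": {k: {"file": p.name, "sha256": _digest(p)} for k, p in inputs.items()},
        "outputs": {k: {"file": p.name, "sha256": _digest(p)} for k, p in outputs.items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return path


def _load_inputs(structure_path: Path, variants_path: Path, collapse: str,
                 cell_preference, gene: str | None):
    structure = load_structure(structure_path)
    distances = distance_map(structure, collapse=collapse)
    table = read_variant_table(variants_path)
    records = table.records
    if gene:
        records = [r for r in records if r.gene == gene]
    aggregated = process_variant_table(records, cell_preference=cell_preference)
    return structure, distances, aggregated, table.predictor_columns


def _predictor_frame(variants: Sequence[NormalizedVariant], columns: Sequence[str]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(
        [(v.gene, v.seq_position, v.alt_aa) for v in variants],
        names=["gene", "seq_position", "alt_aa"],
    )
    data = {c: [v.extra.get(c, np.nan) for v in variants] for c in columns}
    df = pd.DataFrame(data, index=idx)
    return df[~df.index.duplicated()]


def run_simulate(config: GenerativeConfig, out_dir: str | Path) -> Path:
    """Generate a full synthetic bundle and its manifest."""
    out_dir = Path(out_dir)
    bundle = end_to_end_fixture(config, out_dir)
    cfg = dataclasses.asdict(config)
    return _write_manifest(
        out_dir, "simulate", cfg, inputs={},
        outputs={
            "structure": bundle.structure_path,
            "variants": bundle.variants_path,
            "truth": bundle.truth_path,
        },
    )


def run_features(
    structure_path: str | Path,
    variants_path: str | Path,
    out_dir: str | Path,
    parameters: Sequence[str] | None = None,
    gene: str | None = None,
    density_scale: float = DEFAULT_SCALE,
    collapse: str = "min_over_chains",
    cell_preference=None,
) -> Path:
    """Assemble the per-variant feature table.

    Joins, per functional parameter: external predictor columns from the
    variant table, burial features at the variant's position, and
    in-sample functional density (with the same-mutation exclusion) plus
    the weight-only density.
    """
    structure_path, variants_path = Path(structure_path), Path(variants_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, distances, aggregated, predictor_cols = _load_inputs(
        structure_path, variants_path, collapse, cell_preference, gene
    )
    params = parameters or sorted({v.parameter for v in aggregated})

    frames = []
    for param in params:
        subset = [v for v in aggregated if v.parameter == param]
        mapping = map_variants(subset, structure)
        mapped = mapping.mapped
        if not mapped:
            logger.warning("no variants of parameter %s map onto the structure", param)
            continue
        dens = build_density_features(mapped, mapped, distances, param, density_scale)
        dens = dens.rename(columns={"rho": f"rho_{param}", "weight_only": f"wdens_{param}"})
        ext = _predictor_frame(mapped, predictor_cols)
        burial = neighbor_feature_table(structure)
        pos = dens.index.get_level_values("seq_position")
        burial_rows = burial.reindex(pos).set_index(dens.index)
        y = pd.Series(
            [v.delta_function for v in mapped], index=dens.index, name="delta_function"
        )
        frame = pd.concat(
            [y, ext, burial_rows, dens[[f"rho_{param}", f"wdens_{param}"]]], axis=1
        )
        frame.insert(0, "parameter", param)
        frames.append(frame)
    if not frames:
        raise ValueError("no parameter produced a feature table")
    features = pd.concat(frames).reset_index()
    out_path = out_dir / "features.tsv"
    features.to_csv(out_path, sep="\t", index=False)

    cfg = {
        "parameters": list(params),
        "gene": gene,
        "density_scale": density_scale,
        "collapse": collapse,
    }
    return _write_manifest(
        out_dir, "features", cfg,
        inputs={"structure": structure_path, "variants": variants_path},
        outputs={"features": out_path},
    )


def run_fit(
    structure_path: str | Path,
    variants_path: str | Path,
    out_dir: str | Path,
    parameters: Sequence[str] | None = None,
    gene: str | None = None,
    density_scale: float = DEFAULT_SCALE,
    collapse: str = "min_over_chains",
    cell_preference=None,
    folds: int = 10,
    bootstrap_b: int = 1000,
    seed: int = 0,
    nested: bool = True,
) -> Path:
    """Fit relaxed-LASSO models per functional parameter, with nested CV."""
    structure_path, variants_path = Path(structure_path), Path(variants_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, distances, aggregated, predictor_cols = _load_inputs(
        structure_path, variants_path, collapse, cell_preference, gene
    )
    available = sorted({v.parameter for v in aggregated})
    params = parameters or available
    missing = [p for p in params if p not in available]
    if missing:
        raise ValueError(
            f"parameter(s) {missing} absent from the variant table (available: {available})"
        )

    burial = neighbor_feature_table(structure)
    reports: dict[str, dict] = {}
    for param in params:
        subset = [v for v in aggregated if v.parameter == param]
        mapped = map_variants(subset, structure).mapped
        dens = build_density_features(mapped, mapped, distances, param, density_scale)
        ext = _predictor_frame(mapped, predictor_cols)
        pos = dens.index.get_level_values("seq_position")
        burial_rows = burial.reindex(pos).set_index(dens.index)
        X = pd.concat([ext, burial_rows, dens[["rho", "weight_only"]]], axis=1)
        y = np.asarray([v.delta_function for v in mapped], dtype=float)

        fit = modeling.relaxed_lasso_fit(X, y, folds=folds, seed=seed)
        if not fit.intercept_only:
            ci = modeling.bootstrap_adj_r2_ci(X, y, fit, B=bootstrap_b, seed=seed)
            fit.adj_r2_ci = ci
        nested_r2 = None
        if nested:
            ext_plus_burial = pd.concat([ext, burial_rows], axis=1)
            nested_r2 = modeling.nested_cv_r2(
                mapped, distances, param, predictors=ext_plus_burial,
                outer_folds=folds, seed=seed, scale=density_scale,
                min_rows=min(30, max(folds, len(mapped) // 2)),
            )
        reports[param] = {
            "n": fit.n,
            "selected": list(fit.selected),
            "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
            "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
            "adj_r2": fit.adj_r2,
            "adj_r2_ci": list(fit.adj_r2_ci) if fit.adj_r2_ci else None,
            "cv_r2": fit.cv_r2,
            "nested_cv_r2": nested_r2,
            "lambda": fit.alpha,
            "intercept_only": fit.intercept_only,
            "accepted": (
                modeling.model_accepted(fit) if fit.adj_r2_ci is not None else False
            ),
        }

    out_path = out_dir / "model_report.json"
    with open(out_path, "w") as fh:
        json.dump(reports, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = {
        "parameters": list(params),
        "gene": gene,
        "density_scale": density_scale,
        "collapse": collapse,
        "folds": folds,
        "bootstrap_b": bootstrap_b,
        "seed": seed,
        "nested": nested,
    }
    return _write_manifest(
        out_dir, "fit", cfg,
        inputs={"structure": structure_path, "variants": variants_path},
        outputs={"model_report": out_path},
    )


def run_classify(
    structure_path: str | Path,
    variants_path: str | Path,
    out_dir: str | Path,
    gene: str | None = None,
    density_scale: float = DEFAULT_SCALE,
    collapse: str = "min_over_chains",
    cell_preference=None,
    feature_sets: Mapping[str, Sequence[str]] | None = None,
    bootstrap_b: int = 2000,
    seed: int = 0,
) -> Path:
    """Compare LOF classifiers with and without the peak-current density."""
    structure_path, variants_path = Path(structure_path), Path(variants_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, distances, aggregated, predictor_cols = _load_inputs(
        structure_path, variants_path, collapse, cell_preference, gene
    )
    labels, excluded = classification.label_variants(aggregated)
    label_s = pd.Series(
        {(l.gene, l.seq_position, l.alt_aa): l.is_lof for l in labels}, dtype=bool
    )
    label_s.index = pd.MultiIndex.from_tuples(label_s.index,
                                              names=["gene", "seq_position", "alt_aa"])

    peak = [v for v in aggregated if v.parameter == "peak_current"]
    mapped = map_variants(peak, structure).mapped
    dens = build_density_features(mapped, mapped, distances, "peak_current", density_scale)
    dens = dens.rename(columns={"rho": "rho_peak_current"})
    ext = _predictor_frame(mapped, predictor_cols)
    table = pd.concat([ext, dens[["rho_peak_current"]]], axis=1)
    table = table.loc[table.index.intersection(label_s.index)]
    y = label_s.loc[table.index]

    if feature_sets is None:
        published = [c for c in predictor_cols if c in table.columns]
        feature_sets = {
            "published": published,
            "published_plus_density": published + ["rho_peak_current"],
        }
    comparison = classification.compare_feature_sets(
        table, y, feature_sets, B=bootstrap_b, seed=seed
    )

    roc_paths = {}
    for name in feature_sets:
        roc = classification.roc_points(
            comparison.scores[name].to_numpy(), comparison.scores["is_lof"].to_numpy()
        )
        p = out_dir / f"roc_{name}.tsv"
        roc.to_csv(p, sep="\t", index=False)
        roc_paths[f"roc_{name}"] = p

    report = {
        "n_variants": comparison.n_variants,
        "n_excluded_unlabeled": len(excluded),
        "aucs": comparison.aucs,
        "auc_cis": {k: list(v) for k, v in comparison.cis.items()},
        "delong": [
            {"a": a, "b": b, "z": z, "p": p} for a, b, z, p in comparison.contrasts
        ],
    }
    out_path = out_dir / "classification_report.json"
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    cfg = {
        "gene": gene,
        "density_scale": density_scale,
        "collapse": collapse,
        "feature_sets": {k: list(v) for k, v in feature_sets.items()},
        "bootstrap_b": bootstrap_b,
        "seed": seed,
    }
    return _write_manifest(
        out_dir, "classify", cfg,
        inputs={"structure": structure_path, "variants": variants_path},
        outputs={"classification_report": out_path, **roc_paths},
    )
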