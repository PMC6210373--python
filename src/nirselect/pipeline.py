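"""End-to-end orchestration: smooth -> clean -> PCA -> split -> GA -> SVM -> metrics.

A run is fully described by a :class:`RunConfig`; one global seed fans out
to per-stage seeds through ``numpy.random.SeedSequence`` so stages are
independently reproducible.  Artifacts are written as plain CSV/JSON:
a per-k accuracy table (GA-selected subset vs the first-k components,
each with its explained-information share), the mask matrix, per-class
metrics at the reporting k, GA traces and a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import SpectraSet, read_spectra
from .decomposition import SpectralPCA, explained_information
from .evaluation import confusion, grid_search_params, metrics, split_train_test
from .ga import GAConfig, run_ga
from .preprocessing import remove_outliers, sg_smooth
from .svm import SVMParams, TreeSVM
from .synthetic import generate, preset

__all__ = ["RunConfig", "run_full", "sweep_ga_hyperparams"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one full run."""

    # input: a spectra CSV/TSV, or a synthetic preset if no path given
    input_path: str | None = None
    synthetic_preset: str = "tobacco-like"
    synthetic_overrides: dict = field(default_factory=dict)
    # preprocessing
    sg_window: int = 121
    sg_poly_order: int = 2
    outlier_space: str = "pc"
    outlier_q: float = 0.999
    # feature extraction
    pca_components: int = 25
    subset_sizes: tuple = (6, 8, 10, 12, 14, 16)
    # SVM
    C: float = 2.0
    sigma: float = 2.0
    grid_search: bool = False
    split_policy: str = "centroid"
    # GA
    pop_size: int = 200
    max_generations: int = 100
    p_crossover: float = 0.6
    p_mutation: float = 0.01
    elitism_count: int = 1
    stagnation_generations: int = 20
    cv_folds: int = 5
    # evaluation
    train_fraction: float = 0.8
    metrics_k: int | None = None
    # bookkeeping
    seed: int = 0
    output_dir: str = "nirselect-run"

    def __post_init__(self) -> None:
        if any(k > self.pca_components for k in self.subset_sizes):
            raise ValueError(
                f"subset sizes {self.subset_sizes} must not exceed "
                f"pca_components={self.pca_components}"
            )
        if self.metrics_k is not None and self.metrics_k not in self.subset_sizes:
            raise ValueError("metrics_k must be one of subset_sizes")


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds below 2^31 from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _load_input(cfg: RunConfig, synth_seed: int) -> SpectraSet:
    if cfg.input_path is not None:
        return read_spectra(cfg.input_path)
    syn_cfg = preset(cfg.synthetic_preset, seed=synth_seed, **cfg.synthetic_overrides)
    ds, _ = generate(syn_cfg)
    return ds


def run_full(cfg: RunConfig, write: bool = True) -> dict:
    """Execute the whole workflow; returns (and optionally writes) the report.

    For every subset size k the report carries the GA-selected mask with
    its test accuracy and explained-information share, alongside the
    first-k-components baseline.  Per-class metrics are computed at
    `metrics_k` (default: the k with the best GA test accuracy).
    """
    names = ["synth", "split", "cv", "grid"] + [f"ga_k{k}" for k in cfg.subset_sizes]
    seeds = _stage_seeds(cfg.seed, names)

    ds = _load_input(cfg, seeds["synth"])
    logger.info("input: %d samples x %d points", ds.n_samples, ds.n_points)
    ds = sg_smooth(ds, window=cfg.sg_window, poly_order=cfg.sg_poly_order)
    ds, outlier_report = remove_outliers(
        ds, space=cfg.outlier_space, q=cfg.outlier_q,
        n_components=min(cfg.pca_components, ds.n_samples - 1),
    )
    logger.info("outliers removed: %d", outlier_report.flagged.size)

    pca = SpectralPCA(n_components=cfg.pca_components).fit(ds.absorbance)
    scores = pca.transform(ds.absorbance)
    logger.info(
        "top-%d PCs keep %.4f of total variance",
        cfg.pca_components, float(pca.explained_ratio_.sum()),
    )

    train_idx, test_idx = split_train_test(
        ds.labels, train_fraction=cfg.train_fraction, stratified=True,
        seed=seeds["split"],
    )
    X_train, y_train = scores[train_idx], ds.labels[train_idx]
    X_test, y_test = scores[test_idx], ds.labels[test_idx]

    if cfg.grid_search:
        kmax = max(cfg.subset_sizes)
        params, grid_table = grid_search_params(
            X_train[:, :kmax], y_train, folds=cfg.cv_folds, seed=seeds["grid"],
            split_policy=cfg.split_policy,
        )
        logger.info("grid search chose C=%g sigma=%g", params.C, params.sigma)
    else:
        params, grid_table = SVMParams(cfg.C, cfg.sigma), None

    rows, masks, traces, trees = [], {}, {}, {}
    for k in cfg.subset_sizes:
        ga_cfg = GAConfig(
            k=k, pop_size=cfg.pop_size, max_generations=cfg.max_generations,
            p_crossover=cfg.p_crossover, p_mutation=cfg.p_mutation,
            elitism_count=cfg.elitism_count,
            stagnation_generations=cfg.stagnation_generations,
            cv_folds=cfg.cv_folds, seed=seeds[f"ga_k{k}"],
        )
        mask, trace = run_ga(X_train, y_train, params, ga_cfg,
                             split_policy=cfg.split_policy)
        bmask = mask.astype(bool)
        ga_tree = TreeSVM(C=params.C, sigma=params.sigma,
                          split_policy=cfg.split_policy).fit(X_train[:, bmask], y_train)
        ga_acc = float(np.mean(ga_tree.predict(X_test[:, bmask]) == y_test))

        first_mask = np.zeros(cfg.pca_components, dtype=bool)
        first_mask[:k] = True
        sv_tree = TreeSVM(C=params.C, sigma=params.sigma,
                          split_policy=cfg.split_policy).fit(
            X_train[:, first_mask], y_train)
        sv_acc = float(np.mean(sv_tree.predict(X_test[:, first_mask]) == y_test))

        rows.append(
            {
                "k": k,
                "ga_accuracy": ga_acc,
                "ga_information": explained_information(pca, bmask),
                "svm_accuracy": sv_acc,
                "svm_information": explained_information(pca, first_mask),
            }
        )
        masks[k] = mask
        traces[k] = trace
        trees[k] = (ga_tree, bmask, sv_tree, first_mask)
        logger.info("k=%d: GA-SVM %.3f vs first-k SVM %.3f (GA generations: %d)",
                    k, ga_acc, sv_acc, trace.n_generations)

    accuracy_by_k = pd.DataFrame(rows)
    best_row = accuracy_by_k.sort_values(
        ["ga_accuracy", "k"], ascending=[False, True]).iloc[0]
    metrics_k = int(best_row["k"]) if cfg.metrics_k is None else cfg.metrics_k

    ga_tree, bmask, sv_tree, first_mask = trees[metrics_k]
    per_class = []
    for model_name, tree, m in (
        ("GA-SVM", ga_tree, bmask), ("SVM", sv_tree, first_mask)
    ):
        rep = metrics(confusion(y_test, tree.predict(X_test[:, m]),
                                labels=np.unique(ds.labels)))
        frame = rep.to_frame()
        frame.insert(0, "model", model_name)
        frame["accuracy"] = rep.accuracy
        per_class.append(frame)
    metrics_table = pd.concat(per_class, ignore_index=True)

    mask_matrix = pd.DataFrame(
        {f"k{k}": masks[k] for k in cfg.subset_sizes},
        index=pd.Index(np.arange(1, cfg.pca_components + 1), name="pc"),
    )

    report = {
        "config": asdict(cfg),
        "seeds": seeds,
        "n_samples_in": int(outlier_report.distances.size),
        "n_outliers_removed": int(outlier_report.flagged.size),
        "n_train": int(train_idx.size),
        "n_test": int(test_idx.size),
        "params": {"C": params.C, "sigma": params.sigma},
        "explained_by_candidates": float(pca.explained_ratio_.sum()),
        "accuracy_by_k": accuracy_by_k,
        "mask_matrix": mask_matrix,
        "metrics_k": metrics_k,
        "metrics": metrics_table,
        "traces": traces,
        "grid_table": grid_table,
    }
    if write:
        _write_report(cfg, report, outlier_report)
    return report


def _write_report(cfg: RunConfig, report: dict, outlier_report) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report["accuracy_by_k"].to_csv(out / "accuracy_by_k.csv", index=False)
    report["mask_matrix"].to_csv(out / "masks.csv")
    report["metrics"].to_csv(out / "metrics.csv", index=False)
    for k, trace in report["traces"].items():
        trace.to_frame().to_csv(out / f"trace_k{k}.csv", index=False)
    pd.DataFrame(
        {"distance": outlier_report.distances,
         "flagged": np.isin(np.arange(outlier_report.distances.size),
                            outlier_report.flagged).astype(int)}
    ).to_csv(out / "outliers.csv", index_label="sample")
    if report["grid_table"] is not None:
        report["grid_table"].to_csv(out / "grid_search.csv", index=False)

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "nirselect_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seeds": report["seeds"],
        "params": report["params"],
        "metrics_k": report["metrics_k"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


_SWEEP_AXES = {"population": "pop_size", "crossover": "p_crossover",
               "mutation": "p_mutation"}


def sweep_ga_hyperparams(
    cfg: RunConfig, axis: str, values, n_seeds: int = 1
) -> pd.DataFrame:
    """Best-fitness traces of the GA while varying one hyperparameter.

    `axis` is 'population', 'crossover' or 'mutation'; for each value the
    GA is run `n_seeds` times (seeded) at ``k = min(subset_sizes)`` on the
    training split and the per-generation best/mean fitness recorded.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"axis must be one of {sorted(_SWEEP_AXES)}, got {axis!r}")
    names = ["synth", "split"] + [f"sweep{i}" for i in range(len(values) * n_seeds)]
    seeds = _stage_seeds(cfg.seed, names)

    ds = _load_input(cfg, seeds["synth"])
    ds = sg_smooth(ds, window=cfg.sg_window, poly_order=cfg.sg_poly_order)
    ds, _ = remove_outliers(ds, space=cfg.outlier_space, q=cfg.outlier_q,
                            n_components=min(cfg.pca_components, ds.n_samples - 1))
    pca = SpectralPCA(n_components=cfg.pca_components).fit(ds.absorbance)
    scores = pca.transform(ds.absorbance)
    train_idx, _ = split_train_test(ds.labels, cfg.train_fraction, True,
                                    seed=seeds["split"])
    X_train, y_train = scores[train_idx], ds.labels[train_idx]
    params = SVMParams(cfg.C, cfg.sigma)
    k = min(cfg.subset_sizes)

    frames = []
    i = 0
    for value in values:
        for s in range(n_seeds):
            kwargs = dict(
                k=k, pop_size=cfg.pop_size, max_generations=cfg.max_generations,
                p_crossover=cfg.p_crossover, p_mutation=cfg.p_mutation,
                elitism_count=cfg.elitism_count,
                stagnation_generations=cfg.stagnation_generations,
                cv_folds=cfg.cv_folds, seed=seeds[f"sweep{i}"],
            )
            kwargs[_SWEEP_AXES[axis]] = value
            _, trace = run_ga(X_train, y_train, params, GAConfig(**kwargs),
                              split_policy=cfg.split_policy)
            frame = trace.to_frame()[["generation", "best_fitness", "mean_fitness"]]
            frame.insert(0, "seed_index", s)
            frame.insert(0, "value", value)
            frame.insert(0, "axis", axis)
            frames.append(frame)
            i += 1
    return pd.concat(frames, ignore_index=True)
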