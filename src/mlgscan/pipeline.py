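"""End-to-end orchestration: stats -> features -> scores -> calls.

The pipeline is a pure function of (input genotypes, configuration,
seeds): every stage writes a self-describing TSV into the run directory
and can be re-loaded, and reruns with the same configuration and seed
produce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import calibration, detectors, features, sumstats
from .calibration import OutlierCallSet, PValueTable
from .features import FDA, MOMENTS, FeatureMatrix
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: feature-set suffix -> feature method name
_FEATURE_OF_SUFFIX = {"M": MOMENTS, "F": FDA}


@dataclass
class RunConfig:
    """Tunable parameters of a scan; defaults follow the reference setup.

    ``window_size`` (l) and ``stretch_size`` (w) must be odd so windows
    and stretches have unique center anchors.
    """

    window_size: int = 51
    stretch_size: int = 129
    n_basis: int = 10
    methods: tuple[str, ...] = ("MD-M", "MD-F", "IF-M", "IF-F")
    alpha: float = calibration.DEFAULT_ALPHA
    seed: int = 0
    m_batches: int = 18
    n_perm: int = 10_000
    standardize: bool = False  # optional z-scaling before IF/SVM

    def __post_init__(self) -> None:
        if self.window_size % 2 == 0 or self.stretch_size % 2 == 0:
            raise ValueError("window_size and stretch_size must be odd")
        if not self.methods:
            raise ValueError("at least one method must be configured")
        bad = set(self.methods) - set(detectors.METHODS)
        if bad:
            raise ValueError(f"unknown methods {sorted(bad)}; valid: {detectors.METHODS}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def feature_sets_needed(config: RunConfig) -> set[str]:
    return {_FEATURE_OF_SUFFIX[m.split("-")[1]] for m in config.methods}


def compute_feature_matrices(
    genomes: list[GenotypeMatrix], config: RunConfig
) -> dict[str, FeatureMatrix]:
    """Summary statistics and genome-wide feature matrices per feature set."""
    needed = feature_sets_needed(config)
    basis = (
        features.build_basis(config.stretch_size, config.n_basis)
        if FDA in needed
        else None
    )
    per_set: dict[str, list[FeatureMatrix]] = {name: [] for name in needed}
    for gm in genomes:
        sm = sumstats.compute_stat_matrix(gm, config.window_size)
        if MOMENTS in needed:
            per_set[MOMENTS].append(
                features.moment_feature_matrix(sm, config.stretch_size)
            )
        if FDA in needed:
            per_set[FDA].append(features.fda_feature_matrix(sm, basis))
    return {name: features.assemble_features(parts) for name, parts in per_set.items()}


def score_method(
    fm: FeatureMatrix, method: str, config: RunConfig
) -> PValueTable:
    """Raw scores and calibrated p-values for one of the six methods."""
    detector = method.split("-")[0]
    X = fm.X
    if config.standardize and detector in (detectors.IF, detectors.SVM):
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if detector == detectors.MD:
        table = calibration.score_features(fm, method=method)
    elif detector == detectors.IF:
        raw = detectors.isolation_forest_scores(X, seed=config.seed)
        table = calibration.score_features(fm, detector_scores=raw, method=method)
    elif detector == detectors.SVM:
        plan = detectors.plan_minibatches(fm.n_observations, config.m_batches)
        raw = detectors.ocsvm_scores(X, plan)
        table = calibration.score_features(fm, detector_scores=raw, method=method)
    else:
        raise ValueError(f"unknown detector in method {method!r}")
    logger.info("method %s: lambda = %.4f", method, table.lam)
    return table


@dataclass
class PipelineResult:
    config: RunConfig
    feature_matrices: dict[str, FeatureMatrix]
    tables: dict[str, PValueTable]
    calls: dict[str, OutlierCallSet]


def run_pipeline(
    genomes: list[GenotypeMatrix],
    config: RunConfig,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run stats -> features -> scores -> calibration -> calls.

    When ``outdir`` is given, each stage's TSV artifacts are written
    there (summary stats per chromosome, feature matrices, p-value
    tables, outlier calls, Manhattan tables).
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for gm in genomes:
            sm = sumstats.compute_stat_matrix(gm, config.window_size)
            sumstats.write_stats_tsv(sm, out / f"stats_{gm.chrom}.tsv")
    fms = compute_feature_matrices(genomes, config)
    expected_n = sum(
        gm.n_snps - config.window_size - config.stretch_size + 2 for gm in genomes
    )
    for name, fm in fms.items():
        if fm.n_observations != expected_n:
            raise RuntimeError(
                f"bookkeeping error: {name} has {fm.n_observations} rows, "
                f"expected {expected_n}"
            )
        if out is not None:
            features.write_features_tsv(fm, out / f"features_{name}.tsv")
    tables: dict[str, PValueTable] = {}
    calls: dict[str, OutlierCallSet] = {}
    for method in config.methods:
        fm = fms[_FEATURE_OF_SUFFIX[method.split("-")[1]]]
        table = score_method(fm, method, config)
        tables[method] = table
        calls[method] = calibration.call_outliers(table, config.alpha)
        if out is not None:
            calibration.write_pvalue_tsv(table, out / f"pvalues_{method}.tsv")
            from .images import manhattan_table, write_manhattan_tsv

            write_manhattan_tsv(
                manhattan_table(table), out / f"manhattan_{method}.tsv"
            )
    if out is not None:
        with open(out / "calls.tsv", "w") as fh:
            fh.write("method\tlambda\tn_total\tn_outliers\tn_peaks\talpha\n")
            for method, cs in calls.items():
                fh.write(
                    f"{method}\t{tables[method].lam:.6g}\t{cs.n_total}\t"
                    f"{cs.n_outliers}\t{cs.n_peaks}\t{cs.alpha:g}\n"
                )
    return PipelineResult(
        config=config, feature_matrices=fms, tables=tables, calls=calls
    )
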