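"""Configuration-driven orchestration of the full analysis layout.

These functions reproduce the study's analysis tables on synthetic (or
user-supplied) data: per-arm evaluation of the three feature-set models
(baseline / 1-week change / longitudinally joint), optional permutation
significance, cross-drug transferability, and top-10 feature-contribution
rankings. Each is a thin layer over the library modules; the CLI and the
numbered analysis drivers call these.

Every report file embeds the resolved configuration and seeds as ``#``
comment lines (provenance contract), and contains no timestamps, so
identical configs yield byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .contribution import fold_averaged_contributions, top_k
from .errors import ConfigError
from .evaluation import cross_validate, permutation_test, transferability
from .features import (
    FeatureTable,
    compute_change_features,
    concatenate_joint,
    read_feature_table,
    write_feature_table,
)
from .model import TwoStageConfig
from .outcomes import (
    ARMS,
    apply_cohort_flow,
    format_flow_table,
    label_responders,
    read_subject_records,
    write_subject_records,
)
from .schema import build_default_schema
from .simulate import (
    SyntheticCohort,
    SyntheticCohortSpec,
    default_effect_features,
    simulate_cohort,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "run_simulate",
    "run_evaluate",
    "run_transfer",
    "run_contributions",
    "load_cohort_tables",
    "FEATURE_SETS",
]

FEATURE_SETS = ("baseline", "change", "joint")


@dataclass
class RunConfig:
    """Resolved run configuration: one data source, model and evaluation params."""

    output_dir: Path
    subjects_path: Optional[Path] = None
    baseline_path: Optional[Path] = None
    week1_path: Optional[Path] = None
    synthetic: Optional[SyntheticCohortSpec] = None
    feature_sets: tuple[str, ...] = FEATURE_SETS
    arms: tuple[str, ...] = ARMS
    model: TwoStageConfig = field(default_factory=TwoStageConfig)
    k_folds: int = 10
    n_permutations: int = 0
    eval_seed: int = 0
    delimiter: str = ","
    contribution_method: str = "connection_weight"
    top_k: int = 10

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        has_files = self.baseline_path is not None
        if has_files == (self.synthetic is not None):
            raise ConfigError(
                "exactly one data source required: feature files or a synthetic spec"
            )
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ConfigError(f"unknown feature sets {sorted(unknown)}")

    def resolved_dict(self) -> dict:
        d = {
            "output_dir": str(self.output_dir),
            "feature_sets": list(self.feature_sets),
            "arms": list(self.arms),
            "model": self.model.to_dict(),
            "k_folds": self.k_folds,
            "n_permutations": self.n_permutations,
            "eval_seed": self.eval_seed,
            "contribution_method": self.contribution_method,
            "top_k": self.top_k,
        }
        if self.synthetic is not None:
            spec = self.synthetic
            d["synthetic"] = {
                "n_per_arm": list(spec.arm_sizes.values()),
                "responder_proportion": spec.responder_proportion,
                "baseline_week1_correlation": spec.baseline_week1_correlation,
                "n_excluded_baseline": spec.n_excluded_baseline,
                "n_lost": list(spec.n_lost),
                "seed": spec.seed,
            }
        else:
            d["files"] = {
                "subjects": str(self.subjects_path),
                "baseline": str(self.baseline_path),
                "week1": str(self.week1_path),
            }
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_run_config(path, **overrides) -> RunConfig:
    """Load a YAML run-config document; keyword overrides win."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if doc.get("config_version", 1) != 1:
        raise ConfigError(f"unsupported config_version {doc.get('config_version')}")
    kwargs: dict = {"output_dir": doc.get("output_dir", "results")}
    if "model" in doc:
        kwargs["model"] = TwoStageConfig.from_dict(
            {**TwoStageConfig().to_dict(), **doc["model"]}
        )
    if "synthetic" in doc:
        syn = dict(doc["synthetic"])
        if isinstance(syn.get("n_per_arm"), list):
            syn["n_per_arm"] = tuple(syn["n_per_arm"])
        if "n_lost" in syn:
            syn["n_lost"] = tuple(syn["n_lost"])
        if "effect_size" in syn:
            size = syn.pop("effect_size")
            effects = default_effect_features()
            syn["baseline_effects"] = {
                a: [(i, size) for i in idx] for a, idx in effects.items()
            }
            syn["change_effects"] = {
                a: [(i, size) for i in idx] for a, idx in effects.items()
            }
        kwargs["synthetic"] = SyntheticCohortSpec(**syn)
    if "files" in doc:
        kwargs["subjects_path"] = Path(doc["files"]["subjects"])
        kwargs["baseline_path"] = Path(doc["files"]["baseline"])
        kwargs["week1_path"] = Path(doc["files"]["week1"])
    for key in (
        "feature_sets",
        "arms",
        "k_folds",
        "n_permutations",
        "eval_seed",
        "delimiter",
        "contribution_method",
        "top_k",
    ):
        if key in doc:
            value = doc[key]
            kwargs[key] = tuple(value) if isinstance(value, list) else value
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def _provenance_lines(config: RunConfig) -> list[str]:
    return [
        f"# config_hash: {config.config_hash()}",
        f"# resolved_config: {json.dumps(config.resolved_dict(), sort_keys=True)}",
    ]


def _write_with_header(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in _provenance_lines(config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def _cohort_to_tables(cohort: SyntheticCohort):
    labels = cohort.labels()
    arms = cohort.arm_of()
    return cohort.baseline, cohort.week1, labels, arms


def load_cohort_tables(config: RunConfig):
    """Materialize (baseline, week1, labels, arm) from the configured source."""
    schema = build_default_schema()
    if config.synthetic is not None:
        return _cohort_to_tables(simulate_cohort(config.synthetic, schema))
    records = read_subject_records(config.subjects_path, config.delimiter)
    analyzed, _ = apply_cohort_flow(records)
    baseline = read_feature_table(config.baseline_path, schema, "baseline", config.delimiter)
    week1 = read_feature_table(config.week1_path, schema, "week1", config.delimiter)
    by_id = {lab.subject_id: lab.responder for lab in label_responders(analyzed)}
    arm_by_id = {r.subject_id: r.arm for r in analyzed}
    labels = np.array([by_id[s] for s in baseline.subject_ids], dtype=int)
    arms = np.array([arm_by_id[s] for s in baseline.subject_ids])
    return baseline, week1, labels, arms


def _feature_set_table(name: str, baseline: FeatureTable, week1: FeatureTable) -> FeatureTable:
    if name == "baseline":
        return baseline
    if name == "change":
        return compute_change_features(baseline, week1)
    return concatenate_joint(baseline, week1)


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Draw the configured synthetic cohort and write its files."""
    if config.synthetic is None:
        raise ConfigError("run_simulate needs a synthetic spec")
    schema = build_default_schema()
    cohort = simulate_cohort(config.synthetic, schema)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.csv",
        "baseline": out / "features_baseline.csv",
        "week1": out / "features_week1.csv",
        "truth": out / "truth.csv",
        "flow": out / "cohort_flow.txt",
    }
    write_subject_records(cohort.records, paths["subjects"], config.delimiter)
    write_feature_table(cohort.baseline, paths["baseline"], config.delimiter)
    write_feature_table(cohort.week1, paths["week1"], config.delimiter)
    truth_df = pd.DataFrame(
        {
            "subject_id": list(cohort.truth.keys()),
            "latent_responder": [int(v) for v in cohort.truth.values()],
        }
    )
    _write_with_header(truth_df, paths["truth"], config)
    _, counts = apply_cohort_flow(cohort.records)
    paths["flow"].write_text(
        "\n".join(_provenance_lines(config)) + "\n" + format_flow_table(counts) + "\n",
        encoding="utf-8",
    )
    return paths


def run_evaluate(config: RunConfig) -> pd.DataFrame:
    """Cross-validate the configured feature-set models per arm (Table-2 style)."""
    baseline, week1, labels, arms = load_cohort_tables(config)
    rows = []
    for arm in config.arms:
        mask = arms == arm
        idx = np.nonzero(mask)[0]
        for fset in config.feature_sets:
            table = _feature_set_table(fset, baseline, week1).select(idx)
            report = cross_validate(
                table, labels[idx], config.model, k=config.k_folds, seed=config.eval_seed
            )
            row = {"arm": arm, "feature_set": fset, **report.as_dict()}
            if config.n_permutations > 0:
                perm = permutation_test(
                    table,
                    labels[idx],
                    config.model,
                    n_permutations=config.n_permutations,
                    k=config.k_folds,
                    seed=config.eval_seed,
                    observed=report,
                )
                row["p_value"] = perm.p_value
            rows.append(row)
    df = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    _write_with_header(df, config.output_dir / "model_performance.csv", config)
    (config.output_dir / "model_performance.txt").write_text(
        "\n".join(_provenance_lines(config))
        + "\n"
        + _format_performance_table(df)
        + "\n",
        encoding="utf-8",
    )
    return df


def run_transfer(config: RunConfig) -> pd.DataFrame:
    """Train on each whole arm, evaluate on the other, per feature set."""
    baseline, week1, labels, arms = load_cohort_tables(config)
    if len(config.arms) < 2:
        raise ConfigError("transferability needs both arms")
    rows = []
    for source in config.arms:
        for target in config.arms:
            if source == target:
                continue
            si = np.nonzero(arms == source)[0]
            ti = np.nonzero(arms == target)[0]
            for fset in config.feature_sets:
                table = _feature_set_table(fset, baseline, week1)
                report = transferability(
                    table.select(si), labels[si], table.select(ti), labels[ti], config.model
                )
                rows.append(
                    {
                        "source_arm": source,
                        "target_arm": target,
                        "feature_set": fset,
                        **report.as_dict(),
                    }
                )
    df = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    _write_with_header(df, config.output_dir / "transferability.csv", config)
    return df


def run_contributions(config: RunConfig) -> pd.DataFrame:
    """Fold-averaged top-k contribution rankings per arm per feature set."""
    baseline, week1, labels, arms = load_cohort_tables(config)
    rows = []
    for arm in config.arms:
        idx = np.nonzero(arms == arm)[0]
        for fset in config.feature_sets:
            table = _feature_set_table(fset, baseline, week1).select(idx)
            ranking = fold_averaged_contributions(
                table,
                labels[idx],
                config.model,
                method=config.contribution_method,
                k=config.k_folds,
                seed=config.eval_seed,
            )
            for rank, (name, score) in enumerate(top_k(ranking, config.top_k), start=1):
                rows.append(
                    {
                        "arm": arm,
                        "feature_set": fset,
                        "rank": rank,
                        "feature": name,
                        "score": score,
                        "method": ranking.method,
                    }
                )
    df = pd.DataFrame(rows)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    _write_with_header(df, config.output_dir / "contributions.csv", config)
    return df


def _format_performance_table(df: pd.DataFrame) -> str:
    """Render a Table-2-style plain-text performance table (percentages)."""
    lines = ["Model performance (pooled held-out predictions)", ""]
    header = f"{'arm':<12} {'feature set':<12} {'BAC':>6} {'SEN':>6} {'SPE':>6} {'AUC':>6}"
    if "p_value" in df.columns:
        header += f" {'p':>8}"
    lines.append(header)
    lines.append("-" * len(header))
    for _, row in df.iterrows():
        line = (
            f"{row['arm']:<12} {row['feature_set']:<12} "
            f"{100 * row['balanced_accuracy']:>5.1f}% "
            f"{100 * row['sensitivity']:>5.1f}% "
            f"{100 * row['specificity']:>5.1f}% "
            f"{row['auc']:>6.3f}"
        )
        if "p_value" in df.columns:
            line += f" {row['p_value']:>8.4f}"
        lines.append(line)
    return "\n".join(lines)
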