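"""End-to-end orchestration: simulate/ingest -> preprocess -> PCA -> LDA
-> marker discovery -> diagnosis -> report.

All randomness flows from one top-level seed: the simulation uses it
directly and the train/test split draws from a named substream, so a rerun
with the same config reproduces every intermediate byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import (
    DEFAULT_FEATURE_RANGE,
    DEFAULT_PCA_RANK,
    accuracy,
    lda_fit,
    lda_score,
    pca_fit,
    pca_project,
    split_set,
)
from .io import read_spectra, write_spectra
from .markers import MarkerConfig, diagnose, discover_markers
from .simulate import SimDesign, study_design, simulate_set
from .spectra import SpectrumSet, preprocess_set

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Settings for one full analysis run (published defaults)."""

    seed: int = 0
    design: SimDesign | None = None  # simulate when set ...
    input_path: str | None = None  # ... else read spectra from file
    ratio: float = 0.6
    grouping: str = "none"
    pca_components: int = 10
    pca_rank: int = DEFAULT_PCA_RANK
    feature_range: tuple[float, float] = DEFAULT_FEATURE_RANGE
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    outdir: str | None = None  # persist intermediates when set

    def __post_init__(self) -> None:
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if self.design is None and self.input_path is None:
            self.design = study_design()


@dataclass
class RunReport:
    """Everything the run computed, recomputable from the persisted CSVs."""

    class_counts: dict
    train_size: int
    test_size: int
    explained_variance_ratio: list[float]
    train_confusion: dict
    test_confusion: dict
    train_accuracy: float
    test_accuracy: float
    marker_table: pd.DataFrame
    skipped_targets: list
    diagnosis_counts: dict
    seed: int
    config: dict
    version: str = __version__


def _confusion(scored: pd.DataFrame) -> dict:
    out = {}
    for true in ("control", "heat"):
        for pred in ("control", "heat"):
            out[f"{true}_as_{pred}"] = int(
                ((scored["class_label"] == true) & (scored["predicted_label"] == pred)).sum()
            )
    return out


def _split_seed(seed: int) -> int:
    # named substream so simulation and split draws never collide
    return int(np.random.SeedSequence([seed, 0x5917]).generate_state(1)[0] % 2**31)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in fixed order; persist intermediates if outdir set."""
    outdir = config.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.design is not None:
        design = dataclasses.replace(config.design, seed=config.seed)
        raw: SpectrumSet = stage("simulate", simulate_set, design)
    else:
        raw = stage("read", read_spectra, config.input_path)
    log.info("input: %d spectra, classes %s", len(raw), raw.class_counts)

    pre = stage("preprocess", preprocess_set, raw)
    if outdir:
        write_spectra(pre, os.path.join(outdir, "preprocessed.csv"), "csv-wide")

    pca = stage("pca", pca_fit, pre, config.pca_components)
    scores = pca_project(pca, pre)
    if outdir:
        pd.DataFrame(
            {"component": np.arange(1, len(pca.explained_variance_ratio) + 1),
             "explained_variance_ratio": pca.explained_variance_ratio}
        ).to_csv(os.path.join(outdir, "pca_explained_variance.csv"), index=False)
        score_df = pd.DataFrame(
            scores, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        )
        score_df.insert(0, "spectrum_id", pre.meta["spectrum_id"].to_numpy())
        score_df.insert(1, "class_label", pre.meta["class_label"].to_numpy())
        score_df.to_csv(os.path.join(outdir, "pca_scores.csv"), index=False)

    split = stage("split", split_set, pre, config.ratio, _split_seed(config.seed), config.grouping)
    lda = stage("lda", lda_fit, pre, split, config.pca_rank, config.feature_range)
    train = pre.select_ids(split.train_ids)
    test = pre.select_ids(split.test_ids)
    train_scored = lda_score(lda, train)
    test_scored = lda_score(lda, test)
    if outdir:
        pd.DataFrame({"spectrum_id": split.train_ids, "role": "train"}).to_csv(
            os.path.join(outdir, "split_train.csv"), index=False
        )
        pd.DataFrame({"spectrum_id": split.test_ids, "role": "test"}).to_csv(
            os.path.join(outdir, "split_test.csv"), index=False
        )
        pd.DataFrame(
            {"wavenumber_cm1": lda.wavenumbers, "ld1_loading": lda.ld1_loadings}
        ).to_csv(os.path.join(outdir, "lda_loadings.csv"), index=False)
        pd.concat(
            [train_scored.assign(role="train"), test_scored.assign(role="test")],
            ignore_index=True,
        ).to_csv(os.path.join(outdir, "lda_scores.csv"), index=False)

    discovery = stage("markers", discover_markers, pre, lda, config.markers)
    marker_table = discovery.table()
    if outdir:
        marker_table.to_csv(os.path.join(outdir, "markers.csv"), index=False)

    if discovery.evaluations:
        verdicts = stage("diagnose", diagnose, pre, discovery.evaluations)
        diagnosis_counts = verdicts["verdict"].value_counts().to_dict()
        if outdir:
            verdicts.to_csv(os.path.join(outdir, "verdicts.csv"), index=False)
    else:
        diagnosis_counts = {}

    config_echo = {
        "seed": config.seed,
        "ratio": config.ratio,
        "grouping": config.grouping,
        "pca_components": config.pca_components,
        "pca_rank": config.pca_rank,
        "feature_range": list(config.feature_range),
        "loading_threshold": config.markers.loading_threshold,
        "max_distance": config.markers.max_distance,
        "p_threshold": config.markers.p_threshold,
        "input": config.input_path or "simulated",
    }
    report = RunReport(
        class_counts=pre.class_counts,
        train_size=len(split.train_ids),
        test_size=len(split.test_ids),
        explained_variance_ratio=[float(v) for v in pca.explained_variance_ratio],
        train_confusion=_confusion(train_scored),
        test_confusion=_confusion(test_scored),
        train_accuracy=accuracy(train_scored),
        test_accuracy=accuracy(test_scored),
        marker_table=marker_table,
        skipped_targets=list(discovery.skipped),
        diagnosis_counts={str(k): int(v) for k, v in diagnosis_counts.items()},
        seed=config.seed,
        config=config_echo,
    )
    if outdir:
        render_report(report, os.path.join(outdir, "report.md"))
    return report


def render_report(report: RunReport, path: str, format: str = "markdown") -> str:
    """Write a human-readable run summary (markdown or CSV bundle stub)."""
    if format == "csv-bundle":
        report.marker_table.to_csv(path, index=False)
        return path
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    lines = [
        "# FTIR heat-stress analysis report",
        "",
        f"- version: {report.version}, seed: {report.seed}",
        f"- config: `{json.dumps(report.config)}`",
        f"- spectra per class: {report.class_counts}",
        f"- split: {report.train_size} train / {report.test_size} test",
        "",
        "## PCA explained variance",
        "",
        "| component | ratio |",
        "|---|---|",
    ]
    for i, v in enumerate(report.explained_variance_ratio, start=1):
        lines.append(f"| PC{i} | {v:.4f} |")
    lines += [
        "",
        "## LDA classification",
        "",
        f"- training accuracy: {report.train_accuracy:.3f} ({report.train_confusion})",
        f"- test accuracy: {report.test_accuracy:.3f} ({report.test_confusion})",
        "",
        "## Fm markers",
        "",
    ]
    table = report.marker_table
    if table.empty:
        lines.append("no markers")
    else:
        lines.append(
            "| Marker Name | Target | Anchor-1 | Anchor-2 | Loading | Median C | Median H | Ratio | p |"
        )
        lines.append("|---|---|---|---|---|---|---|---|---|")
        for _, r in table.iterrows():
            lines.append(
                f"| {r['name']} | {r.target:.0f} | {r.anchor1:.0f} | {r.anchor2:.0f} "
                f"| {r.loading:.3f} | {r.median_C:.3f} | {r.median_H:.3f} "
                f"| {r.ratio:.3f} | {r.p:.3g} |"
            )
    if report.skipped_targets:
        lines += ["", "skipped targets: " + ", ".join(f"{nu:g}" for nu, _ in report.skipped_targets)]
    if report.diagnosis_counts:
        lines += ["", f"diagnosis verdicts: {report.diagnosis_counts}"]
    lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
    return path
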