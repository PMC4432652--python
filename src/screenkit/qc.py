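"""Replicate-sample quality control for pooled screens.

Two metrics decide whether a replicate survives:

* replicate reproducibility — Pearson correlation with same-line siblings,
  against a threshold that is either fixed (the historical constant
  0.6795) or derived as the 75th percentile of all non-replicate pair
  correlations;
* overall distribution — the 75th percentile of the replicate's logged
  normalized counts, failing anything below mean − 1·SD of all scores.

A cell line keeps its data only if at least ``min_passing`` (default 3)
replicates survive both metrics.  Percentiles use linear interpolation;
the SD is the population SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .formats import GctMatrix

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = 0.6795


@dataclass
class ReplicateMap:
    """replicate id -> cell line assignment."""

    assignments: dict[str, str]

    def lines(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rep, line in self.assignments.items():
            out.setdefault(line, []).append(rep)
        return out

    def line_of(self, replicate: str) -> str:
        return self.assignments[replicate]


@dataclass
class QcReport:
    pairwise_correlations: pd.DataFrame | None = None
    correlation_threshold: float | None = None
    distribution_scores: dict[str, float] = field(default_factory=dict)
    distribution_cutoff: float | None = None
    failed_replicates: dict[str, set[str]] = field(default_factory=dict)  # rep -> reasons
    failed_cell_lines: set[str] = field(default_factory=set)

    def fail(self, replicate: str, reason: str) -> None:
        self.failed_replicates.setdefault(replicate, set()).add(reason)

    def merge(self, other: "QcReport") -> "QcReport":
        merged = QcReport(
            pairwise_correlations=(
                self.pairwise_correlations
                if self.pairwise_correlations is not None
                else other.pairwise_correlations
            ),
            correlation_threshold=self.correlation_threshold
            if self.correlation_threshold is not None
            else other.correlation_threshold,
            distribution_scores={**self.distribution_scores, **other.distribution_scores},
            distribution_cutoff=self.distribution_cutoff
            if self.distribution_cutoff is not None
            else other.distribution_cutoff,
            failed_cell_lines=self.failed_cell_lines | other.failed_cell_lines,
        )
        for rep, reasons in list(self.failed_replicates.items()) + list(
            other.failed_replicates.items()
        ):
            for r in reasons:
                merged.fail(rep, r)
        return merged

    def summary(self) -> dict:
        return {
            "correlation_threshold": self.correlation_threshold,
            "distribution_cutoff": self.distribution_cutoff,
            "failed_replicates": {k: sorted(v) for k, v in self.failed_replicates.items()},
            "failed_cell_lines": sorted(self.failed_cell_lines),
        }


def _pairwise_pearson(values: np.ndarray, columns: list[str]) -> pd.DataFrame:
    sd = values.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[:, sd == 0] = np.nan
    corr[sd == 0, :] = np.nan
    return pd.DataFrame(corr, index=columns, columns=columns)


def replicate_correlation_qc(
    matrix: GctMatrix,
    reps: ReplicateMap,
    threshold: float | str = DEFAULT_CORRELATION_THRESHOLD,
    agg: str = "max",
) -> QcReport:
    """Fail replicates that do not reproduce any same-line sibling.

    With ``threshold="auto"`` the cutoff is the 75th percentile of all
    non-replicate (different cell line) pair correlations.  A replicate
    fails when its ``agg`` (max by default; mean/median available)
    correlation to same-line siblings falls below the threshold.  A
    zero-variance replicate has undefined correlations and fails as
    "degenerate".  Singleton lines have no sibling and pass vacuously.
    """
    cols = matrix.column_ids
    if len(cols) < 2:
        raise ValueError("need at least 2 replicates for correlation QC")
    if agg not in ("max", "mean", "median"):
        raise ValueError(f"unknown aggregation {agg!r}")
    corr = _pairwise_pearson(matrix.values, cols)
    line = {c: reps.line_of(c) for c in cols}

    if threshold == "auto":
        inter = [
            corr.iloc[i, j]
            for i in range(len(cols))
            for j in range(i + 1, len(cols))
            if line[cols[i]] != line[cols[j]] and np.isfinite(corr.iloc[i, j])
        ]
        if not inter:
            raise ValueError("auto threshold needs at least one non-replicate pair")
        thr = float(np.percentile(inter, 75))
    else:
        thr = float(threshold)

    report = QcReport(pairwise_correlations=corr, correlation_threshold=thr)
    aggfun = {"max": np.max, "mean": np.mean, "median": np.median}[agg]
    for c in cols:
        sibs = [o for o in cols if o != c and line[o] == line[c]]
        if not sibs:
            continue
        vals = corr.loc[c, sibs].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            report.fail(c, "degenerate")
            continue
        if aggfun(vals) < thr:
            report.fail(c, "correlation")
    return report


def distribution_qc(matrix: GctMatrix) -> QcReport:
    """Fail replicates whose 75th-percentile score is below mean − 1·SD."""
    cols = matrix.column_ids
    if len(cols) < 2:
        raise ValueError("distribution cutoff undefined for a single replicate")
    scores = {c: float(np.percentile(matrix.values[:, j], 75)) for j, c in enumerate(cols)}
    arr = np.array(list(scores.values()))
    cutoff = float(arr.mean() - arr.std())  # population SD
    report = QcReport(distribution_scores=scores, distribution_cutoff=cutoff)
    for c, s in scores.items():
        if s < cutoff:
            report.fail(c, "distribution")
    return report


def run_qc(
    matrix: GctMatrix,
    reps: ReplicateMap,
    threshold: float | str = DEFAULT_CORRELATION_THRESHOLD,
    agg: str = "max",
    min_passing: int = 3,
) -> QcReport:
    """Both QC metrics plus the < min_passing whole-line rule."""
    report = replicate_correlation_qc(matrix, reps, threshold, agg).merge(
        distribution_qc(matrix)
    )
    survivors: dict[str, int] = {}
    for c in matrix.column_ids:
        if c not in report.failed_replicates:
            ln = reps.line_of(c)
            survivors[ln] = survivors.get(ln, 0) + 1
    for ln, rep_list in reps.lines().items():
        if any(r in matrix.column_ids for r in rep_list) and survivors.get(ln, 0) < min_passing:
            report.failed_cell_lines.add(ln)
    return report


def apply_removals(
    matrix: GctMatrix,
    report: QcReport,
    reps: ReplicateMap,
    min_passing: int = 3,
    manual_removals: list[tuple[str, str]] | None = None,
) -> GctMatrix:
    """Drop failing replicates, short-handed cell lines, then manual removals.

    Every removal is logged with its reason.  Manual entries naming an
    absent column warn rather than raise (curation lists routinely carry
    samples already gone).
    """
    missing = [c for c in matrix.column_ids if c not in report.failed_replicates
               and c not in reps.assignments]
    if missing:
        raise ValueError(f"replicate map does not cover columns: {missing}")
    keep: list[str] = []
    removed: list[tuple[str, str]] = []
    for c in matrix.column_ids:
        if c in report.failed_replicates:
            removed.append((c, "+".join(sorted(report.failed_replicates[c]))))
        else:
            keep.append(c)
    per_line: dict[str, int] = {}
    for c in keep:
        ln = reps.line_of(c)
        per_line[ln] = per_line.get(ln, 0) + 1
    keep2 = []
    for c in keep:
        ln = reps.line_of(c)
        if per_line[ln] < min_passing or ln in report.failed_cell_lines:
            removed.append((c, f"cell_line<{min_passing}_passing"))
        else:
            keep2.append(c)
    for name, reason in manual_removals or []:
        if name in keep2:
            keep2.remove(name)
            removed.append((name, reason))
        elif name not in matrix.column_ids:
            logger.warning("manual removal of absent column %r ignored", name)
    for name, reason in removed:
        logger.info("removed replicate %s (%s)", name, reason)
    return matrix.select_columns(keep2)


def pca_batch_report(
    matrix: GctMatrix, annotations: dict[str, dict[str, str]] | None = None
) -> pd.DataFrame:
    """First two principal-component coordinates per replicate sample.

    Samples are observations and shRNAs features; features are centered,
    not scaled.  Annotation categories (lineage, screener, PCR date, ...)
    are joined for downstream batch-effect plotting.
    """
    if len(matrix.column_ids) < 3:
        raise ValueError("PCA batch report needs at least 3 columns")
    if not np.isfinite(matrix.values).all():
        bad = [matrix.row_ids[i] for i in np.where(~np.isfinite(matrix.values).all(axis=1))[0]]
        raise ValueError(f"non-finite values in rows: {bad[:10]}")
    X = matrix.values.T  # samples x shRNAs
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    out = pd.DataFrame(coords, index=matrix.column_ids, columns=["PC1", "PC2"])
    out.index.name = "replicate"
    for key, mapping in (annotations or {}).items():
        out[key] = [mapping.get(c, "") for c in matrix.column_ids]
    return out
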