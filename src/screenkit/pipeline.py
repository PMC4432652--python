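"""Post-QC depletion-score processing.

The chain mirrors the historical GenePattern module order and refuses to
run in any other order:

1. drop shRNAs starting at low abundance in the plasmid DNA pool
   (median logged normalized count <= 1),
2. drop one of every pair of same-gene shRNAs whose sequences overlap by
   an offset of < 3 basepairs,
3. drop QC-failing replicate samples,
4. log2 fold change of each replicate against its mapped reference pool
   (chemistry batches stay separate until this step),
5. quantile normalization across replicate columns,
6. collapse replicates to one column per cell line,
7. annotate each shRNA row with its mapped gene symbol(s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .formats import NO_SYMBOL, ChipMap, GctMatrix, SampleSheetEntry
from .qc import QcReport, ReplicateMap, apply_removals

logger = logging.getLogger(__name__)

StageTag = Literal["per_replicate", "normalized", "collapsed", "gene_mapped"]

PIPELINE_STAGE_ORDER = (
    "filter_low_abundance",
    "remove_overlapping",
    "apply_removals",
    "fold_change",
    "quantile_normalize",
    "collapse_replicates",
    "map_genes",
)


@dataclass
class FoldChangeMatrix:
    """Log2 depletion scores vs the reference pool, staged through the chain."""

    matrix: GctMatrix
    stage_tag: StageTag = "per_replicate"

    @property
    def shrna_ids(self) -> list[str]:
        return self.matrix.row_ids

    @property
    def column_ids(self) -> list[str]:
        return self.matrix.column_ids

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


def filter_low_abundance(plasmid_reference: GctMatrix, cutoff: float = 1.0) -> set[str]:
    """shRNAs whose median logged normalized plasmid-pool count is <= cutoff.

    The boundary is inclusive: a median of exactly 1 is dropped.
    """
    if not plasmid_reference.column_ids:
        raise ValueError("reference needs at least one column")
    medians = np.median(plasmid_reference.values, axis=1)
    return {rid for rid, m in zip(plasmid_reference.row_ids, medians) if m <= cutoff}


def _overlaps(a: str, b: str, max_offset: int = 3) -> bool:
    # offset 0..max_offset-1 in either direction; equal-length sequences
    for k in range(max_offset):
        if a[k:] == b[: len(b) - k] or b[k:] == a[: len(a) - k]:
            return True
    return False


def remove_overlapping(
    chip: ChipMap,
    sequences: Sequence[str],
    abundance: Mapping[str, float] | None = None,
    max_offset: int = 3,
) -> set[str]:
    """Drop one member of every same-gene pair of shRNAs offset by < 3 bp.

    Overlap is detected as sequence-shift equality: the leading (L-k)-mer
    of one hairpin equals the trailing (L-k)-mer of the other for k <
    ``max_offset``, and both target the same gene.  The survivor of each
    pair is the member with higher plasmid-pool abundance (ties broken by
    lexicographically smaller barcode); chains are resolved greedily in
    that priority order, so the surviving set contains no overlapping pair.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError("sequences of mixed length")
    sym = chip.symbol_table()
    by_gene: dict[str, list[str]] = {}
    for s in sequences:
        by_gene.setdefault(sym.get(s, NO_SYMBOL), []).append(s)

    def priority(s: str) -> tuple[float, str]:
        return (-(abundance or {}).get(s, 0.0), s)

    dropped: set[str] = set()
    for gene, seqs in by_gene.items():
        if len(seqs) < 2:
            continue
        kept: list[str] = []
        for s in sorted(seqs, key=priority):
            if any(_overlaps(s, k, max_offset) for k in kept):
                dropped.add(s)
            else:
                kept.append(s)
    if dropped:
        logger.info("overlap filter dropped %d shRNAs", len(dropped))
    return dropped


def fold_change(
    samples: GctMatrix,
    reference: GctMatrix,
    mapping: Sequence[SampleSheetEntry],
) -> FoldChangeMatrix:
    """Per-replicate log2 fold change: logged sample minus logged reference.

    Each sample column must map (via the sample sheet) to a reference pool
    column of its own chemistry batch; batches are merged into one matrix
    only at this point.
    """
    ref_frame = reference.to_frame()
    by_rep = {e.replicate_id: e for e in mapping}
    cols = []
    values = np.empty_like(samples.values)
    for j, c in enumerate(samples.column_ids):
        entry = by_rep.get(c)
        if entry is None:
            raise ValueError(f"sample {c!r} has no sample-sheet entry mapping a reference pool")
        if entry.reference_pool_id not in ref_frame.columns:
            raise ValueError(
                f"sample {c!r}: reference pool {entry.reference_pool_id!r} absent"
            )
        ref_col = ref_frame.loc[samples.row_ids, entry.reference_pool_id].to_numpy()
        values[:, j] = samples.values[:, j] - ref_col
        cols.append(c)
    out = GctMatrix(
        row_ids=list(samples.row_ids),
        row_descriptions=list(samples.row_descriptions),
        column_ids=cols,
        values=values,
    )
    return FoldChangeMatrix(out, stage_tag="per_replicate")


def quantile_normalize(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Force every column onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; within-column ranks are preserved and ties receive the
    average of the tied target values.
    """
    X = fc.values
    if np.isnan(X).any():
        raise ValueError("quantile normalization requires complete data")
    if X.shape[1] == 1:
        return FoldChangeMatrix(fc.matrix, stage_tag="normalized")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    m = GctMatrix(
        row_ids=list(fc.shrna_ids),
        row_descriptions=list(fc.matrix.row_descriptions),
        column_ids=list(fc.column_ids),
        values=out,
    )
    return FoldChangeMatrix(m, stage_tag="normalized")


def collapse_replicates(
    fc: FoldChangeMatrix,
    reps: ReplicateMap,
    method: Literal["mean", "median"] = "mean",
) -> FoldChangeMatrix:
    """One column per cell line: mean (default) or median over replicates."""
    if method not in ("mean", "median"):
        raise ValueError(f"unknown collapse method {method!r}")
    lines: dict[str, list[int]] = {}
    for j, c in enumerate(fc.column_ids):
        lines.setdefault(reps.line_of(c), []).append(j)
    fun = np.mean if method == "mean" else np.median
    cols = list(lines)
    values = np.column_stack([fun(fc.values[:, idx], axis=1) for idx in lines.values()])
    m = GctMatrix(
        row_ids=list(fc.shrna_ids),
        row_descriptions=list(fc.matrix.row_descriptions),
        column_ids=cols,
        values=values,
    )
    return FoldChangeMatrix(m, stage_tag="collapsed")


def map_genes(fc: FoldChangeMatrix, chip: ChipMap) -> FoldChangeMatrix:
    """Annotate each shRNA row with its gene symbol(s) in the Description.

    Rows are never aggregated: multiple hairpins keep their own rows and
    share a symbol.  A barcode mapping to several symbols gets them
    semicolon-joined; barcodes absent from the chip get ``NO_SYMBOL`` and
    are logged.
    """
    if not chip.records:
        raise ValueError("empty chip map")
    table = chip.symbol_table()
    descriptions = []
    n_missing = 0
    for rid in fc.shrna_ids:
        sym = table.get(rid)
        if sym is None:
            sym = NO_SYMBOL
            n_missing += 1
        descriptions.append(sym)
    if n_missing:
        logger.warning("%d shRNAs absent from chip map annotated %s", n_missing, NO_SYMBOL)
    m = GctMatrix(
        row_ids=list(fc.shrna_ids),
        row_descriptions=descriptions,
        column_ids=list(fc.column_ids),
        values=fc.values.copy(),
    )
    return FoldChangeMatrix(m, stage_tag="gene_mapped")


@dataclass
class PipelineResult:
    final: FoldChangeMatrix
    stages: dict[str, GctMatrix] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write_provenance(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        return path


def run_pipeline(
    batches: Mapping[str, GctMatrix],
    reference: GctMatrix,
    sheet: Sequence[SampleSheetEntry],
    chip: ChipMap,
    qc_report: QcReport,
    reps: ReplicateMap,
    min_passing: int = 3,
    manual_removals: list[tuple[str, str]] | None = None,
    collapse_method: Literal["mean", "median"] = "mean",
    low_abundance_cutoff: float = 1.0,
    stage_order: Sequence[str] = PIPELINE_STAGE_ORDER,
) -> PipelineResult:
    """Run the whole chain in the fixed module order.

    ``batches`` maps chemistry-batch ids to their logged normalized count
    matrices; ``reference`` holds the plasmid-pool columns named by the
    sample sheet.  ``stage_order`` exists only so a caller attempting to
    permute it is refused — the order is part of the method.
    """
    if tuple(stage_order) != PIPELINE_STAGE_ORDER:
        raise ValueError("pipeline stage order is fixed; refusing permuted order")
    prov: dict = {"stage_order": list(PIPELINE_STAGE_ORDER), "parameters": {
        "min_passing": min_passing,
        "collapse_method": collapse_method,
        "low_abundance_cutoff": low_abundance_cutoff,
    }}
    stages: dict[str, GctMatrix] = {}

    stage = "filter_low_abundance"
    try:
        low = filter_low_abundance(reference, low_abundance_cutoff)
        abundance = dict(zip(reference.row_ids, np.median(reference.values, axis=1)))
        overlap = remove_overlapping(chip, list(abundance), abundance)
        drop = low | overlap
        prov["dropped_shrnas"] = {
            "low_abundance": sorted(low),
            "overlap": sorted(overlap),
        }

        stage = "apply_removals"
        trimmed: dict[str, GctMatrix] = {}
        for batch, mat in batches.items():
            keep_rows = [r for r in mat.row_ids if r not in drop]
            if not keep_rows:
                raise ValueError("all shRNAs filtered before fold change")
            sub = mat.select_rows(keep_rows)
            sub_reps = ReplicateMap({c: reps.line_of(c) for c in sub.column_ids})
            trimmed[batch] = apply_removals(
                sub, qc_report, sub_reps, min_passing, manual_removals
            )

        stage = "fold_change"
        ref_rows = [r for r in reference.row_ids if r not in drop]
        ref_kept = reference.select_rows(ref_rows)
        fcs = []
        for batch, mat in trimmed.items():
            if not mat.column_ids:
                continue
            fcs.append(fold_change(mat, ref_kept, sheet))
        if not fcs:
            raise ValueError("no surviving replicate columns")
        merged = GctMatrix(
            row_ids=list(fcs[0].shrna_ids),
            row_descriptions=list(fcs[0].matrix.row_descriptions),
            column_ids=[c for f in fcs for c in f.column_ids],
            values=np.column_stack([f.values for f in fcs]),
        )
        fc = FoldChangeMatrix(merged, stage_tag="per_replicate")
        stages["fold_change"] = fc.matrix

        stage = "quantile_normalize"
        fc = quantile_normalize(fc)
        stages["quantile_normalize"] = fc.matrix

        stage = "collapse_replicates"
        fc = collapse_replicates(fc, reps, collapse_method)
        stages["collapse_replicates"] = fc.matrix

        stage = "map_genes"
        fc = map_genes(fc, chip)
        stages["map_genes"] = fc.matrix
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    prov["batches"] = sorted(batches)
    prov["final_columns"] = list(fc.column_ids)
    prov["final_rows"] = len(fc.shrna_ids)
    return PipelineResult(final=fc, stages=stages, provenance=prov)
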