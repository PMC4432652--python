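"""Sequencing deconvolution for pooled shRNA screens.

Raw 45-mer reads carry a 4-mer PCR barcode identifying the screening
replicate followed by the 21-mer hairpin sequence.  Reads are binned by
barcode, hairpins counted by exact match against the reference 21-mer
list, and counts converted to logged reads-per-million:

    normalized = log2((raw / column_total) * 1e6) + 1

A pseudocount (default 1, applied to the numerator only) keeps zero-count
hairpins finite; pseudocount 0 reproduces the formula literally.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .formats import GctMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadLayout:
    """Where the PCR barcode and the hairpin sit inside a read.

    ``shrna_start`` is the 0-based offset of the 21-mer; by default it
    begins immediately after the barcode.  ``scan`` mode searches every
    offset instead, for library preps whose constant-region length is
    unknown; a read matching reference hairpins at more than one offset is
    tallied as ambiguous.
    """

    read_length: int = 45
    barcode_start: int = 1  # 1-based, as wet-lab protocols quote positions
    barcode_length: int = 4
    shrna_length: int = 21
    shrna_start: int | None = None  # 0-based; None -> right after barcode
    scan: bool = False

    def __post_init__(self) -> None:
        b0 = self.barcode_start - 1
        if b0 < 0 or b0 + self.barcode_length > self.read_length:
            raise ValueError("barcode window outside read")
        s0 = self.shrna_offset
        if s0 + self.shrna_length > self.read_length:
            raise ValueError("shRNA window outside read")
        if not self.scan and s0 < b0 + self.barcode_length:
            raise ValueError("shRNA window overlaps barcode")

    @property
    def shrna_offset(self) -> int:
        if self.shrna_start is not None:
            return self.shrna_start
        return (self.barcode_start - 1) + self.barcode_length


@dataclass
class RawCountMatrix:
    """Integer read counts per (shRNA, replicate sample) plus loss tallies."""

    shrna_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    unmatched_reads: dict[str, int] = field(default_factory=dict)
    ambiguous_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.shrna_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        for d in (self.unmatched_reads, self.ambiguous_reads):
            for s in self.sample_ids:
                d.setdefault(s, 0)

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.shrna_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "shrna"
        frame.to_csv(path, sep="\t")
        return path


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzip)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def count_reads(
    fastq_stream: Iterable[str],
    layout: ReadLayout,
    barcodes: Mapping[str, str],
    reference: Sequence[str],
) -> RawCountMatrix:
    """Bin reads by PCR barcode and count exact hairpin matches.

    Parameters
    ----------
    fastq_stream:
        Read sequences (strings); use :func:`iter_fastq` for files.
    barcodes:
        4-mer PCR barcode -> sample id.  Reads whose barcode is absent are
        dropped (tallied per matrix, not per sample).  The map must be
        injective: two barcodes may not name the same sample.
    reference:
        The expected hairpin 21-mers; must be unique.

    Reads too short for the layout are skipped and tallied as unmatched
    under their sample when the barcode is readable, otherwise dropped.
    """
    if not reference:
        raise ValueError("empty reference list")
    if len(set(reference)) != len(reference):
        raise ValueError("reference 21-mers are not unique")
    sample_ids = list(dict.fromkeys(barcodes.values()))
    if len(sample_ids) != len(barcodes):
        raise ValueError("barcode map is not injective (samples repeated)")
    ref_index = {seq: i for i, seq in enumerate(reference)}
    col = {s: j for j, s in enumerate(sample_ids)}
    counts = np.zeros((len(reference), len(sample_ids)), dtype=np.int64)
    unmatched = {s: 0 for s in sample_ids}
    ambiguous = {s: 0 for s in sample_ids}
    dropped_barcode = 0

    b0 = layout.barcode_start - 1
    b1 = b0 + layout.barcode_length
    s0 = layout.shrna_offset
    L = layout.shrna_length

    for read in fastq_stream:
        if len(read) < b1:
            dropped_barcode += 1
            continue
        sample = barcodes.get(read[b0:b1])
        if sample is None:
            dropped_barcode += 1
            continue
        j = col[sample]
        if layout.scan:
            hits = {
                ref_index[read[k : k + L]]
                for k in range(b1, len(read) - L + 1)
                if read[k : k + L] in ref_index
            }
            if len(hits) == 1:
                counts[hits.pop(), j] += 1
            elif len(hits) > 1:
                ambiguous[sample] += 1
            else:
                unmatched[sample] += 1
        else:
            if len(read) < s0 + L:
                unmatched[sample] += 1
                continue
            i = ref_index.get(read[s0 : s0 + L])
            if i is None:
                unmatched[sample] += 1
            else:
                counts[i, j] += 1
    if dropped_barcode:
        logger.info("dropped %d reads with unrecognized/unreadable barcode", dropped_barcode)
    for s in sample_ids:
        logger.debug(
            "sample %s: %d matched, %d unmatched, %d ambiguous",
            s, counts[:, col[s]].sum(), unmatched[s], ambiguous[s],
        )
    return RawCountMatrix(list(reference), sample_ids, counts, unmatched, ambiguous)


def normalize_counts(
    raw: RawCountMatrix, pseudocount: float = 1.0, scale: float = 1e6
) -> GctMatrix:
    """Logged reads-per-million normalization.

    value(i, j) = log2(((counts(i,j) + pseudocount) / total_j) * scale) + 1
    with total_j the column sum of raw counts (before pseudocount).  With
    pseudocount 0, zero-count cells are -inf by design.
    """
    totals = raw.totals.astype(float)
    zero = [s for s, t in zip(raw.sample_ids, totals) if t <= 0]
    if zero:
        raise ValueError(f"zero total reads for sample(s): {', '.join(zero)}")
    with np.errstate(divide="ignore"):
        values = np.log2((raw.counts + float(pseudocount)) / totals * scale) + 1.0
    return GctMatrix(
        row_ids=list(raw.shrna_ids),
        row_descriptions=[""] * len(raw.shrna_ids),
        column_ids=list(raw.sample_ids),
        values=values,
    )


def min_depth_check(raw: RawCountMatrix, min_reads: float = 1e7) -> pd.DataFrame:
    """Flag replicates below the minimum read-depth target.

    Read depth per replicate counts every read assigned to its barcode:
    matched + unmatched + ambiguous.  Reporting only — nothing is removed.
    """
    rows = []
    for j, s in enumerate(raw.sample_ids):
        depth = int(raw.counts[:, j].sum()) + raw.unmatched_reads[s] + raw.ambiguous_reads[s]
        rows.append({"sample": s, "reads": depth, "pass": depth >= min_reads})
    return pd.DataFrame(rows).set_index("sample")
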