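"""Readers and writers for the on-disk formats the screen pipeline touches.

All matrices travel as GCT v1.2 (tab-delimited, ``Name``/``Description``
annotation columns, shRNAs in rows and replicate samples in columns).
Hairpin-to-gene annotation travels as a ``.chip`` table, genotypes and
sample sheets as plain TSV.  Round-trips are bit-exact: values are written
with ``repr`` precision and re-read with ``float``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_ALPHABET = frozenset({"AA", "AB", "BB", "NoCall"})
NO_SYMBOL = "NO_SYMBOL"

_VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# GCT


@dataclass
class GctMatrix:
    """A GCT v1.2 matrix: real values with row/column annotations.

    Rows are shRNA barcodes (or gene-solution ids), columns are replicate
    samples or cell lines.  ``row_descriptions`` holds the mapped gene
    symbol per row, or the empty string before gene mapping.
    """

    row_ids: list[str]
    row_descriptions: list[str]
    column_ids: list[str]
    values: np.ndarray
    version_tag: str = "#1.2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("GCT values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.row_ids) != n:
            raise FormatError(
                f"{len(self.row_ids)} row ids for {n} value rows"
            )
        if len(self.row_descriptions) != n:
            raise FormatError("row_descriptions length mismatch")
        if len(self.column_ids) != m:
            raise FormatError(
                f"{len(self.column_ids)} column ids for {m} value columns"
            )
        if len(set(self.row_ids)) != n:
            raise FormatError("duplicate row ids")
        if len(set(self.column_ids)) != m:
            raise FormatError("duplicate column ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, descriptions: Sequence[str] | None = None
    ) -> "GctMatrix":
        desc = list(descriptions) if descriptions is not None else [""] * len(frame)
        return cls(
            row_ids=[str(i) for i in frame.index],
            row_descriptions=desc,
            column_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def select_columns(self, columns: Sequence[str]) -> "GctMatrix":
        idx = [self.column_ids.index(c) for c in columns]
        return GctMatrix(
            row_ids=list(self.row_ids),
            row_descriptions=list(self.row_descriptions),
            column_ids=list(columns),
            values=self.values[:, idx],
            version_tag=self.version_tag,
        )

    def select_rows(self, rows: Sequence[str]) -> "GctMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[r] for r in rows]
        return GctMatrix(
            row_ids=list(rows),
            row_descriptions=[self.row_descriptions[i] for i in idx],
            column_ids=list(self.column_ids),
            values=self.values[idx, :],
            version_tag=self.version_tag,
        )


def read_gct(path: str | Path) -> GctMatrix:
    """Read a GCT v1.2 file.

    The first line is the version tag, the second declares ``rows<TAB>cols``,
    the third is the header row, and each data row is
    ``Name<TAB>Description<TAB>value...``.  Blank descriptions are preserved
    as empty strings.
    """
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if not version.startswith("#"):
            raise FormatError(f"{path}: first line is not a GCT version tag")
        dims = fh.readline().rstrip("\n").split("\t")
        if len(dims) < 2:
            raise FormatError(f"{path}: missing dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError(f"{path}: bad dimension line {dims!r}") from exc
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != n_cols + 2:
            raise FormatError(
                f"{path}: header declares {len(header) - 2} columns, "
                f"dimension line declares {n_cols}"
            )
        column_ids = header[2:]
        row_ids: list[str] = []
        descriptions: list[str] = []
        values = np.empty((n_rows, n_cols), dtype=float)
        i = 0
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if i >= n_rows:
                raise FormatError(
                    f"{path}: expected {n_rows} data rows, found more"
                )
            parts = line.split("\t")
            if len(parts) != n_cols + 2:
                raise FormatError(
                    f"{path}: row {i + 1} has {len(parts) - 2} values, "
                    f"expected {n_cols}"
                )
            row_ids.append(parts[0])
            descriptions.append(parts[1])
            for j, cell in enumerate(parts[2:]):
                try:
                    values[i, j] = float(cell)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: non-numeric cell at data row {i + 1}, "
                        f"column {column_ids[j]!r}: {cell!r}"
                    ) from exc
            i += 1
        if i != n_rows:
            raise FormatError(
                f"{path}: header declares {n_rows} rows but body has {i}"
            )
    return GctMatrix(row_ids, descriptions, column_ids, values, version_tag=version)


def _fmt(x: float) -> str:
    # repr keeps full double precision so write->read->write is stable
    if np.isnan(x):
        return "nan"
    return repr(float(x))


def write_gct(matrix: GctMatrix, path: str | Path) -> Path:
    """Write ``matrix`` as GCT v1.2; validation happens before any write."""
    if not matrix.column_ids:
        raise FormatError("refusing to write GCT with no columns")
    # dataclass invariants (unique ids, shapes) re-checked on construction
    GctMatrix(
        matrix.row_ids,
        matrix.row_descriptions,
        matrix.column_ids,
        matrix.values,
        matrix.version_tag,
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(matrix.version_tag + "\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.column_ids) + "\n")
        for rid, desc, row in zip(
            matrix.row_ids, matrix.row_descriptions, matrix.values
        ):
            fh.write(rid + "\t" + desc + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# .chip shRNA -> gene mapping


@dataclass(frozen=True)
class ChipRecord:
    barcode_sequence: str
    transcript_id: str
    gene_id: str
    gene_symbol: str


@dataclass
class ChipMap:
    """Mapping from shRNA barcode sequences to transcript/gene annotations.

    A barcode may map to more than one transcript; every record carries a
    non-empty gene symbol or the sentinel ``NO_SYMBOL``.
    """

    records: list[ChipRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.barcode_sequence) for r in self.records}
        if len(lengths) > 1:
            raise FormatError(f"barcodes of mixed lengths: {sorted(lengths)}")
        for r in self.records:
            if not set(r.barcode_sequence) <= _VALID_BASES:
                raise FormatError(f"non-ACGT barcode {r.barcode_sequence!r}")

    def symbols_for(self, barcode: str) -> list[str]:
        """Distinct gene symbols mapped to a barcode, in first-seen order."""
        seen: list[str] = []
        for r in self.records:
            if r.barcode_sequence == barcode and r.gene_symbol not in seen:
                seen.append(r.gene_symbol)
        return seen

    def symbol_table(self) -> dict[str, str]:
        """barcode -> semicolon-joined gene symbols."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.barcode_sequence, [])
            if r.gene_symbol not in out[r.barcode_sequence]:
                out[r.barcode_sequence].append(r.gene_symbol)
        return {k: ";".join(v) for k, v in out.items()}

    def gene_for(self, barcode: str) -> str:
        syms = self.symbols_for(barcode)
        return ";".join(syms) if syms else NO_SYMBOL


def read_chip(path: str | Path) -> ChipMap:
    """Read a tab-delimited .chip file.

    Columns: barcode sequence, transcript id, gene id, gene symbol.  A
    header line is detected (first field not a pure ACGT sequence) and
    skipped.  Duplicate (barcode, transcript) pairs are collapsed with a
    warning.
    """
    path = Path(path)
    records: list[ChipRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected >= 4"
                )
            barcode = parts[0].upper()
            if lineno == 1 and not set(barcode) <= _VALID_BASES:
                continue  # header row
            if not set(barcode) <= _VALID_BASES:
                raise FormatError(
                    f"{path}: line {lineno}: barcode {parts[0]!r} contains "
                    "non-ACGT characters"
                )
            key = (barcode, parts[1])
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            symbol = parts[3].strip() or NO_SYMBOL
            records.append(ChipRecord(barcode, parts[1], parts[2], symbol))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate (barcode, transcript) pairs", path, n_dup)
    return ChipMap(records)


def write_chip(chip: ChipMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("Barcode Sequence\tTranscript\tGene ID\tGene Symbol\n")
        for r in chip.records:
            fh.write(f"{r.barcode_sequence}\t{r.transcript_id}\t{r.gene_id}\t{r.gene_symbol}\n")
    return path


# ---------------------------------------------------------------------------
# Genotype panels


def normalize_genotype(call: str) -> str:
    """Map a raw genotype string to {AA, AB, BB, NoCall}.

    Heterozygotes are allele-sorted (BA == AB) so that calls from platforms
    with different allele-order conventions compare equal.
    """
    call = call.strip().upper()
    if call in ("AA", "BB"):
        return call
    if call in ("AB", "BA"):
        return "AB"
    return "NoCall"


@dataclass
class GenotypePanel:
    """Per-sample SNP calls keyed by dbSNP identifier."""

    sample_id: str
    calls: dict[str, str]
    platform: str = "SNP6.0"

    def __post_init__(self) -> None:
        bad = {v for v in self.calls.values()} - GENOTYPE_ALPHABET
        if bad:
            raise FormatError(f"invalid genotype symbols: {sorted(bad)}")


def read_genotypes(path: str | Path) -> list[GenotypePanel]:
    """Read a TSV genotype table (samples in rows, SNPs in columns).

    The header names SNP columns by dbSNP identifier (``rs...``); a
    ``platform`` column is optional.  Unparseable calls become ``NoCall``
    and their count is logged.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    snp_cols = [c for c in table.columns if c.lower().startswith("rs")]
    if not snp_cols:
        raise FormatError(f"{path}: no dbSNP (rs...) columns recognized")
    id_col = table.columns[0]
    panels: list[GenotypePanel] = []
    n_nocall = 0
    for _, row in table.iterrows():
        calls: dict[str, str] = {}
        for snp in snp_cols:
            raw = row[snp] if isinstance(row[snp], str) else ""
            g = normalize_genotype(raw)
            if g == "NoCall" and raw.strip().upper() not in ("", "NOCALL", "--", "NC"):
                n_nocall += 1
            calls[snp] = g
        platform = str(row["platform"]) if "platform" in table.columns else "SNP6.0"
        panels.append(GenotypePanel(str(row[id_col]), calls, platform))
    if n_nocall:
        logger.info("%s: %d unparseable genotype calls set to NoCall", path, n_nocall)
    return panels


def write_genotypes(panels: Sequence[GenotypePanel], path: str | Path) -> Path:
    path = Path(path)
    snps = sorted({s for p in panels for s in p.calls})
    with open(path, "w") as fh:
        fh.write("sample_id\tplatform\t" + "\t".join(snps) + "\n")
        for p in panels:
            row = [p.calls.get(s, "NoCall") for s in snps]
            fh.write(p.sample_id + "\t" + p.platform + "\t" + "\t".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Sample sheets and removal lists


@dataclass(frozen=True)
class SampleSheetEntry:
    replicate_id: str
    cell_line: str
    pcr_barcode: str
    chemistry_batch: str
    reference_pool_id: str

    def __post_init__(self) -> None:
        if not set(self.pcr_barcode.upper()) <= _VALID_BASES:
            raise FormatError(f"non-ACGT PCR barcode {self.pcr_barcode!r}")


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"replicate_id", "cell_line", "pcr_barcode", "chemistry_batch", "reference_pool_id"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    entries = [
        SampleSheetEntry(
            r.replicate_id, r.cell_line, r.pcr_barcode, r.chemistry_batch, r.reference_pool_id
        )
        for r in table.itertuples()
    ]
    barcodes = [e.pcr_barcode for e in entries]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"{path}: duplicate PCR barcodes in one sheet")
    return entries


def write_sample_sheet(entries: Sequence[SampleSheetEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("replicate_id\tcell_line\tpcr_barcode\tchemistry_batch\treference_pool_id\n")
        for e in entries:
            fh.write(
                f"{e.replicate_id}\t{e.cell_line}\t{e.pcr_barcode}\t"
                f"{e.chemistry_batch}\t{e.reference_pool_id}\n"
            )
    return path


def read_removal_list(path: str | Path) -> list[tuple[str, str]]:
    """One column id per line, optional tab-separated reason."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 else "manual"))
    return out
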