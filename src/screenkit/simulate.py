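"""Synthetic pooled-screen data with known ground truth.

The generator follows the physical model of a pooled viability screen:
plasmid abundances are log-normal; over D population doublings an shRNA
with per-doubling fitness deficit s grows as 2^(D(1-s)), so its expected
log2 fold change against the plasmid pool is -D*s (up to a small
pool-renormalization constant); replicate noise is a multiplicative
log-normal perturbation; sequencing draws a multinomial of the requested
read depth.  Dilution-series pools, mutation-context datasets and SNP
genotype panels for the downstream modules come from the same seed-pure
machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconv import RawCountMatrix, ReadLayout
from .formats import ChipMap, ChipRecord, GctMatrix, GenotypePanel, SampleSheetEntry
from .paris import TargetProfile
from .qc import ReplicateMap

_BASES = np.array(list("ACGT"))


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """n unique random k-mers (k must give enough headroom, 4^k >> n)."""
    out: set[str] = set()
    while len(out) < n:
        draw = rng.integers(0, 4, size=(n - len(out), k))
        for row in draw:
            out.add("".join(_BASES[row]))
    return sorted(out)[:n] if len(out) > n else sorted(out)


@dataclass
class ScreenSimConfig:
    """Study conditions for the synthetic screen.

    Defaults are the desk-scale profile: 5,000 hairpins over 1,000 genes
    (5 per gene), 12 lines in quadruplicate, 16 doublings, 10^6 reads per
    replicate.  ``profile="full"`` scales to the library-scale 54,020
    hairpins / ~11,000 genes screen.
    """

    n_shrnas: int = 5000
    shrnas_per_gene: int = 5
    n_cell_lines: int = 12
    n_replicates: int = 4
    doublings: int = 16
    read_depth: int = 1_000_000
    plasmid_log_mu: float = 0.0
    plasmid_log_sigma: float = 0.5
    essential_fraction: float = 0.05
    essential_deficit: float = 0.25
    context_fraction: float = 0.05
    context_deficit: float = 0.25
    mutant_fraction: float = 0.3
    noise_sigma: float = 0.1
    n_reference_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shrnas <= 0 or self.n_cell_lines <= 0 or self.read_depth <= 0:
            raise ValueError("counts must be positive")
        for s in (self.essential_deficit, self.context_deficit):
            if not 0 < s <= 1:
                raise ValueError("fitness deficits must be in (0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_shrnas // self.shrnas_per_gene

    @classmethod
    def full_scale(cls, seed: int = 0) -> "ScreenSimConfig":
        return cls(n_shrnas=54020, shrnas_per_gene=5, n_cell_lines=102,
                   read_depth=10_000_000, seed=seed)


@dataclass
class TruthTable:
    """Ground truth behind a simulated screen, derivable from config+seed."""

    expected_lfc: pd.DataFrame  # shRNA x cell line expected log2 fold change
    deficits: pd.DataFrame  # shRNA x cell line per-doubling fitness deficit
    gene_labels: dict[str, str]  # gene -> neutral | essential | context
    line_features: dict[str, int]  # cell line -> binary mutation feature
    shrna_gene: dict[str, str]


@dataclass
class SimulatedScreen:
    counts: RawCountMatrix  # screen replicates + plasmid reference columns
    truth: TruthTable
    chip: ChipMap
    sheet: list[SampleSheetEntry]
    replicate_map: ReplicateMap
    reference_columns: list[str]
    pcr_barcodes: dict[str, str]  # 4-mer -> sample id
    layout: ReadLayout = field(default_factory=ReadLayout)


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Simulate endpoint sequencing counts for a pooled shRNA screen."""
    rng = np.random.default_rng(config.seed)
    n = config.n_shrnas
    sequences = _random_kmers(rng, n, 21)
    genes = [f"GENE{g:05d}" for g in range(config.n_genes)]
    shrna_gene = {
        seq: genes[min(i // config.shrnas_per_gene, config.n_genes - 1)]
        for i, seq in enumerate(sequences)
    }
    chip = ChipMap(
        [
            ChipRecord(seq, f"NM_{i:06d}", str(10000 + i), shrna_gene[seq])
            for i, seq in enumerate(sequences)
        ]
    )

    n_ess = int(round(config.essential_fraction * config.n_genes))
    n_ctx = int(round(config.context_fraction * config.n_genes))
    order = rng.permutation(config.n_genes)
    gene_labels = {g: "neutral" for g in genes}
    for gi in order[:n_ess]:
        gene_labels[genes[gi]] = "essential"
    for gi in order[n_ess : n_ess + n_ctx]:
        gene_labels[genes[gi]] = "context"

    lines = [f"LINE{j:03d}" for j in range(config.n_cell_lines)]
    line_features = {ln: int(rng.random() < config.mutant_fraction) for ln in lines}

    a = rng.lognormal(config.plasmid_log_mu, config.plasmid_log_sigma, n)
    D = config.doublings
    deficits = np.zeros((n, config.n_cell_lines))
    for i, seq in enumerate(sequences):
        label = gene_labels[shrna_gene[seq]]
        if label == "essential":
            deficits[i, :] = config.essential_deficit
        elif label == "context":
            for j, ln in enumerate(lines):
                if line_features[ln]:
                    deficits[i, j] = config.context_deficit

    # expected normalized log2 fold change: -D*s minus the pool shift
    w = a[:, None] * np.power(2.0, -D * deficits)
    pool_shift = np.log2(w.sum(axis=0) / a.sum())
    expected_lfc = -D * deficits - pool_shift[None, :]

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    reps = {}
    sheet: list[SampleSheetEntry] = []
    n_samples = config.n_cell_lines * config.n_replicates + config.n_reference_replicates
    barcode_pool = _random_kmers(rng, n_samples, 4)
    bi = 0
    pcr_barcodes: dict[str, str] = {}
    ref_cols = [f"pDNA_ref_{k + 1}" for k in range(config.n_reference_replicates)]
    for j, ln in enumerate(lines):
        for r in range(config.n_replicates):
            rid = f"{ln}_rep{r + 1}"
            noise = np.exp(rng.normal(0.0, config.noise_sigma, n))
            wj = w[:, j] * noise
            columns.append(rng.multinomial(config.read_depth, wj / wj.sum()))
            sample_ids.append(rid)
            reps[rid] = ln
            pcr_barcodes[barcode_pool[bi]] = rid
            sheet.append(
                SampleSheetEntry(rid, ln, barcode_pool[bi], "simBatch1", ref_cols[0])
            )
            bi += 1
    for rc in ref_cols:
        noise = np.exp(rng.normal(0.0, config.noise_sigma, n))
        wr = a * noise
        columns.append(rng.multinomial(config.read_depth, wr / wr.sum()))
        sample_ids.append(rc)
        pcr_barcodes[barcode_pool[bi]] = rc
        bi += 1

    counts = RawCountMatrix(
        shrna_ids=sequences,
        sample_ids=sample_ids,
        counts=np.column_stack(columns),
    )
    truth = TruthTable(
        expected_lfc=pd.DataFrame(expected_lfc, index=sequences, columns=lines),
        deficits=pd.DataFrame(deficits, index=sequences, columns=lines),
        gene_labels=gene_labels,
        line_features=line_features,
        shrna_gene=shrna_gene,
    )
    return SimulatedScreen(
        counts=counts,
        truth=truth,
        chip=chip,
        sheet=sheet,
        replicate_map=ReplicateMap(reps),
        reference_columns=ref_cols,
        pcr_barcodes=pcr_barcodes,
    )


def write_fastq(
    counts: RawCountMatrix,
    pcr_barcodes: dict[str, str],
    path: str | Path,
    layout: ReadLayout | None = None,
    rng: np.random.Generator | None = None,
) -> Path:
    """Wrap a count matrix back into 45-mer reads honoring the layout.

    Row ids must be the hairpin sequences themselves.  Filler bases pad
    reads to the layout length; order is deterministic given ``rng``.
    """
    layout = layout or ReadLayout()
    rng = rng or np.random.default_rng(0)
    sample_barcode = {v: k for k, v in pcr_barcodes.items()}
    pad = layout.read_length - layout.shrna_offset - layout.shrna_length
    path = Path(path)
    with open(path, "w") as fh:
        i = 0
        for j, sample in enumerate(counts.sample_ids):
            bc = sample_barcode[sample]
            for seq, c in zip(counts.shrna_ids, counts.counts[:, j]):
                if c == 0:
                    continue
                read = bc + seq + "".join(_BASES[rng.integers(0, 4, pad)])
                for _ in range(int(c)):
                    fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")
                    i += 1
    return path


# ---------------------------------------------------------------------------
# Dilution series (pool-mixing validation experiment)


def simulate_dilution_pools(
    n_shrnas: int = 45000,
    ratios_reference: tuple[float, ...] = (1, 1, 1, 1),
    ratios_dilution: tuple[float, ...] = (1, 4, 16, 64),
    read_depth: int = 1_000_000,
    seed: int = 0,
    plasmid_log_sigma: float = 0.25,
) -> tuple[RawCountMatrix, RawCountMatrix, dict[str, int]]:
    """Two pools mixed from four equal shRNA subsets at known ratios.

    The same per-plasmid abundances enter both pools (the physical preps
    are shared); only the subset concentrations differ.  Returns the two
    single-column count matrices and the subset label per shRNA.
    """
    if n_shrnas % len(ratios_reference) != 0:
        raise ValueError("n_shrnas must divide evenly into subsets")
    if len(ratios_reference) != len(ratios_dilution):
        raise ValueError("ratio vectors must have equal length")
    rng = np.random.default_rng(seed)
    n_sub = len(ratios_reference)
    per = n_shrnas // n_sub
    ids = [f"sh{i:06d}" for i in range(n_shrnas)]
    labels = {ids[i]: i // per for i in range(n_shrnas)}
    a = rng.lognormal(0.0, plasmid_log_sigma, n_shrnas)
    subset = np.repeat(np.arange(n_sub), per)

    def sample_pool(ratios: tuple[float, ...], name: str) -> RawCountMatrix:
        wt = a * np.asarray(ratios, dtype=float)[subset]
        reads = rng.multinomial(read_depth, wt / wt.sum())
        return RawCountMatrix(ids, [name], reads[:, None])

    ref = sample_pool(ratios_reference, "reference_pool")
    dil = sample_pool(ratios_dilution, "dilution_pool")
    return ref, dil, labels


def dilution_series_report(
    reference_norm: GctMatrix,
    dilution_norm: GctMatrix,
    labels: dict[str, int],
) -> pd.DataFrame:
    """Median normalized log2 abundance difference per subset.

    Each pool's subsets are summarized by the median normalized value of
    their detected shRNAs (zero-count hairpins have no finite logged
    value and are excluded); the per-subset difference between pools then
    cancels plasmid-prep variation, and the adjacent-subset differences
    estimate the planted concentration steps (log2 of 4 = 2 for the
    canonical 1:4:16:64 design).
    """
    sub = np.array([labels[r] for r in reference_norm.row_ids])
    rows = []
    for s in sorted(set(sub)):
        ref_v = reference_norm.values[sub == s, 0]
        dil_v = dilution_norm.values[sub == s, 0]
        m = float(
            np.median(dil_v[np.isfinite(dil_v)]) - np.median(ref_v[np.isfinite(ref_v)])
        )
        rows.append(
            {
                "subset": s,
                "median_log2_diff": m,
                "detected_fraction": float(np.isfinite(dil_v).mean()),
            }
        )
    out = pd.DataFrame(rows)
    out["adjacent_step_log2"] = out["median_log2_diff"].diff()
    return out


# ---------------------------------------------------------------------------
# Context-dependency dataset for feature matching


def simulate_context_dataset(
    n_lines: int = 60,
    n_features: int = 200,
    effect: float = 2.0,
    mutant_fraction: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
    planted_feature: str = "G_planted",
) -> tuple[GctMatrix, TargetProfile, dict]:
    """Fold-change profiles with one gene depleted in mutant lines.

    ``effect`` is in units of the noise SD; mutant lines' values for the
    planted feature are shifted down by ``effect * noise_sd`` (greater
    sensitivity to suppression).  ``effect=0`` gives a pure null dataset.
    """
    if effect < 0:
        raise ValueError("planted effect must be >= 0")
    rng = np.random.default_rng(seed)
    lines = [f"LINE{j:03d}" for j in range(n_lines)]
    # guarantee both classes present
    mut = np.zeros(n_lines, dtype=int)
    while mut.sum() in (0, n_lines):
        mut = (rng.random(n_lines) < mutant_fraction).astype(int)
    features = [f"G{i:04d}" for i in range(n_features - 1)] + [planted_feature]
    values = rng.normal(0.0, noise_sd, (n_features, n_lines))
    values[-1, mut == 1] -= effect * noise_sd
    matrix = GctMatrix(
        row_ids=features,
        row_descriptions=[""] * n_features,
        column_ids=lines,
        values=values,
    )
    target = TargetProfile(sample_ids=lines, values=mut.astype(float))
    truth = {
        "planted_feature": planted_feature,
        "effect": effect,
        "mutant_lines": [ln for ln, m in zip(lines, mut) if m],
    }
    return matrix, target, truth


# ---------------------------------------------------------------------------
# Genotype panels


def simulate_genotype_panels(
    n_lines: int = 20,
    n_snps: int = 79,
    error_rate: float = 0.02,
    nocall_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[GenotypePanel], list[GenotypePanel], np.ndarray]:
    """Reference panels plus post-screen queries with call error/dropout.

    Genotypes are Hardy–Weinberg draws per SNP with allele frequencies
    uniform on (0.1, 0.9); queries copy their reference with per-call
    error (switched to one of the other genotypes) and NoCall dropout.
    Returns (references, queries, allele_frequencies).
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, n_snps)
    snps = [f"rs{100000 + i}" for i in range(n_snps)]
    genotypes = np.array(["AA", "AB", "BB"])
    refs: list[GenotypePanel] = []
    queries: list[GenotypePanel] = []
    for j in range(n_lines):
        calls: dict[str, str] = {}
        for i, snp in enumerate(snps):
            p = freqs[i]
            probs = [p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]
            calls[snp] = str(rng.choice(genotypes, p=probs))
        refs.append(GenotypePanel(f"CL{j:03d}", calls, platform="SNP6.0"))
        qcalls: dict[str, str] = {}
        for snp, g in calls.items():
            if rng.random() < nocall_rate:
                qcalls[snp] = "NoCall"
            elif rng.random() < error_rate:
                qcalls[snp] = str(rng.choice(genotypes[genotypes != g]))
            else:
                qcalls[snp] = g
        queries.append(GenotypePanel(f"CL{j:03d}", qcalls, platform="Fluidigm"))
    return refs, queries, freqs


def expected_unrelated_match(freqs: np.ndarray) -> float:
    """Chance concordance of two unrelated Hardy–Weinberg panels.

    Per SNP with allele frequency p, two independent draws agree with
    probability (p^2)^2 + (2pq)^2 + (q^2)^2; averaged over the panel.
    """
    p = np.asarray(freqs)
    q = 1 - p
    return float(((p**2) ** 2 + (2 * p * q) ** 2 + (q**2) ** 2).mean())
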