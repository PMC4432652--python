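"""Cell-line identity verification by SNP genotype concordance.

Post-screen fingerprints (Sequenom/Fluidigm) are compared with reference
genotypes (typically Birdseed calls from SNP6.0 arrays over a fixed panel
of dbSNP sites).  The match fraction over SNPs called on both sides
decides identity; unrelated lines agree only at the Hardy–Weinberg
chance level, far below the default 0.8 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .formats import GenotypePanel

Verdict = Literal["match", "mismatch", "insufficient"]


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    reference_id: str
    n_compared: int
    n_matching: int
    fraction_matching: float
    verdict: Verdict


def match_fraction(
    query: GenotypePanel,
    reference: GenotypePanel,
    min_snps: int = 20,
    match_threshold: float = 0.8,
) -> MatchResult:
    """Fraction of concordant genotype calls over SNPs called on both sides.

    ``NoCall`` on either side excludes a SNP from the comparison; calls are
    already allele-sort normalized by the readers.  Fewer than ``min_snps``
    comparable SNPs (including zero shared identifiers) yields verdict
    ``insufficient`` rather than an exception.
    """
    shared = set(query.calls) & set(reference.calls)
    compared = 0
    matching = 0
    for snp in shared:
        a, b = query.calls[snp], reference.calls[snp]
        if a == "NoCall" or b == "NoCall":
            continue
        compared += 1
        if a == b:
            matching += 1
    fraction = matching / compared if compared else 0.0
    if compared < min_snps:
        verdict: Verdict = "insufficient"
    elif fraction >= match_threshold:
        verdict = "match"
    else:
        verdict = "mismatch"
    return MatchResult(query.sample_id, reference.sample_id, compared, matching, fraction, verdict)


def best_match(
    query: GenotypePanel,
    references: Sequence[GenotypePanel],
    match_threshold: float = 0.8,
    min_snps: int = 20,
) -> list[MatchResult]:
    """Rank references by match fraction (descending, ties by id).

    The top result's verdict is ``match`` only when its fraction clears
    the threshold; the margin to the runner-up is informative, not
    enforced.
    """
    if not references:
        raise ValueError("need at least one reference panel")
    results = [
        match_fraction(query, ref, min_snps, match_threshold) for ref in references
    ]
    results.sort(key=lambda r: (-r.fraction_matching, r.reference_id))
    return results


def match_table(results: Sequence[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": r.query_id,
                "reference": r.reference_id,
                "n_compared": r.n_compared,
                "n_matching": r.n_matching,
                "fraction_matching": r.fraction_matching,
                "verdict": r.verdict,
            }
            for r in results
        ]
    )
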