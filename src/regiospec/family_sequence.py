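"""Gene-family analysis: global protein alignment vs spatial correlation.

Members of a gene family can divide labour spatially: near-identical
proteins expressed in complementary sets of brain regions (Neurog1/Neurog2
being the classic bHLH example).  To surface such pairs, every within-
category gene pair is scored with a Needleman-Wunsch global alignment
(BLOSUM50, linear gap penalty of 8 per gap symbol; score >= 0 counts as a
sequence match) and with the Pearson correlation of the two genes' regional
expression patterns at the two ages of peak dissimilarity.  Matched pairs
with spatial correlation below -0.2 are the "similar sequence, complementary
expression" stratum; above +0.2 the "similar and co-expressed" stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_core import ExpressionDataset, GeneAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentResult",
    "needleman_wunsch",
    "family_pairs",
    "spatial_correlation",
    "build_family_table",
    "GAP_PENALTY",
    "CORRELATION_THRESHOLD",
]

GAP_PENALTY = 8
#: |r| beyond which a matched pair is flagged correlated / anti-correlated
CORRELATION_THRESHOLD = 0.2

_BLOSUM50 = substitution_matrices.load("BLOSUM50")
_ALPHABET = set(_BLOSUM50.alphabet) - {"*"}


def _make_aligner(open_gap: float = GAP_PENALTY,
                  extend_gap: float | None = None) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="global")
    aligner.substitution_matrix = _BLOSUM50
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -(open_gap if extend_gap is None else extend_gap)
    return aligner


@dataclass
class AlignmentResult:
    """Optimal global alignment of two protein sequences."""

    gene_a: str
    gene_b: str
    score: int
    aligned_a: str
    aligned_b: str

    @property
    def matched(self) -> bool:
        """Score >= 0 counts as a family (sequence-similar) pair."""
        return self.score >= 0


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"sequence {name!r} is empty")
    for i, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise ValidationError(
                f"sequence {name!r}: illegal character {ch!r} at position {i + 1}")


def needleman_wunsch(seq_a: str, seq_b: str,
                     gene_a: str = "A", gene_b: str = "B",
                     open_gap: float = GAP_PENALTY,
                     extend_gap: float | None = None) -> AlignmentResult:
    """Optimal global alignment under BLOSUM50 with a linear gap penalty of
    8 per gap symbol (pass a smaller ``extend_gap`` for an affine model).
    The score is symmetric in the argument order; one optimal alignment is
    returned."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _check_sequence(seq_a, gene_a)
    _check_sequence(seq_b, gene_b)
    aligner = _make_aligner(open_gap, extend_gap)
    aln = aligner.align(seq_a, seq_b)
    best = aln[0]
    return AlignmentResult(gene_a, gene_b, int(round(best.score)),
                           str(best[0]), str(best[1]))


def family_pairs(
    annotation: GeneAnnotation,
    categories: Sequence[str],
    sequences: Mapping[str, str],
) -> list[tuple[str, str, set[str]]]:
    """All unordered within-category gene pairs with available sequences.

    A pair occurring in several categories is listed once, tagged with every
    category it belongs to.  Categories with fewer than two sequenced genes
    contribute nothing (logged).
    """
    t2g = annotation.term_to_genes()
    tagged: dict[tuple[str, str], set[str]] = {}
    for cat in categories:
        genes = sorted(g for g in t2g.get(cat, set()) if g in sequences)
        skipped = sorted(t2g.get(cat, set()) - set(genes))
        if skipped:
            logger.info("category %s: %d gene(s) without sequence excluded",
                        cat, len(skipped))
        if len(genes) < 2:
            logger.info("category %s has < 2 sequenced genes; no pairs", cat)
            continue
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                tagged.setdefault((genes[i], genes[j]), set()).add(cat)
    return [(a, b, cats) for (a, b), cats in sorted(tagged.items())]


def spatial_correlation(
    dataset: ExpressionDataset,
    gene_a: str,
    gene_b: str,
    timepoint: str,
) -> float:
    """Pearson r between two genes' regional expression patterns at one age.

    Computed over regions where both genes are observed; requires at least 3
    such regions; NaN when either pattern has zero variance.
    """
    m = dataset.matrix_at(timepoint)
    xa = m[dataset.gene_index(gene_a)]
    xb = m[dataset.gene_index(gene_b)]
    mask = ~(np.isnan(xa) | np.isnan(xb))
    if mask.sum() < 3:
        raise ValidationError(
            f"genes {gene_a!r}/{gene_b!r} share < 3 regions at {timepoint!r}")
    xa, xb = xa[mask], xb[mask]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    from scipy import stats

    return float(stats.pearsonr(xa, xb).statistic)


def build_family_table(
    dataset: ExpressionDataset,
    annotation: GeneAnnotation,
    sequences: Mapping[str, str],
    categories: Sequence[str],
    timepoints: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Sequence-similarity vs spatial-correlation table over family pairs.

    ``timepoints`` defaults to the first and last dataset timepoints (the
    two ages of peak dissimilarity in an hourglass-shaped series).  Each row
    carries the alignment score, the matched flag, the spatial r at both
    ages, and per-age strata: ``anti`` (matched and r < -0.2), ``corr``
    (matched and r > 0.2) or ``none``.
    """
    if timepoints is None:
        timepoints = (dataset.timepoints[0], dataset.timepoints[-1])
    t1, t2 = timepoints
    rows = []
    for gene_a, gene_b, cats in family_pairs(annotation, categories, sequences):
        if gene_a not in dataset.genes or gene_b not in dataset.genes:
            logger.info("pair (%s, %s) lacks expression data; skipped",
                        gene_a, gene_b)
            continue
        res = needleman_wunsch(sequences[gene_a], sequences[gene_b],
                               gene_a, gene_b)
        r_vals = []
        for t in (t1, t2):
            try:
                r_vals.append(spatial_correlation(dataset, gene_a, gene_b, t))
            except ValidationError:
                r_vals.append(float("nan"))

        def stratum(r: float) -> str:
            if not res.matched or np.isnan(r):
                return "none"
            if r < -CORRELATION_THRESHOLD:
                return "anti"
            if r > CORRELATION_THRESHOLD:
                return "corr"
            return "none"

        rows.append((gene_a, gene_b, ";".join(sorted(cats)), res.score,
                     res.matched, r_vals[0], r_vals[1],
                     stratum(r_vals[0]), stratum(r_vals[1])))
    return pd.DataFrame(rows, columns=[
        "gene_a", "gene_b", "categories", "score", "matched",
        f"r_{t1}", f"r_{t2}", f"stratum_{t1}", f"stratum_{t2}"])
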