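"""Ortholog screening and Kimura-corrected amino-acid distances.

Orthologous pairs are accepted when their alignment summary clears four
thresholds (E-value <= 1e-5, similarity >= 75%, overlap >= 80%, gaps < 3%).
From an accepted aligned pair the observed difference proportion p (gap
columns excluded pairwise) is corrected for multiple substitutions with
Kimura's approximation

    d = -ln(1 - p - 0.2 p^2),

defined for p below the positive root of 0.2 p^2 + p - 1 (~0.8541); pairs
at or beyond that saturation point carry no usable distance and are
excluded rather than capped, since a silent cap would bias downstream
correlations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Positive root of 0.2 p^2 + p - 1 = 0: the domain boundary of the correction.
P_SATURATION = (math.sqrt(1.8) - 1) / 0.4

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class SaturatedDistanceError(ValueError):
    """p at or beyond the Kimura correction's domain boundary."""


class UndefinedDistanceError(ValueError):
    """No ungapped alignment column to estimate p from."""


@dataclass(frozen=True)
class AlignmentSummaryRecord:
    """Summary statistics of one query-subject protein alignment."""

    query_id: str
    subject_id: str
    e_value: float
    percent_similarity: float
    percent_overlap: float
    percent_gaps: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        for name in ("percent_similarity", "percent_overlap", "percent_gaps"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass(frozen=True)
class OrthologFilterConfig:
    """Acceptance thresholds for orthologous pairs."""

    max_e_value: float = 1e-5
    min_percent_similarity: float = 75.0
    min_percent_overlap: float = 80.0
    max_percent_gaps: float = 3.0  # strict: gaps must be < this


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: Optional[str] = None  # first failing criterion when rejected


@dataclass(frozen=True)
class AlignedOrthologPair:
    """Two equal-length gapped amino-acid sequences with their IDs."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"aligned sequences differ in length ({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        alphabet = set(AMINO_ACIDS + GAP + "X*")
        for seq in (self.seq_a, self.seq_b):
            bad = set(seq.upper()) - alphabet
            if bad:
                raise ValueError(f"unexpected alignment characters: {sorted(bad)}")


@dataclass(frozen=True)
class DistanceResult:
    protein_id: str
    ortholog_id: str
    p_distance: float
    kimura_distance: float
    ungapped_columns: int


def ortholog_filter(
    rec: AlignmentSummaryRecord, config: OrthologFilterConfig = OrthologFilterConfig()
) -> FilterDecision:
    """Accept or reject an orthologous pair on its alignment summary.

    Accept iff E <= max_e_value, similarity >= min_percent_similarity,
    overlap >= min_percent_overlap and gaps strictly < max_percent_gaps.
    A rejection names the first failing criterion in threshold order.
    """
    if rec.e_value > config.max_e_value:
        return FilterDecision(False, "e_value")
    if rec.percent_similarity < config.min_percent_similarity:
        return FilterDecision(False, "similarity")
    if rec.percent_overlap < config.min_percent_overlap:
        return FilterDecision(False, "overlap")
    if rec.percent_gaps >= config.max_percent_gaps:
        return FilterDecision(False, "gaps")
    return FilterDecision(True)


def p_distance(pair: AlignedOrthologPair) -> tuple[float, int]:
    """Observed difference proportion over the ungapped alignment columns.

    Columns with a gap in either sequence are excluded pairwise; comparison
    is case-insensitive.  Raises :class:`UndefinedDistanceError` when no
    column survives.
    """
    a = pair.seq_a.upper()
    b = pair.seq_b.upper()
    columns = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        columns += 1
        if x != y:
            diffs += 1
    if columns == 0:
        raise UndefinedDistanceError(
            f"{pair.id_a}/{pair.id_b}: no ungapped column to estimate p from"
        )
    return diffs / columns, columns


def kimura_distance(p: float) -> float:
    """Kimura's corrected amino-acid distance d = -ln(1 - p - 0.2 p^2).

    Defined for 0 <= p < ~0.8541; beyond that the pair is saturated and a
    :class:`SaturatedDistanceError` is raised.
    """
    if p < 0:
        raise ValueError("p must be non-negative")
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        raise SaturatedDistanceError(
            f"p = {p:.4f} at or beyond the saturation bound {P_SATURATION:.4f}"
        )
    return -math.log(arg)


def inverse_kimura(d: float) -> float:
    """The p solving kimura_distance(p) = d (exact algebraic inverse).

    p* = (-1 + sqrt(1 + 0.8 (1 - e^-d))) / 0.4, the positive root of
    0.2 p^2 + p - (1 - e^-d) = 0.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    return (-1.0 + math.sqrt(1.0 + 0.8 * (1.0 - math.exp(-d)))) / 0.4


def read_aligned_pairs(source: Union[str, Path, IO[str]]) -> list[AlignedOrthologPair]:
    """Read consecutive record pairs from an aligned FASTA file.

    Records come two per pair (first the focal protein, then its ortholog);
    an odd record count is a format error.
    """
    records = list(SeqIO.parse(source, "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"aligned FASTA holds an odd number of records ({len(records)})")
    pairs = []
    for i in range(0, len(records), 2):
        ra, rb = records[i], records[i + 1]
        pairs.append(AlignedOrthologPair(ra.id, rb.id, str(ra.seq), str(rb.seq)))
    return pairs


def batch_distances(pairs: Iterable[AlignedOrthologPair]) -> list[DistanceResult]:
    """Kimura distances for a batch of aligned pairs.

    Saturated or undefined pairs are logged and omitted from the output
    rather than silently capped.
    """
    results = []
    for pair in pairs:
        try:
            p, cols = p_distance(pair)
            d = kimura_distance(p)
        except (SaturatedDistanceError, UndefinedDistanceError) as exc:
            logger.warning("pair %s/%s excluded: %s", pair.id_a, pair.id_b, exc)
            continue
        results.append(DistanceResult(pair.id_a, pair.id_b, p, d, cols))
    return results
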