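"""Functional-class annotations and the coefficient of functionality.

For a protein with *m* interaction partners of which *n* share one of its
functional classes, the coefficient of functionality is n/m.  Multi-class
proteins evaluate the coefficient for each of their own classes and keep the
class with the largest value.  Proteins at or above the dataset-mean
coefficient are "same functional" (SF); the rest are "different functional"
(DF).  The default vocabulary is the 17 top-level MIPS functional classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Literal, Optional, Sequence, Union

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

SF = "SF"
DF = "DF"
UNCLASSIFIED = "unclassified"

#: The 17 top-level functional classes of the MIPS functional catalogue.
MIPS_FUNCTIONAL_CLASSES: tuple[str, ...] = (
    "Metabolism",
    "Energy",
    "Cell cycle and DNA processing",
    "Transcription",
    "Protein synthesis",
    "Protein fate (folding, modification, destination)",
    "Protein with binding function or cofactor requirement (structural or catalytic)",
    "Regulation of metabolism and protein function",
    "Cellular transport, Transport facilities and transport routes",
    "Cellular communication/signal transduction mechanism",
    "Cell rescue, defense and virulence",
    "Interaction with the environment",
    "Transposable elements, viral and plasmid proteins",
    "Cell fate",
    "Development",
    "Biogenesis of cellular components",
    "Cell type differentiation",
)


class AnnotationError(ValueError):
    """Annotation row outside the class vocabulary."""


@dataclass
class FunctionalAnnotation:
    """Mapping protein ID -> set of functional-class labels."""

    classes: dict[str, set[str]] = field(default_factory=dict)
    vocabulary: tuple[str, ...] = MIPS_FUNCTIONAL_CLASSES

    def add(self, protein: str, label: str) -> None:
        if label not in self.vocabulary:
            raise AnnotationError(f"class label {label!r} not in vocabulary")
        self.classes.setdefault(protein, set()).add(label)

    def __getitem__(self, protein: str) -> set[str]:
        return self.classes.get(protein, set())

    def __contains__(self, protein: str) -> bool:
        return protein in self.classes

    def is_annotated(self, protein: str) -> bool:
        return bool(self.classes.get(protein))


@dataclass(frozen=True)
class FunctionalityResult:
    """Coefficient of functionality for one protein.

    ``coefficient`` is max over the protein's own classes c of n_c/m, where
    m counts interaction partners and n_c the partners annotated with c.
    ``label`` is filled in by :func:`classify_functionality`.
    """

    protein: str
    coefficient: Optional[float]
    assigned_class: Optional[str]
    m: int
    n: int
    label: str = UNCLASSIFIED


def read_annotations(
    source: Union[str, Path, IO[str]],
    vocabulary: Sequence[str] = MIPS_FUNCTIONAL_CLASSES,
) -> FunctionalAnnotation:
    """Read a (protein_id, class_label) TSV into a :class:`FunctionalAnnotation`.

    Rows with labels outside the vocabulary raise :class:`AnnotationError`
    naming the offending line.
    """
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_annotations(handle, vocabulary=vocabulary)
    ann = FunctionalAnnotation(vocabulary=tuple(vocabulary))
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise AnnotationError(f"line {lineno}: expected (protein_id, class_label)")
        protein, label = fields[0].strip(), fields[1].strip()
        if lineno == 1 and label.lower() in {"class_label", "class", "label"}:
            continue
        try:
            ann.add(protein, label)
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
    return ann


def functionality_coefficient(
    net: InteractionNetwork,
    ann: FunctionalAnnotation,
    p: str,
    count_unannotated_partners: bool = True,
) -> FunctionalityResult:
    """Coefficient of functionality of protein ``p`` with the largest-value class rule.

    For each class c the protein itself carries, count partners n_c that
    carry c (a partner matches on any of its own classes); the coefficient
    is the largest n_c/m.  Ties among classes resolve to the
    lexicographically smallest label, for determinism.

    ``count_unannotated_partners`` controls the denominator: by default m is
    the full partner count (unannotated partners dilute the coefficient but
    never contribute to n); set False to restrict m to annotated partners.
    The coefficient is missing when the protein is unannotated or has no
    (counted) partners.
    """
    partners = net.neighbors(p)  # raises KeyError for unknown protein
    own_classes = ann[p]
    if count_unannotated_partners:
        m = len(partners)
    else:
        m = sum(1 for q in partners if ann.is_annotated(q))
    if not own_classes or m == 0:
        return FunctionalityResult(p, None, None, m, 0)
    best_class = None
    best_n = -1
    for c in sorted(own_classes):
        n_c = sum(1 for q in partners if c in ann[q])
        if n_c > best_n:
            best_n = n_c
            best_class = c
    return FunctionalityResult(p, best_n / m, best_class, m, best_n)


def classify_functionality(
    results: Iterable[FunctionalityResult],
    cutoff: Union[float, Literal["mean"]] = "mean",
) -> list[FunctionalityResult]:
    """Attach SF/DF labels using a cutoff on the coefficient of functionality.

    ``cutoff="mean"`` averages the defined coefficients; a coefficient at or
    above the cutoff gives SF, below gives DF, missing stays unclassified.
    """
    results = list(results)
    defined = [r.coefficient for r in results if r.coefficient is not None]
    if cutoff == "mean":
        if not defined:
            raise ValueError("cannot take the mean cutoff: no defined coefficients")
        threshold = sum(defined) / len(defined)
    else:
        threshold = float(cutoff)
    labelled = []
    for r in results:
        if r.coefficient is None:
            label = UNCLASSIFIED
        elif r.coefficient >= threshold:
            label = SF
        else:
            label = DF
        labelled.append(
            FunctionalityResult(r.protein, r.coefficient, r.assigned_class, r.m, r.n, label)
        )
    return labelled
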