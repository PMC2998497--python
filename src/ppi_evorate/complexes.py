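"""Protein-complex catalog: complex number and complex-forming status.

A protein's *complex number* is the count of complexes in which it appears
as a subunit; a protein is complex-forming iff that count is at least one.
Proteins absent from the catalog are non-complex-forming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Union

logger = logging.getLogger(__name__)


@dataclass
class ComplexCatalog:
    """Mapping complex ID -> set of member protein IDs."""

    members: dict[str, set[str]] = field(default_factory=dict)

    def add(self, complex_id: str, protein: str) -> None:
        self.members.setdefault(complex_id, set()).add(protein)

    @property
    def n_complexes(self) -> int:
        return len(self.members)

    def complex_number(self, protein: str) -> int:
        """Number of complexes containing ``protein`` (0 if absent)."""
        return sum(1 for m in self.members.values() if protein in m)

    def is_complex_forming(self, protein: str) -> bool:
        return any(protein in m for m in self.members.values())

    def complex_numbers(self) -> dict[str, int]:
        """Complex number for every protein that appears in the catalog."""
        counts: dict[str, int] = {}
        for m in self.members.values():
            for p in m:
                counts[p] = counts.get(p, 0) + 1
        return counts


def read_complex_catalog(source: Union[str, Path, IO[str]]) -> ComplexCatalog:
    """Read a (complex_id, protein_id) TSV; duplicate memberships collapse."""
    if isinstance(source, (str, Path)):
        with open(source, "rt", encoding="utf-8") as handle:
            return read_complex_catalog(handle)
    cat = ComplexCatalog()
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected (complex_id, protein_id)")
        cid, protein = fields[0].strip(), fields[1].strip()
        if lineno == 1 and protein.lower() in {"protein_id", "member", "protein"}:
            continue
        if not cid or not protein:
            logger.warning("line %d: empty field, skipped", lineno)
            continue
        cat.add(cid, protein)
    return cat


def complex_number(cat: ComplexCatalog, p: str) -> int:
    return cat.complex_number(p)


def is_complex_forming(cat: ComplexCatalog, p: str) -> bool:
    return cat.is_complex_forming(p)
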