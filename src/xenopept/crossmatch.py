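"""Cross-species shared-peptide filtering under I/L equivalence.

In an orthotopic xenograft, tumor tissue is graft-derived (e.g. human) and
control tissue host-derived (e.g. mouse), so identifications are made
against two different proteome databases.  Label-free counts are only
comparable for peptides whose sequence occurs in BOTH theoretical digests,
treating isoleucine and leucine as interchangeable (they are isobaric and
cannot be distinguished by standard fragmentation).

Comparability is checked against the theoretical digests of the two
proteomes by default; an observed-list intersection is also provided for
sensitivity analysis.  For endogenous (no-enzyme) peptides comparability is
substring containment, handled by :class:`SubstringMatcher`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

from .digest import DigestParams, PeptideIndex, ProteinRecord, canonicalize_il

if TYPE_CHECKING:  # pragma: no cover
    from .evidence import PsmRecord

__all__ = [
    "SharedPeptideSet",
    "shared_peptide_set",
    "shared_from_observed",
    "is_comparable",
    "filter_to_comparable",
    "SubstringMatcher",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SharedPeptideSet:
    """Canonical peptides present in both species' digests."""

    peptides: frozenset[str]
    params: DigestParams | None = None

    def __contains__(self, canonical: str) -> bool:
        return canonical in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)


def shared_peptide_set(
    index_a: PeptideIndex, index_b: PeptideIndex
) -> SharedPeptideSet:
    """Intersect two canonical peptide indexes.

    Keys are already I/L-canonical, so peptides differing only by I<->I/L
    swaps intersect.  Symmetric in argument order.  Raises ``ValueError``
    when the indexes were built with different digest parameters (their
    peptide universes would not be comparable).
    """
    if index_a.params != index_b.params:
        raise ValueError(
            "peptide indexes built with different digest parameters are not "
            f"comparable: {index_a.params} vs {index_b.params}"
        )
    shared = frozenset(index_a.mapping.keys() & index_b.mapping.keys())
    return SharedPeptideSet(peptides=shared, params=index_a.params)


def shared_from_observed(
    peptides_a: Iterable[str], peptides_b: Iterable[str]
) -> SharedPeptideSet:
    """Intersection of two OBSERVED peptide lists (canonicalized).

    Alternative to the theoretical-digest intersection for sensitivity
    analysis: comparability is then 'identified in both datasets' rather
    than 'encoded in both proteomes'.
    """
    set_a = {canonicalize_il(p) for p in peptides_a}
    set_b = {canonicalize_il(p) for p in peptides_b}
    return SharedPeptideSet(peptides=frozenset(set_a & set_b), params=None)


def is_comparable(peptide: str, shared: SharedPeptideSet) -> bool:
    """True iff the peptide's canonical form is in the shared set."""
    return canonicalize_il(peptide) in shared


def filter_to_comparable(
    evidence: Sequence["PsmRecord"], shared: SharedPeptideSet
) -> list["PsmRecord"]:
    """Retain exactly the records whose peptide is species-comparable.

    Order-preserving and idempotent; the number of removed records is
    logged at INFO level.
    """
    kept = [rec for rec in evidence if is_comparable(rec.peptide, shared)]
    removed = len(evidence) - len(kept)
    logger.info(
        "cross-species filter: retained %d of %d records (%d removed)",
        len(kept), len(evidence), removed,
    )
    return kept


class SubstringMatcher:
    """Canonical substring search over a proteome, for endogenous peptides.

    Endogenous cleavage peptides carry no tryptic termini, so cross-species
    comparability (and parent-protein mapping) is containment of the
    I/L-canonical peptide anywhere in a protein sequence.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self._accessions: list[str] = []
        self._canonical: list[str] = []
        for rec in records:
            self._accessions.append(rec.accession)
            self._canonical.append(canonicalize_il(rec.sequence))
        # concatenated text with a separator never found in sequences,
        # for fast any-match queries
        self._text = "\x00".join(self._canonical)

    def contains(self, peptide: str) -> bool:
        """True iff some protein contains the canonical peptide."""
        return canonicalize_il(peptide) in self._text

    def parents(self, peptide: str) -> list[str]:
        """Accessions of all proteins containing the canonical peptide."""
        key = canonicalize_il(peptide)
        return [
            acc
            for acc, seq in zip(self._accessions, self._canonical)
            if key in seq
        ]
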