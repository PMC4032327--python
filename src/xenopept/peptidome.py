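"""Endogenous-peptidome (degradome) branch of the pipeline.

Endogenous cleavage peptides are products of in vivo proteolysis, acquired
without enzymatic digestion and searched with no enzyme specificity, so
parent-protein mapping and cross-species comparability are substring
containment of the I/L-canonical peptide rather than tryptic-index lookup.
Datasets are partitioned by fragmentation mode (CID, HCD, ETD) and each
mode is analyzed independently with the same unique-peptide counting and
FC + Fisher statistics as the tryptic proteome branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .crossmatch import SubstringMatcher
from .digest import ProteinRecord
from .evidence import CountMatrix, PsmRecord, count_unique_peptides
from .stats import DiffRecord, test_all_proteins

__all__ = [
    "FRAGMENTATION_MODES",
    "ModeDataset",
    "map_endogenous",
    "filter_endogenous_comparable",
    "mode_count_matrix",
    "test_mode",
]

FRAGMENTATION_MODES = ("CID", "HCD", "ETD")


@dataclass
class ModeDataset:
    """Endogenous-peptide evidence from one fragmentation mode."""

    mode: str
    records: list[PsmRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in FRAGMENTATION_MODES:
            raise ValueError(
                f"mode must be one of {FRAGMENTATION_MODES}, got {self.mode!r}"
            )

    def __len__(self) -> int:
        return len(self.records)


def map_endogenous(
    peptide: str, proteome: SubstringMatcher | Iterable[ProteinRecord]
) -> list[str]:
    """All proteins containing the canonical peptide as a substring.

    No cleavage constraint applies; an I/L-rewritten query returns the same
    parents.  Returns an empty list when no protein matches.
    """
    matcher = (
        proteome
        if isinstance(proteome, SubstringMatcher)
        else SubstringMatcher(proteome)
    )
    return matcher.parents(peptide)


def filter_endogenous_comparable(
    records: Sequence[PsmRecord],
    proteome_a: SubstringMatcher | Iterable[ProteinRecord],
    proteome_b: SubstringMatcher | Iterable[ProteinRecord],
) -> list[PsmRecord]:
    """Retain endogenous PSMs whose peptide occurs in BOTH proteomes.

    Substring containment under I/L canonicalization replaces the tryptic
    shared-peptide set: endogenous peptides carry no enzyme termini.
    """
    m_a = (
        proteome_a
        if isinstance(proteome_a, SubstringMatcher)
        else SubstringMatcher(proteome_a)
    )
    m_b = (
        proteome_b
        if isinstance(proteome_b, SubstringMatcher)
        else SubstringMatcher(proteome_b)
    )
    return [
        rec
        for rec in records
        if m_a.contains(rec.peptide) and m_b.contains(rec.peptide)
    ]


def mode_count_matrix(
    dataset: ModeDataset, grouping: Mapping[str, str], *, mode: str = "unique_peptides"
) -> CountMatrix:
    """Distinct endogenous peptide sequences per parent protein per sample."""
    if not dataset.records:
        raise ValueError(f"empty {dataset.mode} dataset")
    return count_unique_peptides(dataset.records, grouping, mode=mode)


def test_mode(
    dataset: ModeDataset,
    grouping: Mapping[str, str],
    *,
    fc_cut: float = 2.0,
    alpha: float = 0.05,
) -> list[DiffRecord]:
    """Per-protein FC + Fisher on one fragmentation mode's counts.

    Each mode is analyzed independently; results for one mode do not
    depend on the presence of any other.
    """
    matrix = mode_count_matrix(dataset, grouping)
    return test_all_proteins(matrix, fc_cut=fc_cut, alpha=alpha)


test_mode.__test__ = False  # statistical routine, not a pytest case
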