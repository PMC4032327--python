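"""In silico tryptic digestion and I/L-canonicalized peptide indexing.

Proteome FASTA files are digested with the trypsin rule (cleave C-terminal
to K or R, by default suppressed when the next residue is proline) allowing
a configurable number of missed cleavages.  Because isoleucine and leucine
are isobaric and indistinguishable by CID/HCD fragmentation, peptides are
indexed under an I/L-canonical form (every I rewritten to L) so that
cross-species peptide matching treats I<->L differences as identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "STANDARD_AA",
    "ProteinRecord",
    "DigestParams",
    "PeptideIndex",
    "FastaParseError",
    "read_fasta",
    "canonicalize_il",
    "digest_protein",
    "build_peptide_index",
    "write_index_tsv",
    "read_index_tsv",
]

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CANON_TABLE = str.maketrans("I", "L")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome database entry.

    Attributes
    ----------
    accession:
        Unique identifier (first whitespace-delimited token of the header).
    description:
        Remainder of the header line (may be empty).
    sequence:
        Uppercase amino-acid string.
    """

    accession: str
    description: str
    sequence: str

    @property
    def nonstandard_residues(self) -> frozenset[str]:
        """Residue letters outside the 20 standard amino acids (B, Z, X, U...)."""
        return frozenset(self.sequence) - STANDARD_AA


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in silico tryptic digest.

    max_missed_cleavages=1 mirrors the common database-search setting for
    tryptic proteome data; min/max length bound the peptides to the range
    typically detectable by LC-MS/MS.
    """

    max_missed_cleavages: int = 1
    min_length: int = 6
    max_length: int = 50
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")


@dataclass(frozen=True)
class DigestPeptide:
    """A digest product: sequence, 0-based start, missed-cleavage count."""

    peptide: str
    start: int
    missed: int

    @property
    def has_nonstandard(self) -> bool:
        return bool(frozenset(self.peptide) - STANDARD_AA)


def canonicalize_il(peptide: str) -> str:
    """Return the I/L-canonical form of *peptide* (every I rewritten to L).

    Idempotent and length-preserving; non-I characters pass through
    unchanged.  'L' is the (arbitrary but fixed) canonical letter.
    """
    return peptide.translate(_CANON_TABLE)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved.  Raises :class:`FastaParseError` (naming the offending line)
    for sequence data before the first header, an empty sequence, or a
    duplicate accession.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        sequence = "".join(chunks)
        if not sequence:
            raise FastaParseError(
                f"{path}: empty sequence for record at line {header_line}"
            )
        token = header.split(None, 1)
        accession = token[0]
        description = token[1] if len(token) > 1 else ""
        if accession in seen:
            raise FastaParseError(
                f"{path}: duplicate accession {accession!r} at line {header_line} "
                f"(first seen at line {seen[accession]})"
            )
        seen[accession] = header_line
        records.append(ProteinRecord(accession, description, sequence))

    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append("".join(line.split()).upper())
    flush()
    return records


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based positions i such that trypsin cleaves between i and i+1.

    Cleavage occurs C-terminal to K or R; with the proline rule, not when
    position i+1 is P.  The sequence terminus is not a site.
    """
    sites = []
    last = len(sequence) - 1
    for i, aa in enumerate(sequence):
        if aa in "KR" and i < last:
            if proline_rule and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest_protein(
    record: ProteinRecord, params: DigestParams
) -> list[DigestPeptide]:
    """Digest one protein, returning peptides in sequence order.

    Peptides with 0..max_missed_cleavages retained internal sites are
    emitted; the length filter is applied last.  Peptides containing
    non-standard residues are emitted (callers may check
    :attr:`DigestPeptide.has_nonstandard`), never silently dropped.
    """
    seq = record.sequence
    if not seq:
        return []
    sites = cleavage_sites(seq, params.proline_rule)
    # fragment boundaries of the 0-missed digest, half-open [start, end)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    n_frag = len(bounds) - 1
    out: list[DigestPeptide] = []
    for i in range(n_frag):
        start = bounds[i]
        for missed in range(params.max_missed_cleavages + 1):
            j = i + missed + 1
            if j > n_frag:
                break
            end = bounds[j]
            if params.min_length <= end - start <= params.max_length:
                out.append(DigestPeptide(seq[start:end], start, missed))
    out.sort(key=lambda p: (p.start, p.missed))
    return out


@dataclass
class PeptideIndex:
    """Lookup from I/L-canonical peptide to its proteome occurrences.

    ``mapping`` maps each canonical peptide string to the set of
    ``(accession, start, missed)`` tuples at which some peptide with that
    canonical form occurs.  ``params`` records the digest settings, so that
    two indexes can be checked for comparability before intersection.
    """

    params: DigestParams
    mapping: dict[str, set[tuple[str, int, int]]] = field(default_factory=dict)

    def add(self, peptide: str, accession: str, start: int, missed: int) -> None:
        key = canonicalize_il(peptide)
        self.mapping.setdefault(key, set()).add((accession, start, missed))

    def __contains__(self, peptide: str) -> bool:
        return canonicalize_il(peptide) in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def keys(self):
        return self.mapping.keys()

    def occurrences(self, peptide: str) -> set[tuple[str, int, int]]:
        return self.mapping.get(canonicalize_il(peptide), set())


def build_peptide_index(
    records: Iterable[ProteinRecord], params: DigestParams
) -> PeptideIndex:
    """Digest every record and build the canonical peptide index."""
    records = list(records)
    if not records:
        raise ValueError("cannot build a peptide index from zero records")
    index = PeptideIndex(params=params)
    for rec in records:
        for pep in digest_protein(rec, params):
            index.add(pep.peptide, rec.accession, pep.start, pep.missed)
    return index


def write_index_tsv(index: PeptideIndex, path: str | Path) -> None:
    """Serialize an index as tab-separated (canonical_peptide, accession, start, missed)."""
    with Path(path).open("w") as handle:
        handle.write("canonical_peptide\taccession\tstart\tmissed\n")
        for key in sorted(index.mapping):
            for accession, start, missed in sorted(index.mapping[key]):
                handle.write(f"{key}\t{accession}\t{start}\t{missed}\n")


def read_index_tsv(path: str | Path, params: DigestParams) -> PeptideIndex:
    """Read an index written by :func:`write_index_tsv`.

    ``params`` must be supplied by the caller (the TSV stores occurrences
    only); they are attached for comparability checks.
    """
    index = PeptideIndex(params=params)
    with Path(path).open() as handle:
        header = handle.readline()
        if not header.startswith("canonical_peptide"):
            raise ValueError(f"{path}: not a peptide index file")
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            key, accession, start, missed = fields
            index.mapping.setdefault(key, set()).add(
                (accession, int(start), int(missed))
            )
    return index
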