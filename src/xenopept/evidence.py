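"""PSM evidence tables, xcorr/FDR filtering and unique-peptide counting.

The evidence dialect is a tab-separated table with header
``sample\taccessions\tpeptide\tcharge\txcorr\tis_decoy``; multiple
accessions in one cell are ';'-delimited and the decoy flag is 0/1.

Identification filtering follows the common Sequest/Scaffold convention:
charge-dependent xcorr cutoffs (strict '>'), then a global score cut chosen
so the target-decoy estimated FDR does not exceed a ceiling (1% by
default).  Quantification is by unique-peptide counting: the number of
DISTINCT I/L-canonical peptide sequences per protein per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digest import canonicalize_il

__all__ = [
    "EVIDENCE_COLUMNS",
    "PsmRecord",
    "FilterParams",
    "CountMatrix",
    "read_evidence_table",
    "write_evidence_table",
    "pass_xcorr",
    "filter_by_xcorr",
    "apply_fdr_threshold",
    "count_unique_peptides",
]

logger = logging.getLogger(__name__)

EVIDENCE_COLUMNS = ("sample", "accessions", "peptide", "charge", "xcorr", "is_decoy")

#: Charge-dependent Sequest xcorr cutoffs: +1>1.8, +2>2.2, +3>2.5, +4>3.5.
DEFAULT_XCORR_THRESHOLDS: dict[int, float] = {1: 1.8, 2: 2.2, 3: 2.5, 4: 3.5}


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match."""

    sample_id: str
    accessions: tuple[str, ...]
    peptide: str
    charge: int
    xcorr: float
    is_decoy: bool = False
    row: int | None = None  # source row for diagnostics

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("PSM peptide must be non-empty")
        if self.charge < 1:
            raise ValueError(f"PSM charge must be >= 1, got {self.charge}")
        if self.xcorr < 0:
            raise ValueError(f"PSM xcorr must be non-negative, got {self.xcorr}")


@dataclass(frozen=True)
class FilterParams:
    """Identification-filtering parameters.

    ``fdr_estimator``: 'd_over_t' (#decoys/#targets, concatenated
    target-decoy, conservative) or '2d_over_all' (2D/(T+D)).
    """

    xcorr_thresholds: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_XCORR_THRESHOLDS)
    )
    fdr_max: float = 0.01
    fdr_estimator: str = "d_over_t"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")
        if any(t <= 0 for t in self.xcorr_thresholds.values()):
            raise ValueError("xcorr thresholds must be positive")
        if self.fdr_estimator not in ("d_over_t", "2d_over_all"):
            raise ValueError(f"unknown fdr_estimator {self.fdr_estimator!r}")

    def threshold_for(self, charge: int) -> float:
        """Threshold for a charge; charges above the largest key inherit its cutoff."""
        if charge in self.xcorr_thresholds:
            return self.xcorr_thresholds[charge]
        top = max(self.xcorr_thresholds)
        if charge > top:
            return self.xcorr_thresholds[top]
        raise KeyError(f"no xcorr threshold for charge {charge}")


def read_evidence_table(path: str | Path) -> list[PsmRecord]:
    """Parse one evidence TSV into PSM records.

    Raises ``ValueError`` naming the file, column and data row for a
    missing column or a non-numeric charge/xcorr cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            charge = int(row.charge)
            xcorr = float(row.xcorr)
            decoy = int(row.is_decoy)
        except ValueError as exc:
            raise ValueError(f"{path}: bad numeric field at row {i}: {exc}") from None
        if decoy not in (0, 1):
            raise ValueError(f"{path}: is_decoy must be 0/1 at row {i}")
        accessions = tuple(a for a in row.accessions.split(";") if a)
        if not accessions:
            raise ValueError(f"{path}: empty accession cell at row {i}")
        records.append(
            PsmRecord(
                sample_id=row.sample,
                accessions=accessions,
                peptide=row.peptide,
                charge=charge,
                xcorr=xcorr,
                is_decoy=bool(decoy),
                row=i,
            )
        )
    return records


def write_evidence_table(records: Iterable[PsmRecord], path: str | Path) -> None:
    """Write PSM records in the evidence dialect (stable field order)."""
    with Path(path).open("w") as handle:
        handle.write("\t".join(EVIDENCE_COLUMNS) + "\n")
        for rec in records:
            handle.write(
                f"{rec.sample_id}\t{';'.join(rec.accessions)}\t{rec.peptide}\t"
                f"{rec.charge}\t{rec.xcorr:.4f}\t{int(rec.is_decoy)}\n"
            )


def pass_xcorr(record: PsmRecord, params: FilterParams) -> bool:
    """True iff xcorr STRICTLY exceeds the threshold for the record's charge."""
    return record.xcorr > params.threshold_for(record.charge)


def filter_by_xcorr(
    records: Sequence[PsmRecord], params: FilterParams
) -> list[PsmRecord]:
    """Apply the charge-dependent xcorr cutoffs; order-preserving."""
    return [rec for rec in records if pass_xcorr(rec, params)]


def apply_fdr_threshold(
    records: Sequence[PsmRecord], params: FilterParams
) -> tuple[list[PsmRecord], float, float]:
    """Choose the lowest global score cut meeting the FDR ceiling.

    Candidate cuts are the observed xcorr values; a record is retained when
    ``xcorr >= cut``.  The lowest cut whose estimated FDR (#decoys/#targets
    by default) is <= ``params.fdr_max`` is selected, decoys are removed
    from the returned set, and ``(retained_targets, estimated_fdr, cut)``
    is returned.  Raises ``ValueError`` (reporting the best achievable FDR)
    when no cut reaches the ceiling.

    The result does not depend on input order: records are ranked by
    descending xcorr and FDR is a function of the cut only.
    """
    records = list(records)
    if not records:
        return [], 0.0, 0.0

    ranked = sorted(records, key=lambda r: -r.xcorr)
    n_targets = 0
    n_decoys = 0
    best: tuple[float, float] | None = None  # (cut, fdr) with lowest cut so far
    best_fdr = float("inf")
    i = 0
    n = len(ranked)
    while i < n:
        cut = ranked[i].xcorr
        # absorb ties: all records with the same score fall on one side
        while i < n and ranked[i].xcorr == cut:
            n_decoys += int(ranked[i].is_decoy)
            n_targets += int(not ranked[i].is_decoy)
            i += 1
        if n_targets == 0:
            fdr = float("inf") if n_decoys else 0.0
        elif params.fdr_estimator == "2d_over_all":
            fdr = 2 * n_decoys / (n_targets + n_decoys)
        else:
            fdr = n_decoys / n_targets
        best_fdr = min(best_fdr, fdr)
        if fdr <= params.fdr_max:
            best = (cut, fdr)  # keep lowering the cut while FDR holds
    if best is None:
        raise ValueError(
            f"no score cut achieves FDR <= {params.fdr_max}; "
            f"best achievable FDR is {best_fdr:.4f}"
        )
    cut, fdr = best
    retained = [r for r in records if r.xcorr >= cut and not r.is_decoy]
    logger.info(
        "FDR gate: cut=%.4f, estimated FDR=%.4f, %d targets retained",
        cut, fdr, len(retained),
    )
    return retained, fdr, cut


@dataclass
class CountMatrix:
    """Protein x sample unique-peptide counts with group labels.

    ``counts`` is an integer DataFrame (rows = accessions, columns =
    sample ids); ``groups`` maps every sample to its condition label
    ('control'/'tumor'); ``shared_proteins`` flags accessions that received
    counts from multi-mapped peptides.
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    shared_proteins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.counts.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def to_tsv(self, path: str | Path) -> None:
        """Write counts as TSV with a '#group' header row above the data."""
        with Path(path).open("w") as handle:
            cols = list(self.counts.columns)
            handle.write("#group\t" + "\t".join(self.groups[s] for s in cols) + "\n")
            handle.write("accession\t" + "\t".join(cols) + "\n")
            for acc, row in self.counts.iterrows():
                flag = "*" if acc in self.shared_proteins else ""
                handle.write(acc + flag + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        with path.open() as handle:
            group_line = handle.readline().rstrip("\n").split("\t")
            if group_line[0] != "#group":
                raise ValueError(f"{path}: missing '#group' header row")
            df = pd.read_csv(handle, sep="\t", index_col=0)
        groups = dict(zip(df.columns, group_line[1:]))
        shared = frozenset(a[:-1] for a in df.index if a.endswith("*"))
        df.index = [a[:-1] if a.endswith("*") else a for a in df.index]
        return cls(counts=df.astype(int), groups=groups, shared_proteins=shared)


def count_unique_peptides(
    records: Sequence[PsmRecord],
    grouping: Mapping[str, str],
    *,
    mode: str = "unique_peptides",
    exclude_shared: bool = False,
) -> CountMatrix:
    """Build the protein x sample count matrix from filtered evidence.

    ``mode='unique_peptides'`` counts DISTINCT I/L-canonical peptide
    sequences per protein per sample (spectral redundancy does not inflate
    counts); ``mode='spectral_counts'`` counts PSM rows instead.  A peptide
    listing several accessions increments each of them (those proteins are
    flagged), unless ``exclude_shared`` drops multi-mapped peptides.

    Raises ``ValueError`` for a sample id absent from ``grouping``.
    """
    if mode not in ("unique_peptides", "spectral_counts"):
        raise ValueError(f"unknown counting mode {mode!r}")
    cells: dict[tuple[str, str], set[str] | int] = {}
    shared: set[str] = set()
    accessions_seen: dict[str, None] = {}
    for rec in records:
        if rec.sample_id not in grouping:
            raise ValueError(f"sample {rec.sample_id!r} has no group label")
        if rec.is_decoy:
            continue
        if exclude_shared and len(rec.accessions) > 1:
            continue
        if len(rec.accessions) > 1:
            shared.update(rec.accessions)
        key_pep = canonicalize_il(rec.peptide)
        for acc in rec.accessions:
            accessions_seen.setdefault(acc, None)
            cell = (acc, rec.sample_id)
            if mode == "unique_peptides":
                cells.setdefault(cell, set()).add(key_pep)  # type: ignore[union-attr]
            else:
                cells[cell] = cells.get(cell, 0) + 1  # type: ignore[operator]

    samples = list(grouping)
    proteins = list(accessions_seen)
    data = {
        s: [
            (len(cells[(p, s)]) if mode == "unique_peptides" else cells[(p, s)])
            if (p, s) in cells
            else 0
            for p in proteins
        ]
        for s in samples
    }
    counts = pd.DataFrame(data, index=proteins, dtype=int)
    return CountMatrix(
        counts=counts, groups=dict(grouping), shared_proteins=frozenset(shared)
    )
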