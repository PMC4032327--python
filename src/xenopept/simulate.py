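"""Seeded generators for paired proteomes, PSM evidence and annotations.

The simulator emulates the design of an orthotopic xenograft spectral-
counting study: a graft-species proteome and a host-species proteome whose
orthologs diverge partly by I<->L swaps only; 3 control + 3 tumor samples;
per-protein unique-peptide counts with Poisson dispersion around a baseline
mean; a planted fraction of proteins with known fold changes (up and down);
and decoy PSMs whose xcorr scores are drawn from a lower distribution than
true matches.  All randomness flows from a single seeded generator, so
every output is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .digest import (
    DigestParams,
    ProteinRecord,
    build_peptide_index,
    canonicalize_il,
    digest_protein,
)
from .crossmatch import shared_peptide_set
from .evidence import CountMatrix, PsmRecord, write_evidence_table

__all__ = [
    "SimConfig",
    "GroundTruth",
    "random_proteome",
    "mutate_proteome",
    "simulate_count_matrix",
    "simulate_shifted_matrix",
    "simulate_evidence",
    "write_simulation",
]

# Approximate vertebrate proteome amino-acid frequencies; keeps K+R (tryptic
# sites) and I/L content realistic so digests and I/L swaps behave like real
# sequences.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [
        0.070, 0.023, 0.047, 0.071, 0.036, 0.066, 0.026, 0.044, 0.057, 0.100,
        0.021, 0.036, 0.063, 0.048, 0.056, 0.083, 0.054, 0.060, 0.012, 0.027,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_STANDARD = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulator.

    Defaults mirror the emulated study: 3 replicates per condition, a mean
    of ~10 unique peptides per protein, 10% of proteins planted at 4-fold
    (half up, half down), host/graft proteomes diverging at ~8% of residues
    with a fifth of substitutions being I<->L swaps (I and L together are
    ~15% of residues, so ortholog divergence is rich in I/L exchanges).
    """

    seed: int = 0
    n_proteins: int = 500
    protein_length: tuple[int, int] = (150, 600)
    substitution_rate: float = 0.08
    il_swap_fraction: float = 0.2
    n_replicates: int = 3
    baseline_lambda: float = 10.0
    de_fraction: float = 0.10
    fold_range: tuple[float, float] = (4.0, 4.0)
    decoy_fraction: float = 0.05
    xcorr_true_shift: float = 0.3   # scale of exp. excess over the charge cutoff
    xcorr_decoy_mean: float = 1.2   # mean of the decoy score distribution
    dispersion: float | None = None  # None = Poisson; else NB with this size

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "il_swap_fraction", "de_fraction", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.baseline_lambda <= 0:
            raise ValueError("baseline_lambda must be > 0")
        if self.n_replicates < 1 or self.n_proteins < 1:
            raise ValueError("n_replicates and n_proteins must be >= 1")
        lo, hi = self.fold_range
        if not 0 < lo <= hi:
            raise ValueError("fold_range must satisfy 0 < lo <= hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("protein_length", "fold_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["protein_length"] = list(self.protein_length)
        raw["fold_range"] = list(self.fold_range)
        with Path(path).open("w") as handle:
            yaml.safe_dump(raw, handle, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted effects, for recovery tests.

    ``proteins`` has one row per protein: accession, planted fold change
    (1.0 for nulls), direction ('up'/'down'/'none') and the number of
    species-shared peptides available to sample from.  PSM-level truth is
    the ``is_decoy`` flag on the emitted evidence rows.
    """

    proteins: pd.DataFrame

    def planted(self, direction: str | None = None) -> pd.DataFrame:
        df = self.proteins[self.proteins["direction"] != "none"]
        if direction is not None:
            df = df[df["direction"] == direction]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.proteins.to_csv(path, sep="\t", index=False)


def random_proteome(
    rng: np.random.Generator,
    n_proteins: int,
    length_range: tuple[int, int] = (150, 600),
    prefix: str = "GRAFT",
) -> list[ProteinRecord]:
    """Random protein sequences with realistic residue frequencies."""
    lo, hi = length_range
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AA, size=length, p=_AA_FREQ))
        records.append(ProteinRecord(f"{prefix}{i:05d}", "synthetic protein", seq))
    return records


def mutate_proteome(
    source: list[ProteinRecord],
    config: SimConfig,
    rng: np.random.Generator,
    prefix: str = "HOST",
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Derive a second-species proteome by per-residue substitution.

    Each residue is substituted with probability ``substitution_rate``.  At
    I/L sites, a fraction ``il_swap_fraction`` of substitutions is the
    I<->L swap (the isobaric exchange invisible to MS); all other
    substitutions draw uniformly from the 19 remaining standard residues.
    Returns the mutated records and a per-protein table of realized
    substitution and swap counts.
    """
    if not source:
        raise ValueError("source proteome is empty")
    if config.substitution_rate == 1.0 and config.il_swap_fraction == 1.0:
        if not any(set("IL") & set(rec.sequence) for rec in source):
            raise ValueError(
                "substitution_rate=1 with il_swap_fraction=1 requires I/L sites"
            )
    mutated: list[ProteinRecord] = []
    stats_rows = []
    for i, rec in enumerate(source):
        seq = np.array(list(rec.sequence))
        n = len(seq)
        hit = rng.random(n) < config.substitution_rate
        u = rng.random(n)
        n_sub = 0
        n_swap = 0
        for j in np.flatnonzero(hit):
            aa = seq[j]
            if aa in "IL" and u[j] < config.il_swap_fraction:
                seq[j] = "L" if aa == "I" else "I"
                n_swap += 1
            else:
                choices = _STANDARD.replace(aa, "") if aa in _STANDARD else _STANDARD
                seq[j] = choices[rng.integers(len(choices))]
            n_sub += 1
        mutated.append(
            ProteinRecord(f"{prefix}{i:05d}", f"ortholog of {rec.accession}", "".join(seq))
        )
        stats_rows.append(
            {"accession": rec.accession, "n_residues": n, "n_sub": n_sub, "n_il_swap": n_swap}
        )
    return mutated, pd.DataFrame(stats_rows)


def _plant_effects(
    accessions: list[str], config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose planted proteins and their fold changes (half up, half down)."""
    n = len(accessions)
    n_de = int(round(config.de_fraction * n))
    idx = rng.choice(n, size=n_de, replace=False)
    folds = np.ones(n)
    direction = np.array(["none"] * n, dtype=object)
    lo, hi = config.fold_range
    planted_folds = rng.uniform(lo, hi, size=n_de)
    up_mask = np.zeros(n_de, dtype=bool)
    up_mask[: n_de // 2 + n_de % 2] = True  # first half up, rest down
    for k, i in enumerate(idx):
        if up_mask[k]:
            folds[i] = planted_folds[k]
            direction[i] = "up"
        else:
            folds[i] = 1.0 / planted_folds[k]
            direction[i] = "down"
    return pd.DataFrame({"accession": accessions, "fold": folds, "direction": direction})


def _draw_counts(
    lam: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson counts by default; negative-binomial when dispersion is set."""
    if config.dispersion is None:
        return rng.poisson(lam)
    size = config.dispersion
    p = size / (size + lam)
    return rng.negative_binomial(size, p)


def simulate_count_matrix(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Directly simulate the protein x sample unique-peptide count matrix.

    Control counts ~ Poisson(lambda_g); tumor counts ~ Poisson(lambda_g *
    f_g), f_g = 1 for unplanted proteins.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    accessions = [f"PROT{i:05d}" for i in range(config.n_proteins)]
    truth = _plant_effects(accessions, config, rng)
    lam = np.full(config.n_proteins, config.baseline_lambda)
    folds = truth["fold"].to_numpy()
    samples = {}
    groups = {}
    for r in range(config.n_replicates):
        name = f"C{r + 1}"
        samples[name] = _draw_counts(lam, config, rng)
        groups[name] = "control"
    for r in range(config.n_replicates):
        name = f"T{r + 1}"
        samples[name] = _draw_counts(lam * folds, config, rng)
        groups[name] = "tumor"
    counts = pd.DataFrame(samples, index=accessions, dtype=int)
    truth["n_shared_peptides"] = pd.NA
    return CountMatrix(counts=counts, groups=groups), GroundTruth(proteins=truth)


def simulate_shifted_matrix(
    n_proteins: int,
    n_replicates: int = 3,
    shift_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Gaussian matrix whose group means differ by ``shift_sd`` within-group sds.

    Emulates the signature of a significant-protein submatrix: every row
    carries a condition shift (random sign) of the stated magnitude.  Used
    for clustering-separation checks where the shift-to-noise ratio must be
    controlled exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    control = rng.normal(0.0, 1.0, size=(n_proteins, n_replicates))
    tumor = rng.normal(0.0, 1.0, size=(n_proteins, n_replicates)) + (
        signs[:, None] * shift_sd
    )
    cols = [f"C{r + 1}" for r in range(n_replicates)] + [
        f"T{r + 1}" for r in range(n_replicates)
    ]
    df = pd.DataFrame(
        np.hstack([control, tumor]),
        index=[f"PROT{i:05d}" for i in range(n_proteins)],
        columns=cols,
    )
    groups = {c: ("control" if c.startswith("C") else "tumor") for c in cols}
    return df, groups


def simulate_evidence(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    digest_params: DigestParams | None = None,
) -> dict:
    """Full forward simulation: proteomes -> digests -> PSM evidence.

    Tumor samples draw peptides from the graft-species digest, control
    samples from the host-species digest, restricted to the species-shared
    canonical peptide set.  Per protein and sample the number of distinct
    peptides is Poisson(lambda * fold) truncated at the protein's shared
    repertoire size; each selected peptide is emitted 1 + Poisson(0.5)
    times (spectral redundancy).  True PSMs get xcorr above their charge
    cutoff; decoys (at ``decoy_fraction`` of true PSM rows) get low scores
    from an exponential distribution.

    Returns a dict with the two proteomes, per-sample PSM records, the
    intended count matrix and the ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if digest_params is None:
        digest_params = DigestParams()

    graft = random_proteome(rng, config.n_proteins, config.protein_length, "GRAFT")
    host, _ = mutate_proteome(graft, config, rng, "HOST")
    index_a = build_peptide_index(graft, digest_params)
    index_b = build_peptide_index(host, digest_params)
    shared = shared_peptide_set(index_a, index_b)

    # per-protein shared peptide repertoires, keyed by graft accession;
    # store the graft-species surface form (tumor evidence) and the host
    # form (control evidence) of each shared canonical peptide
    graft_by_acc: dict[str, list[str]] = {rec.accession: [] for rec in graft}
    host_by_acc: dict[str, list[str]] = {rec.accession: [] for rec in graft}
    for i, (g_rec, h_rec) in enumerate(zip(graft, host)):
        g_peps = {canonicalize_il(p.peptide): p.peptide for p in digest_protein(g_rec, digest_params)}
        h_peps = {canonicalize_il(p.peptide): p.peptide for p in digest_protein(h_rec, digest_params)}
        for key in sorted(g_peps.keys() & h_peps.keys()):
            if key in shared:
                graft_by_acc[g_rec.accession].append(g_peps[key])
                host_by_acc[g_rec.accession].append(h_peps[key])

    truth = _plant_effects([rec.accession for rec in graft], config, rng)
    truth["n_shared_peptides"] = [
        len(graft_by_acc[acc]) for acc in truth["accession"]
    ]
    folds = truth["fold"].to_numpy()

    thresholds = {1: 1.8, 2: 2.2, 3: 2.5, 4: 3.5}
    charge_pool = np.array([2, 2, 2, 3, 3, 1, 4])  # mostly 2+/3+ precursors

    samples: dict[str, list[PsmRecord]] = {}
    intended: dict[str, list[int]] = {}
    sample_groups: dict[str, str] = {}

    def emit_sample(name: str, group: str, lam_vec: np.ndarray, use_graft: bool) -> None:
        records: list[PsmRecord] = []
        col: list[int] = []
        for i, rec in enumerate(graft):
            # one analysis database: all samples report the graft accession,
            # but control samples observe the host-species surface form
            pool = graft_by_acc[rec.accession] if use_graft else host_by_acc[rec.accession]
            acc = rec.accession
            want = int(rng.poisson(lam_vec[i]))
            got = min(want, len(pool))
            col.append(got)
            if got == 0:
                continue
            chosen = rng.choice(len(pool), size=got, replace=False)
            for j in chosen:
                redundancy = 1 + int(rng.poisson(0.5))
                for _ in range(redundancy):
                    charge = int(charge_pool[rng.integers(len(charge_pool))])
                    xcorr = thresholds[charge] + rng.exponential(config.xcorr_true_shift) + 1e-6
                    records.append(
                        PsmRecord(
                            sample_id=name,
                            accessions=(acc,),
                            peptide=pool[j],
                            charge=charge,
                            xcorr=round(xcorr, 4),
                            is_decoy=False,
                        )
                    )
        # decoys: shuffled peptides with low scores
        n_decoys = int(rng.poisson(config.decoy_fraction * max(len(records), 1)))
        for _ in range(n_decoys):
            length = int(rng.integers(7, 20))
            pep = "".join(rng.choice(_AA, size=length, p=_AA_FREQ))
            charge = int(charge_pool[rng.integers(len(charge_pool))])
            xcorr = rng.exponential(config.xcorr_decoy_mean)
            records.append(
                PsmRecord(
                    sample_id=name,
                    accessions=("DECOY_" + pep[:6],),
                    peptide=pep,
                    charge=charge,
                    xcorr=round(float(xcorr), 4),
                    is_decoy=True,
                )
            )
        samples[name] = records
        intended[name] = col
        sample_groups[name] = group

    lam = np.full(config.n_proteins, config.baseline_lambda)
    for r in range(config.n_replicates):
        emit_sample(f"C{r + 1}", "control", lam, use_graft=False)
    for r in range(config.n_replicates):
        emit_sample(f"T{r + 1}", "tumor", lam * folds, use_graft=True)

    # the intended matrix indexes both species' forms by the graft accession
    counts = pd.DataFrame(
        intended, index=[rec.accession for rec in graft], dtype=int
    )
    matrix = CountMatrix(counts=counts, groups=sample_groups)
    return {
        "graft": graft,
        "host": host,
        "shared": shared,
        "samples": samples,
        "matrix": matrix,
        "truth": GroundTruth(proteins=truth),
        "digest_params": digest_params,
    }


def write_simulation(sim: Mapping, out_dir: str | Path, config: SimConfig) -> None:
    """Write a simulation to disk: FASTA x2, evidence TSVs, counts, truth, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, records in (("graft.fasta", sim["graft"]), ("host.fasta", sim["host"])):
        with (out / name).open("w") as handle:
            for rec in records:
                handle.write(f">{rec.accession} {rec.description}\n")
                for i in range(0, len(rec.sequence), 60):
                    handle.write(rec.sequence[i : i + 60] + "\n")
    for sample, records in sim["samples"].items():
        write_evidence_table(records, out / f"evidence_{sample}.tsv")
    sim["matrix"].to_tsv(out / "counts.tsv")
    sim["truth"].to_tsv(out / "truth.tsv")
    config.to_yaml(out / "config.yaml")
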