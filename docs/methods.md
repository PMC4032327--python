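# Methods

## The problem

In an orthotopic xenograft model, tumor tissue grows from grafted cells of
one species inside a host of another, so label-free MS comparisons of tumor
vs control tissue face a database asymmetry: tumor identifications come from
the graft proteome, control identifications from the host proteome. A count
difference can then reflect sequence divergence rather than abundance. The
pipeline restores comparability by restricting all quantification to the
peptide sequences that both theoretical proteome digests contain, with
isoleucine and leucine treated as one letter (they are isobaric; CID/HCD
fragmentation cannot distinguish them). Every peptide is canonicalized by
rewriting I to L ('L' is the fixed canonical letter) before indexing,
intersection, and counting.

## Digestion model

Trypsin cleaves C-terminal to K or R; by default cleavage is suppressed when
the next residue is proline ("full trypsin"). The proline rule is
configurable because database-search engines differ in whether they apply
it. Peptides with up to `max_missed_cleavages` retained internal sites are
emitted (default 1, the usual search setting for tryptic data); the length
filter (defaults 6–50 residues, the range typically detectable by LC-MS/MS)
is applied last so that missed-cleavage composition is exact: every
k-missed peptide is the concatenation of k+1 consecutive 0-missed peptides,
and the 0-missed peptides concatenate back to the protein. Coordinates are
0-based half-open internally. Non-standard residues (B, Z, X, U) are never
silently dropped; peptides containing them carry a flag.

Comparability is checked against the *theoretical* digests of the two
proteomes, not against observed identification lists — "encoded in both
databases" is the defensible reading when the two conditions are searched
against different databases, and it is independent of acquisition depth. An
observed-list intersection (`shared_from_observed`) is provided for
sensitivity analysis.

## Evidence filtering

PSM rows are gated by charge-dependent xcorr cutoffs (+1>1.8, +2>2.2,
+3>2.5, +4>3.5), strict inequalities; charges above 4 inherit the charge-4
cutoff. A global score cut is then chosen as the lowest xcorr such that the
target-decoy estimated FDR among retained PSMs — #decoys/#targets, the
conservative concatenated-search estimator; 2D/(T+D) available by option —
does not exceed the ceiling (default 1%). Decoys are removed from the
returned set. If no cut achieves the ceiling the gate raises an error
reporting the best achievable FDR rather than silently passing everything.

Quantification counts DISTINCT I/L-canonical peptide sequences per protein
per sample ("unique peptides"), so spectral redundancy cannot inflate
counts; a PSM-row ("spectral counts") mode exists as an option. Peptides
mapping to several accessions increment each of them and flag those
proteins; an exclusion mode drops multi-mapped peptides instead.

## Differential statistics

Fold change is `(mean_tumor + 1)/(mean_of_control + 1)` over the replicate
unique-peptide counts; the pseudocount avoids division by zero for proteins
absent from one condition. Significance is a two-tailed Fisher's exact test.
The 2×2 table is built from pooled integer sums per group — protein counts
vs the remainder of the group's total — because Fisher's test requires
integer cells while the published procedure describes only averages; a
rounded-average table mode is provided for sensitivity analysis. The
two-tailed rule is "sum of small p": all support probabilities not
exceeding the observed table's probability are summed, admitting ties
within a relative tolerance of 1e-7 (the convention of the mainstream
statistical environments). Degenerate tables (a zero margin) return p = 1.
Selection uses strict cuts: up if FC > 2.0, down if FC < 0.5 (the
symmetric reciprocal bound), both requiring p < 0.05. No multiplicity
correction is applied by default, matching the procedure the pipeline
reimplements; Benjamini–Hochberg is available (`adjust_bh`).

The implementation evaluates the hypergeometric pmf with SciPy, vectorized
over the support; an exact-rational enumeration oracle (independent of that
code path) bounds the error at 3.3e-16 over every 2×2 table with N ≤ 40.
Conditioning on the margins makes the test exact under a Poisson null, but
on discrete counts it is conservative: null simulations show ~4.5% of
proteins at p < 0.05 rather than the nominal 5%.

## Endogenous peptidome

Endogenous cleavage peptides (the tissue degradome) are measured without
enzymatic digestion and searched with no enzyme specificity, so tryptic
termini carry no information: parent-protein mapping and cross-species
comparability are containment of the canonical peptide anywhere in a
protein sequence. Datasets are partitioned by fragmentation mode (CID, HCD,
ETD) and analyzed independently with the same counting and statistics;
counts are distinct endogenous sequences per parent protein per sample,
mirroring the proteome branch.

## Downstream analysis

Rows (proteins) are standardized to Z-scores with the sample (n−1) standard
deviation; constant rows map to zeros. Significant-protein submatrices are
clustered with Euclidean distance and average linkage (UPGMA), whose merge
heights are monotone non-decreasing; SciPy's agglomerative implementation
is used, including its deterministic tie handling. Term enrichment is a
one-tailed hypergeometric test of the query/term overlap against a
background that defaults to all quantified proteins (not an annotation-wide
universe); the EASE option removes one overlap member (floored at zero)
before testing, giving the conservative variant popularized by annotation
tools. Zero-overlap terms report p = 1.

## Synthetic data

The generators emulate the xenograft study design — 3 control + 3 tumor
samples; unique-peptide counts with Poisson dispersion around a baseline
mean of 10 per protein; 10% of proteins planted with 4-fold effects, half
up and half down; paired proteomes of 500 proteins (150–600 residues,
vertebrate residue frequencies) diverging at 8% of residues, with 20% of
substitutions at I/L sites being the I↔L swap (human/mouse orthologs are
~85–90% identical, and I+L make up ~15% of residues, so isobaric exchanges
are a substantial divergence channel); decoy PSMs at 5% of rows with scores
from a clearly lower distribution (exponential, mean 1.2) than true PSMs
(charge cutoff plus an exponential excess, scale 0.3). All draws flow from
one seeded NumPy generator: outputs are byte-identical given (config,
seed). A negative-binomial option introduces overdispersion for robustness
checks.

Two levels are generated. `simulate_count_matrix` draws the count matrix
directly (control ~ Poisson(λ), tumor ~ Poisson(λ·f)); it is the substrate
for recovery and type-I analyses. `simulate_evidence` is the full forward
model — proteomes → digests → shared set → per-sample PSM rows — and is
validated by a round-trip identity: ingesting its evidence through the
xcorr/FDR/comparability filters reproduces its intended count matrix
exactly. In the forward model a protein cannot yield more distinct peptides
than its shared tryptic repertoire (typically 10–20 for these lengths), so
planted up-regulation saturates at the repertoire size: λ = 10 scaled
4-fold asks for ~40 distinct peptides where only ~15 exist. This
detectability ceiling is a real feature of unique-peptide counting (deeply
sampled proteins cannot double their distinct-peptide count), and it is why
recovery benchmarks run at the matrix level while the forward model is held
to the round-trip identity. `simulate_shifted_matrix` generates Gaussian
matrices with an exactly controlled between-group shift (in units of
within-group standard deviation) for clustering-separation checks, where
the shift-to-noise ratio must be pinned.

What the simulations do not emulate: peptide detectability/ionization
models, retention-time structure, intensity-based quantification, shared
peptides between simulated proteins, and protein-level inference ambiguity.
Passing tests therefore demonstrate correctness of the counting and
statistical machinery under the stated stochastic model, not performance on
any particular real dataset.

## Problem sizes and numerical choices

The exhaustive Fisher comparison enumerates all 135,751 tables with
N ≤ 40 (deduplicated by the row/column/transpose symmetry group to 18,656
representatives). Recovery uses 500 proteins, type-I control 2,000, and
clustering separation 100 replicates of a 40 × 6 matrix — sizes at which
the Monte-Carlo error of the reported fractions is well below the margins
of the bounds they are compared against. Ties in the FDR gate are resolved
by treating equal scores as one block (a cut either keeps or drops all of
them). Clustering rejects non-finite input; Z-scoring requires at least two
samples.

## Known limitations

- The 2×2 pooling choice treats replicates as exchangeable and ignores
  between-replicate overdispersion; with strong overdispersion the Fisher
  test is anti-conservative (the negative-binomial simulator option exists
  to probe this).
- Unique-peptide counting compresses high abundance (repertoire
  saturation); fold changes of deeply covered proteins are underestimated.
- Protein inference is by accession as given in the evidence; no parsimony
  grouping is attempted.
- Enrichment p-values depend entirely on the user-supplied annotation sets;
  no annotation database ships with the package.
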