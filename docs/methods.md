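# Methods

## Generative model

Each simulated species is a 15–45 nt subsequence of a parent reference
(miRNA hairpin product, rRNA, mature or precursor tRNA, piRNA cluster,
snRNA, snoRNA, lncRNA, mRNA, mitochondrial tRNA, or intergenic genome) with
three pieces of chemical ground truth:

* a **terminus state**: one of five 5' chemistries {P, OH, m7G cap, m3G cap,
  ppp} × four 3' chemistries {OH, P, cP, aa} (20 states);
* zero or more **methylation sites** (m1A at A, m3C at C, m1G at G) with a
  per-site stoichiometry in [0, 1] — a given molecule carries the mark with
  that probability;
* an **abundance vector** over conditions (tissues).

A library simulation draws `n_reads` molecules multinomially by abundance,
then applies the treatment plan in the fixed bench order *deacylate →
Cap-Clip → PNK → AlkB*:

| enzyme        | transition                                        |
|---------------|---------------------------------------------------|
| deacylation   | 3'-aa → 3'-OH                                     |
| Cap-Clip      | 5' m7G / m3G / ppp → 5'-P                         |
| T4 PNK        | 5'-OH → 5'-P; 3'-P and 3'-cP → 3'-OH              |
| AlkB mix      | removes each realized methyl mark                 |

Every conversion fires with its enzyme efficiency (default 1.0, i.e.
deterministic; the bench data this emulates showed near-complete
conversion, and lower efficiencies are configurable for robustness tests).
Deacylation is applied in every named treatment group. With all
efficiencies at 1.0 the treatment algebra is idempotent, and the full C+P+A
plan maps every terminus state to the ligatable (5'-P, 3'-OH) — the premise
that the fully treated library is a superset of every reduced library.

Molecules failing the ligation rule (5'-P and 3'-OH required) are discarded
without redraw, so library depth honestly reflects ligatability. Survivors
pass reverse transcription: at each residual methylated site the RT
independently **aborts** with `stop_rate` (default 0.1) or
**misincorporates** with `misinc_rate` (default 0.6, substituting uniformly
among the three other bases — the RT's real substitution spectrum is not
modeled). An aborted cDNA lacks the second adapter complement and cannot
amplify, so stops are modeled as molecule loss, not truncated reads;
stop-driven signal therefore appears downstream only as coverage drop-off,
not as a separate caller. Sequencing error (default 10⁻³ per base) is
applied per molecule on the insert; PCR duplicates (geometric, mean 1.5)
are therefore identical copies, and adapters/UMIs are error-free in the
generator. This choice keeps UMI deduplication exactly invertible
(molecule counts are recovered exactly while the UMI space is unsaturated)
at the cost of not exercising adapter-error salvage in simulation — that
path is unit-tested directly instead.

Reads are emitted as `UMI5(6) + insert + UMI3(6) + 3'-adapter`, truncated to
75 nt, at constant quality Q37; a configurable fraction of reads can be
emitted at Q20 to exercise the quality gate. All randomness flows from a
single seed; per-library child generators are derived from (seed, library
index), so every run is byte-reproducible.

## Default scenario

`default_scenario(seed)` builds ≥120 species (≥8 per parent class) with:

* all 20 terminus-state pairs covered (assigned round-robin over the
  non-miRNA species — a deliberate stress design rather than empirical
  terminus frequencies);
* miRNAs fixed at (5'-P, 3'-OH) and unmethylated, since they anchor the
  cross-library normalization;
* nine methylation sites (3 kinds × stoichiometries 0.25/0.5/1.0) placed on
  reference positions of six tRNAs and the three rRNAs, so that every
  species overlapping a site inherits it at consistent stoichiometry;
* three tissues, with two species per class routed to a single tissue
  (abundance rescaled to keep per-tissue sampling comparable) so that
  TSI = 1 rows exist by construction;
* a toy genome contig carrying the tRNA genes, from which precursor
  references (±100 nt flanks) and intergenic "other" windows are cut;
  intergenic windows are placed clear of the precursor flanks so their
  expected annotation is the genome stage.

What the generator does **not** emulate: ligation sequence bias, RNA
secondary structure, NAD caps, realistic class abundance spectra, realistic
tRNA cloverleaf sequence, or adapter-region sequencing errors. Passing
tests therefore demonstrate correctness of the inference machinery under
the stated generative model, not performance on real libraries.

## Preprocessing

"Quality < 30" is interpreted as mean Phred < 30 over the kept (trimmed)
bases. The 3'-adapter search accepts the leftmost occurrence (full adapter,
or a ≥6 nt prefix reaching the read end) with ≤10% mismatches over the
overlap; candidates are seeded by exact matches of the adapter's first two
8-mers, which finds every occurrence with ≤1 mismatch in its first 16 nt —
occurrences with denser early errors fall through to the length gate.
Reads without an adapter hit are kept and rejected by the length gate
(default insert 15–40 nt; a 16–40 gate is available via configuration)
rather than dropped outright. UMI deduplication is exact-match on the
(insert, UMI-pair) string — no edit-distance clustering — because exact
matching is deterministic and the generator makes no UMI errors.

## Annotation cascade

Stages run in the order miRNA, rRNA, cytosolic tRNA, tRNA precursor, piRNA
cluster, mitochondrial tRNA, lncRNA, snRNA, snoRNA, mRNA, other ncRNA,
genome; the first stage with a hit wins. The miRNA stage demands an exact
match and 16–28 nt (protecting tRNA fragments that resemble miRNAs from
misannotation); the piRNA stage gates at 24–32 nt; all other stages allow
one mismatch. Alignment is ungapped and sense-strand only. Where a
short-read aligner with `-k 1` would return an arbitrary single hit, this
implementation is deterministic: exact beats one-mismatch, then reference
input order, then leftmost offset — verified exhaustively against a
brute-force Hamming scan. One-mismatch candidates are found by the
pigeonhole split (one half of the read must match exactly).

Mature tRNA references are the genomic sequences with `CCA` appended
unconditionally (genomic tRNAs conventionally lack it; a rare genomic CCA
ending merely lengthens the reference), and a `G` prefixed to histidine
tRNAs with the anticodon span shifted by one. Precursors span ±100 nt of
genomic context, clipped at contig edges.

tRNA-fragment typing uses the anticodon loop = anticodon ± 2 nt, a 3 nt
tolerance at the CCA end and a 1 nt tolerance at the 5' end (for the
histidine G): 5'-anchored fragments ending inside the loop are 5'-halves,
ending before it tRF-5s; CCA-anchored fragments starting inside the loop
are 3'-halves, after it tRF-3s; anything else is internal. On precursors,
overlap with the upstream flank gives a 5' leader, with the downstream
flank a 3' trailer. These boundary rules are this package's concretization
of fragment-typing conventions and are configurable.

## Quantification and treatment comparison

RPM uses all cascade-annotated reads (genome stage included) as the
denominator; excluding genome-only reads is a configuration switch. The
miRNA-anchored layer rescales each library so its summed miRNA RPM is 10⁶,
on the premise that miRNA termini and methylation are unaffected by the
treatments; values stay RPM-like ("miRNA-million" scale).

A sequence is **treatment-responsive** when `full ≥ 10` (miRNA-million
units) and `(full + 0.5)/(reduced + 0.5) > 30` on that layer. The fold
threshold of 30 is the protocol's published rule; the pseudocount and
minimum-abundance guard are this package's additions against
zero-denominator and shot-noise calls. The inferred chemistry is purely a
function of the omitted enzyme: PNK → 5'-OH or 3'-P/cP (the assay cannot
separate these), Cap-Clip → 5'-cap or ppp, AlkB → m1A/m3C/m1G. Replicates,
when present, are averaged before the ratio.

The greedy parental grouping repeatedly takes the highest-count unassigned
sequence as a representative and absorbs all unassigned sequences related
to it by substring containment; ties break lexicographically. The
containment rule is one reading of an under-specified published procedure.

## Methylome

Pileups accumulate molecule-count-weighted depth and per-base mismatch
counts from the cascade's ≤1-mismatch alignments; a methylated read with an
additional sequencing error is lost to the pileup (small downward bias). A
site is called when the reference base is A/C/G, depth ≥ 50 in both the
AlkB-omitted and AlkB-treated groups, the untreated mismatch frequency is
≥ 0.10, and AlkB reduces it ≥ 3-fold. These thresholds are package
defaults (the protocol's publication states none) and are configurable.

Stoichiometry is reported as the frequency difference
`f_noAlkB − f_withAlkB`. Under the generative model with stop rate *s*,
misincorporation rate *m* and stoichiometry σ, the expected untreated
frequency is `σ(1−s)m / (σ(1−s) + (1−σ))`, which reduces to `σ·m` at
*s* = 0 — a misincorporation-confounded lower bound on σ. Tests and the
acceptance script check the estimate against `σ·m` with the default
*s* = 0.1, where the dilution term stays within the stated ±0.05 band.

## Atlas statistics

TSI is computed exactly as defined above; it is scale-invariant, 1 for
single-tissue rows and 0 for uniform rows. Enrichment requires TSI > 0.95
plus a class-specific RPM floor in at least one tissue (mitochondrial
tsRNA 70, lncRNA-derived 50, snRNA-derived 50, snoRNA-derived 30, default
20 — the general expression prefilter). Clustering prefilters rows to
RPM > 20 in ≥1 tissue, log₂(x+1)-transforms (the +1 offset handles zeros,
which the published description leaves open), and runs average-linkage
agglomerative clustering on Euclidean distances per class — "average
Euclidean distance" read as average linkage. Rows enter in sorted sequence
order, so the tree is permutation-invariant. The differential rule is a
two-sided Welch t-test (the unequal-variance choice where only "t-test"
was specified) on log₂(RPM+1) with P < 0.05 and linear fold change > 2.
t-SNE is deliberately left as an optional plotting hook, not a tested
operation.

## Problem sizes and numerical choices

The acceptance script and the heavyweight tests run the four-group study at
200,000 reads per library (comfortably resolving 30-fold depletion for
~120 species at ~1,500 molecules each and giving ≥1,000-fold site depth),
the zero-error cascade check at 50,000 reads, the UMI-recovery check at
10,000 molecules (far below saturation of the 4¹² UMI space), and the
aligner-oracle comparison on 1,000 random instances. Degenerate inputs are
errors, not silent results: empty species lists, zero-read libraries,
all-zero expression rows, missing anticodon spans and unknown reference
classes all raise.

## Known limitations

* Stoichiometry estimates are lower bounds confounded by the RT
  misincorporation rate; no deconvolution is attempted.
* Exact-match UMI handling slightly overcounts molecules if UMI-region
  errors were introduced upstream of this package.
* The aligner is ungapped with ≤1 mismatch; reads with two errors (or a
  methylation misincorporation plus an error) go unannotated, a small loss
  the model documents rather than corrects.
* The synthetic scenario's uniform terminus round-robin and flat abundances
  are stress-test conditions, not biological frequencies.
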