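# Methods

This note documents the models, numerical choices and limitations behind
`lncwheat`. Coordinates are 0-based half-open internally and 1-based
inclusive at GFF3 boundaries; that conversion happens only in
`splice.load_alignments` and the generator's GFF writer.

## Classification cascade (`classify`)

The cascade reproduces the standard filtering logic used to separate
lncRNAs from coding transcripts in de novo plant assemblies:

* **Contaminant screen.** Optimal local alignment (match +1, mismatch −1,
  gap −2) against bundled synthetic rRNA/tRNA-like reference sequences; a
  transcript is a contaminant when some alignment reaches 95% identity
  over ≥ 30 columns. Both strands are searched. Transcripts that are more
  than 50% N are reported as unscreenable rather than contaminant.
  Alignment is delegated to `Bio.Align.PairwiseAligner`, which computes
  the same optimum as the full Smith–Waterman matrix; the test suite
  asserts exact score agreement with an independent DP oracle. An optional
  exact-k-mer prefilter (`prefilter_k`) restricts which query/subject pairs
  are aligned at pipeline scale; it can only miss hits far below the
  identity cut-offs, never create them.
* **Repeat masking.** Exact 15-mer seeds shared with the repeat library are
  extended while running identity stays ≥ 90%; covered positions become N.
  N never seeds, so masking is idempotent.
* **ORF rule.** Six-frame scan for maximal start-to-stop ORFs (first ATG of
  each stop-to-stop segment; stop codon included in the length; codons
  containing N neither start nor stop). A transcript passes with an ORF of
  ≥ 240 nt (80 aa). A stop-to-stop mode (`require_start=False`) is
  available because published ORF finders differ in this convention.
* **Ab initio vote.** The coding-potential scorer computes the mean
  in-frame hexamer log-likelihood ratio over the longest ORF (coding
  codon-pair model vs uniform background) plus a small ORF-coverage bonus
  (weight 0.2 × ORF fraction of the transcript); the vote is `score > 0`.
  The hexamer table is derived in closed form from the same GC-biased
  codon model the generator uses, giving a self-consistent benchmark. The
  panel interface accepts additional scorers and passes when **any one**
  votes coding. This scorer stands in for external coding-potential tools;
  the cascade logic, not any particular scorer, is what the package
  reproduces. Protein-domain evidence is not implemented; homology rests
  on sequence-level alignment only.
* **Homology.** The translated longest ORF is aligned against the protein
  reference set (BLOSUM62, gap open −11 / extend −1); pass at ≥ 80%
  identity over ≥ 30 columns. The reported E-value uses the
  Karlin–Altschul form with fixed constants (nucl λ=0.625, K=0.41; prot
  λ=0.267, K=0.041); it is advisory — the identity and length thresholds
  carry every decision.
* **Decision.** contaminant ≻ (coding iff ORF ∧ ab initio ∧ homology) ≻
  (lncRNA iff ¬ORF ∧ ¬ab initio ∧ ¬homology ∧ length > 200 nt) ≻
  ambiguous. The conjunctive reading makes the four classes a disjoint,
  exhaustive partition; mixed-evidence transcripts are deliberately left
  ambiguous rather than forced into either class.

## Expression and differential expression (`express`)

FPKM is `counts·10⁹/(length·library size)` with library size defaulting to
the column sum. The activity threshold scans a grid (0.1–2.0, step 0.1) of
the percentage of transcripts below the cut-off in *every* condition and
returns the interior grid point maximizing the discrete second difference
(the point where the slope of the curve changes); exact ties break toward
the smaller threshold (second differences are rounded to 10⁻⁹ first so
floating-point noise cannot override the tie rule), and a flat or linear
curve falls back to 0.5 FPKM.

The DE test conditions on the per-transcript total count summed over
replicates. With dispersion 0 the control-condition sum is binomial with
success probability equal to the control share of the summed library
sizes; with dispersion d > 0 the conditional law is the normalized product
of two negative-binomial terms (size = replicates/d per condition, means
split by library-size share) evaluated by direct summation over all splits
of the total. The two-sided p-value is the total probability of outcomes
no more likely than the observed one (with a 1+10⁻⁹ tolerance on the pmf
comparison so equal-probability outcomes are included despite rounding).
Dispersion is an explicit parameter (default 0.1) rather than an estimate:
with one pooled library per condition — the design this analysis targets —
dispersion is unidentifiable, and stating it is more honest than fitting
it. log₂FC uses library-size-normalized condition sums with a 0.5
pseudocount so condition-specific transcripts get finite fold changes.
Calls use raw p < 0.001 and |log₂FC| > 2; Benjamini–Hochberg adjustment is
available behind `adjust=True` but off by default for fidelity to raw-p
thresholding.

Normalization is total-count only (TMM is not implemented). Consequently a
strongly asymmetric mass of true changes shifts the effective null for
unchanged transcripts — visible in simulations as inflated type-I error
among nulls when a large planted-DE mass is present. The calibration
property (type-I within [0.0005, 0.002] at α=0.001) therefore refers to a
fully null matrix with matched dispersion.

Cross-genotype "common" transcripts require a hit with ≥ 80% identity and
≥ 80% query coverage (alignment columns / query length). N50 is the
largest L such that contigs ≥ L cover at least half the total length.

## miRNA precursors, targets and the mimicry network (`mirnet`)

Mature matching slides every sense-strand window of mature length over the
transcript and reports Hamming distance ≤ 2 (U≡T, no indels); the bound is
exact, so 3-substitution decoys can never match.

Folding is base-pair maximization (Nussinov-style DP with bifurcation,
minimum loop 3, pairs AU/GC/GU), not a thermodynamic nearest-neighbour
model; an external thermodynamic folder can be plugged in behind the same
interface. The traceback resolves ties by pairing the outermost ends
first, then leaving the 5′ base unpaired, then the 3′ base, then the
smallest bifurcation point — fixing one canonical structure among the many
optimal ones. The energy proxy is −(3·GC + 2·AU + 1·GU) over the traceback
pairs and the MFEI-like index is `(energy/length×100)/GC%`.

A precursor call folds mature ± 200 nt and is valid when (i) at least 60%
of mature bases are paired, (ii) no mature base falls inside a terminal
loop, and (iii) the MFEI proxy is ≤ −0.7. Terminal loops only count when
their closing helix stacks ≥ 3 consecutive pairs: base-pair maximization
happily closes single-pair "hairpins" that no real stem would form, and
counting those as apical loops would reject genuine precursors. The −0.7
MFEI ceiling was calibrated once against the generator's planted hairpins
(which score ≈ −2) and functions mainly as a guard against unstructured
(e.g. poly-A) contexts, whose proxy approaches 0; these constants are all
exposed in the configuration.

Target scoring is a psRNATarget-style expectation: mismatch 1.0, G:U
wobble 0.5, single-nt bulge 2.0 (at most one bulge, in either strand),
all penalties doubled at miRNA positions 2–13; a bulge between miRNA
positions i and i+1 is doubled when i ∈ [2,13] (computed as L−g for gap
offset g). The best window per (miRNA, target) is reported when the
expectation is ≤ 3.0. Inhibition is "translation" when a full mismatch
sits at miRNA position 10 or 11, else "cleavage". psRNATarget's exact
defaults vary by version; this scheme is fixed, documented, and verified
against a brute-force scorer over all windows and bulge placements. One
cutoff serves both mRNA and lncRNA targets.

The network is a typed directed graph (miRNA → target) with DE status and
Fig-style coloring (red up, green down). Every (lncRNA, miRNA, mRNA)
combination in which the miRNA targets both partners is a candidate
endogenous target mimic; the triple count is exactly
Σ_miRNA |lncRNA targets| × |mRNA targets|.

## Alternative splicing (`splice`)

A locus is a connected component of exon-overlapping models on the same
chromosome with compatible strands ('.' is compatible with either). For
each transcript pair, intron chains within the shared span are compared:

* intron retention — an intron of one lies entirely within an exon of the
  other;
* exon skipping — an internal exon of one lies entirely within an intron
  of the other while the flanking introns' outer boundaries match that
  intron's boundaries;
* alternative donor/acceptor — two introns share one boundary and differ
  at the other; donor = intron 5′ boundary, acceptor = 3′ boundary in
  transcription orientation (so the genomic side flips with strand);
  unstranded models are excluded from these calls;
* other — any remaining difference.

Rules apply with precedence IR > ES > Alt > other, and introns explained
by a higher rule are consumed — without this, every skipped exon would
also surface as a spurious alternative-acceptor/donor pair. Events are
de-duplicated per locus on (type, coordinates). Classification is
symmetric in the pair and invariant under genome-wide translation. The
residual "other" class is defined operationally and need not coincide
with any external tool's taxonomy.

## Synthetic data (`synthetic_data`)

The generator emulates the statistical structure the analysis assumes.
Defaults: 1,000 coding / 600 lncRNA / 100 contaminant transcripts; coding
lengths 400–2,000 nt (mean ≈ 1,200, matching typical assembled mRNAs);
lncRNA lengths 201–2,900 nt with GC held at 44% ± 1 (within the 43–45%
band reported for wheat lncRNAs) and no ORF ≥ 240 nt on either strand
(long ORFs are destroyed by GC-preserving single-base edits of their start
codons); planted coding ORFs ≥ 300 nt so both classes sit well clear of
the 240-nt decision boundary; contaminants are ≥ 96%-identity copies of
the bundled fixtures. Counts are negative-binomial (Gamma–Poisson) with
dispersion 0.1, three replicates per condition by default (pooled n=1 is
supported), 10% planted DE split equally up/down with condition means
differing by exactly 2^±4 (16-fold). lncRNA mean expression defaults to
¼ of the coding mean — published comparisons are qualitative ("lower"),
so the factor 4 is a package choice, not a literature value. Hairpins
embed the mature (0–2 substitutions) opposite a near-reverse-complement
arm across a 6–12 nt A/C loop; target sites are near-perfect complements
planted in 3′ UTRs (coding) or ORF-free context (lncRNA). The toy genome
places two-isoform loci realizing each planted event on chromosomes 1A–3B
plus an unplaced scaffold, with the event mix defaulting to the
empirically reported shares (38% intron retention, 29% other, 15%
alternative acceptor, 10% alternative donor, 8% exon skipping).

Randomness: one seed per run; each stage draws from its own child stream
(`default_rng([seed, stage])`) so changing one class's count never
reshuffles another. All outputs are byte-deterministic given the
configuration.

What the generator does **not** emulate: read-level noise and assembly
artifacts (no FASTQ, no mis-assembly, no fragmented transcripts),
paralog/homoeolog cross-talk between the A and B copies, composition
heterogeneity along transcripts, thermodynamically realistic RNA
structures, and any correlation between expression and sequence features.
Passing the recovery tests therefore demonstrates the correctness of the
decision logic under its stated assumptions, not the field performance of
the thresholds on real assemblies.

## Problem sizes

The bundled tests and the acceptance script use desk-scale problem sizes
chosen to make each property measurable with comfortable margins: the
1,700-transcript classification benchmark, 20,000 null transcripts for
type-I calibration, 5,000 transcripts (500 planted changes) for power, 50
planted hairpins, 60 splicing loci (12 per event type), and
200–500-instance oracle-equivalence sweeps. Headline counts from the
original full-depth study (tens of millions of reads, external databases)
are not reproducible at this scale and are not targeted; all quantitative
claims here are about the synthetic benchmark.
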