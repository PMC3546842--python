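# Methods

## Scanning model

A consensus binding site is a fixed word of length L over the IUPAC
nucleotide alphabet. Degenerate codes are honoured in the *motif* only: a
window position holding anything other than A/C/G/T (an N, or a degenerate
code sanitised to N on input) never matches. The forward strand is scanned
directly; the reverse strand by scanning the window for the motif's
reverse complement and labelling those hits '−'. All overlapping
occurrences are counted — the census is a per-offset test with no overlap
exclusion, which keeps observed counts well defined.

**Palindromes.** If a motif equals its own reverse complement (the word set
is closed under reverse complementation, e.g. TTACGTAA, GTTACGTAAC), every
occurrence would be reported twice in a naive both-strand census. cisscan
single-counts such intervals as one '+' hit, and correspondingly forces the
null expectation to single strand. This keeps `observed / expected`
interpretable for palindromic and non-palindromic motifs alike.

**Near-matches.** A near-match is a length-L window matching the consensus
at ≥ L−1 *consecutive* positions and not exactly — equivalently, one
deviation confined to the first or last motif position. A run of L−1
identities cannot contain an interior mismatch, so the two formulations
coincide; the brute-force oracle in the test suite checks the run-length
formulation against the implementation's terminal-variant formulation. An
`any`-position single-mismatch mode exists as a sensitivity switch
(default off). Near-matches are excluded from over-representation censuses
by default.

## Null model and statistics

The background model is independent equiprobable bases: a non-degenerate
L-mer matches a given position with (¼)^L; degenerate positions contribute
|allowed|/4 each and are flagged in output. Expected count =
`strands × (window_length − L + 1) × p`; positions with fewer than L bases
remaining are not trials. Both strand conventions (×2 and ×1) are written
to every enrichment table because published fold figures rarely state which
was used. A window-composition null (product of observed mononucleotide
frequencies) is available but off by default — faithfulness to the uniform
model first, realism as an option.

The binomial upper tail P[X ≥ observed] with n = strands × positions and
the per-position p is computed with `scipy.stats.binom.sf`; the test suite
checks it against full outcome enumeration for n ≤ 12.

## Coordinates and regions

Internal coordinates are 1-based inclusive; BED is converted on the way in
and out. TSS offsets are `position − tss` on '+' genes and `tss − position`
on '−' genes, so upstream is negative on either strand; offsets format in
kb with explicit sign ("−31 kb", "+0.147 kb"). Exons and introns are
numbered strand-aware (intron k lies 3' of exon k in reading direction).
Intervals straddling a feature edge are labelled `boundary` rather than
assigned arbitrarily. Gene-span positions 5' of strand-exon 1 label
`upstream` and those 3' of the last exon `downstream`, keeping the labels a
total partition even for annotations whose exons are not flush with the
gene span. The TSS is anchored to the strand-aware start of exon 1 and
offset 0 is the TSS itself (no ±1 skip).

## Cluster rule

Published "clusters" of binding sites rarely come with a definition, so the
rule here is explicit and configurable: single-linkage chaining with a
maximum inter-site start-to-start gap (`window_bp`, default 1000 bp) and a
minimum size (`min_sites`, default 3). Defaults reflect the tight grouping
(hundreds of bp) typical of reported upstream/intronic clusters. Chains are
maximal and disjoint per motif; a mixed-motif mode and an
overlapping-hit-dedup switch exist, both off by default. Note that a long
chain's total span may exceed `window_bp` — the rule bounds consecutive
gaps, not the span.

## ChIP-qPCR arithmetic

Percent input uses the dilution-adjusted input Ct:
`adjusted = mean(input Ct) − log_E(1 / input_fraction)`, then
`percent = 100 × E^(adjusted − mean(IP Ct))` with configurable efficiency E
(default 2.0 = 100%). Technical duplicates are averaged on the Ct scale
within an experiment; percent and fold statistics are computed on the
linear scale across experiments, with the summary fold taken as the ratio
of mean percents and the reported SD the between-experiment SD of
per-experiment folds. Replicate scatter is propagated into a per-percent SD
by the delta method. A zero or negative control percent yields an NA fold
with a warning, never an infinity. Plate-shift invariance (adding a
constant to all Cts) and input-fraction cancellation in the fold are
asserted numerically in the tests.

## Synthetic data

The generator emulates the study geometry, not genome realism: i.i.d.
bases at GC 0.5 (matching the ¼-per-base null; configurable), evenly
spaced fixed-length exons, and planted motif instances written over the
background at chosen TSS offsets or absolute positions, on either strand,
exact or with one mutated terminal base for near plantings. One master
seed fans out to independent child streams, so every artefact is
deterministic per seed. Collisions between plantings raise; collisions
with chance background occurrences are tolerated and the truth table's
expected-background field quantifies them analytically.

Two presets: *appb-like* (160 kb: 60-kb 14-exon '+' gene, 50-kb flanks,
E4BP4 trio at −31 kb with 200-bp spacing, lone E4BP4/XFD1 sites in intron
1) and *app-like* (100 kb: 60-kb 18-exon '−' gene, 20-kb flanks, E4BP4
quartet centred in intron 4, plus one exact and one near XFD1 site). The
minus-strand preset deliberately exercises strand-aware intron numbering
and offset signs end to end.

**Default consensus words.** The supplied motif configuration uses
E4BP4 = `GTTACGTAAC` — the full-length classic E4BP4/PAR-family site, a
10-bp pseudo-palindrome around the TTACGTAA core — and XFD1 =
`TGTTTATTT`, an A/T-rich Forkhead-style 9-mer at which the 8-of-9
near-match rule applies. The 10-mer choice is also an identifiability
decision made at design time: recovering a planted cluster as *exactly*
its planted members requires chance background occurrences near the
cluster to be rare, and at 10 bp the expected number of chance hits in a
cluster's ±1-kb joining halo is ≈0.003 per replicate (vs ≈0.07 for an
8-mer, which would contaminate several replicates in a hundred). Both
words are ordinary configuration — analyses of real loci should supply
whatever consensus the factor at hand is known to bind.

The qPCR simulator inverts the percent-input formula: it fixes an input Ct
(20.0), derives the IgG and specific-antibody Cts from a baseline IgG
recovery (0.05% of input) and the requested true fold, and adds Gaussian
noise (default SD 0.2 cycles) per replicate. The default panel uses true
folds 180 (strong positive-control intron), 120 (clustered-site intron),
150 (housekeeping promoter control) and 1 (three negative-control
introns).

**What passing tests do not show.** The generator has no repeats, CpG
islands, composition heterogeneity, chromatin structure or primer effects;
recovery rates measured here bound performance only under the uniform
null, and real-locus analyses should expect more chance matches in biased
composition (the composition null exists for exactly that check).

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a desk machine: 200 oracle
windows ≤ 5 kb, 200 null windows of 100 kb, 100 truth-recovery replicates
per preset, 300–500 qPCR seeds — a few seconds to ~15 s per suite. The
cluster-recovery criterion (≥95/100 replicates with the planted cluster
recovered exactly) is a deterministic measurement once the seed list is
fixed; measured rates are 99–100/100. Ties in cluster chaining are
resolved by sorting on (start, end, strand); pipeline outputs contain no
timestamps, so identical configs give byte-identical files (hash-checked
in the tests).

## Known limitations

- Exact/near word matching only — no PWM scoring, no motif discovery.
- Single-gene loci; no multi-gene annotations or liftover.
- The uniform null ignores strand-composition asymmetry and higher-order
  sequence structure (no Markov backgrounds of order ≥ 1).
- Near-match planting cannot target a fully degenerate (N) terminal
  position, and planted "at-least" truth counts are not deduplicated
  against chance occurrences.
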