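# Methods

## Redundancy statistics

All entropies are in **nats**.  For counts `c_1..c_S` over `N = Σ c_i`
items, `H = -Σ (c_i/N) ln(c_i/N)` (computed via `scipy.stats.entropy`).

Two deliberate, load-bearing conventions:

* **H_max = ln N**, the logarithm of the number of *items*, not categories.
  `ln S` is the conventional evenness denominator, but this package measures
  redundancy against the state in which every gene founds its own category,
  and only `ln N` reproduces the published redundancy percentages of the
  three reference genomes from their published entropies (e.g.
  `1 − 6.912/ln 2022 = 9.2%`); `ln S`, base-2 or base-10 do not.
* **H_exp** is the entropy of the *exact* broken-stick proportions
  `p_i = (1/S) Σ_{k=i..S} 1/k`, not of the asymptotic form.  The two are
  indistinguishable at three printed decimals for S ≥ ~1000; exactness is
  preferred.  Numerically, the exact entropy exceeds the asymptote
  `ln S − (1 − γ)` (γ Euler–Mascheroni) by ≈ 1.2/S — 0.0118 at S = 100,
  1.0·10⁻³ at S = 1000 — which the tests assert as `gap < 1.5/S`,
  decreasing in S.

`redundancy_max = 1 − H/H_max ∈ [0, 1)`; it is 0 iff every count is 1.
`redundancy_exp = 1 − H/H_exp` is negative when the genome is more even
than a random broken stick.  Reported percentages are rounded to two
decimals in output tables; internal values keep full precision.

**Over-representation** is rank-positional: categories are sorted by count
descending with ties broken by category id ascending, and the category at
rank i is flagged iff its observed frequency **strictly** exceeds `p_i`
(ties at the boundary are conservatively not flagged).  Each tied category
is compared against the expectation of its own assigned rank, matching the
observed-vs-expected curve overlay of a rank-abundance plot.

**Multi-category genes.** An assignment table may list one gene under
several categories.  The default `per_pair` policy counts each distinct
(gene, category) pair as one item (what a flat IMG-style export yields);
`first_only` counts only each gene's first listed category, so N equals the
number of genes.  The source data for the published N/S pairs does not
reveal which convention was used, so both are implemented and tested; the
choice shifts N, never the formulas.  Genes with no category assignment
never appear in the table and are excluded from all entropy computations.

## Homology and Venn partitioning

`local_align` is exact Smith–Waterman (Biopython `PairwiseAligner`, local
mode) under BLOSUM62 with affine gaps (open 11, extend 1: a gap of length g
costs 11 + g).  E-values use Karlin–Altschul
`E = K·m·n·exp(−λ·S_raw)` with the fixed published gapped-BLOSUM62
constants λ = 0.267, K = 0.041 (configurable).  `m·n` is query length ×
subject length per pair by default, or query length × summed subject
lengths under the `effective` search-space policy.  Identity is counted
over all alignment columns including gap columns (BLAST's convention, which
the thresholds presuppose).  A gene has a homolog when at least one
alignment passes **both** E ≤ 10⁻⁵ and identity ≥ 30%.

The three-genome partition is gene-level and directional: genome A's
regions count A's genes by whether B and/or C contain a homolog of each.
Because homology is not transitive, the regions of different genomes need
not agree, and each genome's four region counts always sum to its proteome
size.  This is a desk-scale all-vs-all implementation — no heuristic
seeding — intended for proteomes of tens to hundreds of genes.

## Genome distance

`find_hsps` seeds on exact shared k-mers (default word size 11; minimum 8
as a seed-explosion guard; words containing N never seed) and extends each
seed ungapped in both directions at +1 match / −1 mismatch, stopping once
the running score falls more than `xdrop` (default 20) below its running
maximum and trimming back to the maximum. Every seed is extended (no
skip-ahead shortcuts), duplicates collapse, segments contained in a longer
segment on the same diagonal are dropped, and segments shorter than
`min_length` (default 50) are discarded.  Extension is ungapped and
forward-strand by default; `--both-strands` also scans the reverse
complement of B and pools the HSP sets.

`ggdc_formulas` merges HSP intervals per genome before summing, so no
column is counted twice: `hsp_length = (covered_A + covered_B)/2` and,
where an overlap is cut, the trimmed HSP contributes identities in
proportion to its own identity fraction.  `total_length` is the arithmetic
mean of the two genome lengths.  With one pooled identity mass,
`f3 = f1·f2` is an algebraic identity (asserted to 1e-9).  An empty HSP set
reports f1 = f2 = f3 = 0 with an explicit `empty` flag rather than a 0/0.
Multi-contig FASTAs are concatenated with 100-N spacers for the scan; the
spacers cannot seed or survive inside an HSP (100 mismatches ≫ xdrop) and
are excluded from the length accounting.

## Synthetic data

`simulate_cog_table` draws category counts by model: `uniform` assigns
genes round-robin (counts differ by at most 1); `brokenstick`, `geometric`
(normalized kⁱ) and `dirichlet` (Dirichlet(α·1) weights) are multinomial
draws over the model's proportions; `transposon_burst` gives the designated
burst families a fixed mass fraction split equally (default burst mass 0.3,
emulating a heavy mobile-element expansion on the order of the 601
transposase genes out of ~6,600 COG-assigned genes seen in real
transposon-ridden genomes) on top of a Dirichlet baseline.  Multinomial
sampling means a category can draw zero genes; the truth manifest records
the drawn counts including zeros, while profiles see only categories that
occur.

`simulate_proteomes` gives every family one random ancestral sequence and
mutates each member independently.  `within_family_identity` is the
expected **pairwise** identity between two members: the per-member
substitution rate r solves `(1−r)² + r²/19 = identity` (both members must
either keep a position or coincide among the 19 alternatives).
Substitutions always pick a *different* residue, so per-branch identity is
exactly `1 − r` in expectation.  Default protein length 120 aa (a typical
bacterial domain-sized protein, long enough that a 0.9-identity family is
unambiguous at E ≤ 10⁻⁵ while random 120-mers are not).

`simulate_genome_pair` builds independent i.i.d. backgrounds at the stated
GC (default 0.5) and copies each planted segment from a random
non-overlapping window of A into one of B (forward strand only, rejection
sampling for placement), substituting down to the stated identity.  All
truth coordinates are 0-based half-open.

**What a green test does not establish.**  The generators produce i.i.d.
sequence with no indels, no codon structure, no repeats beyond what is
planted, and no strand variation; family identity is homogeneous along the
sequence.  Passing tests therefore validate the *statistics and the
detection machinery*, not robustness to real genomic mosaicism, gapped
homology, or BLAST's heuristics.  The published multi-Mb genome-pair
values, real Venn counts and the ">80 over-represented COGs" figure need
the real genomes and databases and are out of scope by design.

## Defaults and seeds

Default seed 42 everywhere; every CLI entry point exposes `--seed`, and
every pipeline report embeds the resolved configuration and seed, so reruns
are byte-identical (timings go to the log, not the report).  CLI exit
codes: 0 success, 2 usage error, 1 data/config error.

## Known limitations

* All-vs-all exact alignment scales quadratically; intended for synthetic
  or down-sampled proteomes.
* Ungapped HSPs understate coverage relative to gapped BLAST HSPs on real
  diverged genomes.
* `redundancy_exp` uses the observed S; with strong undersampling (many
  zero-count categories) the broken-stick reference shifts with S, which is
  the behaviour of the statistic itself, not an implementation artifact.
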