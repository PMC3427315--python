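# Methods

## Scope and model of the analysis

`taxonlines` operationalizes integrative delimitation of allopatric
(insular) candidate taxa. The unit of analysis is a *candidate taxon* — a
population, or a pooled clade of populations under a *guide grouping*
that encodes the accepted phylogeny. Tree inference itself is out of
scope: the grouping is user input, or (for file-based runs without one) a
UPGMA cut of mean between-population p-distances at k = 2, with
lexicographic tie-breaking. Ranks are then a deterministic function of
the evidence profiles: clades are evaluated against each other first;
members are evaluated against their within-clade siblings second.

## Lines of evidence

1. **mtDNA** — the candidate's haplotypes on the configured
   mitochondrial marker (default `cytb`) must lie only in
   statistical-parsimony network components containing no other
   candidate's samples. Exclusivity, not connectivity, is the criterion:
   a candidate split across two components that are both free of other
   populations still qualifies.
2. **nDNA** — no nuclear haplotype (default marker `Rag2`,
   missing-as-wildcard collapse) shared with any other candidate, *and*
   at least `min_nuclear_substitutions` alignment columns whose observed
   states are disjoint between the candidate and the pooled others.
   The default of 2 encodes the judgment that one private substitution
   per marker is too slight to carry a line of evidence; setting it to 1
   gives the strict reading under which such a candidate is elevated.
3. **Morphology** — at least one diagnostic character against every
   comparison candidate: a qualitative character with disjoint observed
   state sets, or a numeric character with disjoint observed ranges
   (optionally the 75% rule instead). Characters flagged `graded` or
   `sex-limited` in the data header are excluded unless
   `exclude_graded_characters` is turned off; the exclusion is a data
   annotation, not a hard-coded rule.

Candidate designation (UCS/CCS/DCL) follows the same inputs: admixture ⇒
deep conspecific lineage; molecular distinctness plus a taxonomically
relevant character (or sympatry without admixture) ⇒ confirmed candidate;
molecular distinctness whose other differences are explicitly judged
slight ⇒ deep conspecific lineage; molecular distinctness alone ⇒
unconfirmed candidate. The sympatry criterion is recorded as
not-applicable (None) for allopatric candidates rather than false.

## Parsimony probability and connection limit

For two haplotypes differing at *j* of *L* comparable sites, sites are
modelled as independent, each accumulating Poisson hits with common mean
*m* over the divergence separating the pair; hits move among the four
nucleotide states symmetrically, so a site differs with probability
d(m) = (3/4)(1 − e^(−4m/3)). *m* is estimated by inverting d at the
observed fraction x = j/L (the Jukes–Cantor multiple-hit correction).
A connection is *parsimonious* when each observed difference is the
product of exactly one substitution, so the inferred path carries no
hidden extra steps; conditioning site by site,

    P_j = [ m e^(−m) / d(m) ]^j .

Hidden multiple hits at sites observed identical leave the inferred path
between the two haplotypes intact and are deliberately not counted
against the connection; a variant that counts them collapses to the
birthday bound P ≈ exp(−j²/2L) and yields limits (~1.1% of sites at
600–700 bp) short enough to fragment within-island variation that
statistical-parsimony software demonstrably connects. The implemented
form gives 95% limits of 8–13 steps at 468–1143 bp (1.2–1.7% of sites),
matching reported behaviour of the historical tools; because the exact
estimator in those tools is undocumented, the full probability table is
exported with every partition so any step-limit discrepancy is visible
rather than hidden.

`j_max` is the largest j with P_j ≥ 1 − α (α = 0.05 for the 95% limit);
P_0 = 1 by convention; the table is populated up to the first failing j.
Step distance between haplotypes is the Hamming distance over sites
non-missing in both, consistent with the collapse policy, and network
topology (which intermediate path) is never resolved — only components
and step-annotated edges feed the evidence engine, so tie-breaking among
equal-length connections cannot affect results.

## Distances

p-distances use pairwise deletion by default (a
`complete-against-matrix` mode drops every column with missing data in
any sequence first); gaps, N and IUPAC ambiguity codes count as missing.
Group summaries keep raw fractions internally and report percentages
rounded to one decimal; singleton populations get an absent (not zero)
within-group record. Clade-level records pool all cross-clade sample
pairs, so the clade-pair maximum equals the maximum over constituent
population-pair maxima. The barcoding-threshold relation is computed on
the pair maximum and is inclusive at the boundary.

## Morphology

MANOVA uses Wilks' lambda with Rao's F approximation (exact for ≤ 2
variables or ≤ 3 groups — the null calibration in the test suite uses
2 variables × 4 groups, where the rejection rate at α = 0.05 is exact up
to Monte-Carlo error). Pairwise tests are two-group Hotelling T² with the
standard F transform; pairs too small for a pooled covariance are
reported as untestable rather than silently NA. Multivariate analyses are
complete-case (rows missing any selected character are dropped and
counted). CVA solves the generalized eigenproblem of between- vs pooled
within-group scatter; axes are scaled to unit pooled within-group
variance and signed so the largest-magnitude loading is positive —
loadings are therefore comparable across software by rank of |loading|
only. A singular within-group scatter is ridge-regularized
(1e-8 × mean diagonal) with a logged warning.

The 75% rule is implemented against the central 99% interval of a normal
fitted to the reference sample (mean ± 2.576 sd) because raw ranges are
unstable at the specimen counts typical of museum series; a raw-range
mode is available. Zero reference variance degenerates to a point
interval.

## Synthetic scenarios

The generator draws sequences on the fixed population tree
root → clade → population → tip with Poisson substitution counts per
branch, calibrated directly in expected pairwise p% (within-population
tier = 2 × tip branch, sister tier adds population branches, clade tier
adds clade branches). Substitutions land on previously untouched sites
whenever possible, so p-distance equals step distance and homoplasy is
minimal; exhaustion falls back to multiple hits with a logged warning.
No model correction is applied anywhere, since the analysis quantities
are uncorrected p-distances. Nuclear-style markers place an exact,
deterministic number of substitutions on one group's branch.

The `comoro_preset` encodes the four-island study conditions: sequence
samples {Anjouan 4, Mayotte 4, GrandComoro 6, Moheli 5}; marker lengths
16S 520 + cyt b 714 + COI 658 + ND4 980 + c-mos 626 = 3498 bp, plus
Rag2 613 and PRLR 468. Cyt b tiers are 0.5% within islands (putting the
within-island *maximum* near 1%, the reported quantity), 5.4% between
Anjouan and Mayotte, 7.7% between GrandComoro and Moheli, 9.5% between
clades; COI uses 5.8/5.65/8.5% so the between-clade maximum brackets the
8.3% barcoding threshold; 16S is slow (0.8% between the AM sisters,
below the ~8-step limit at 520 bp, so those islands share a network).
Each nuclear marker separates exactly one group (Rag2: Anjouan; c-mos:
GrandComoro; PRLR: the AM clade) by one substitution. Morphology draws
six size/scale-count characters from the published per-island
means ± sd (43 specimens: 6/7/19/11), a loreal-contact state fixed per
clade, a rare 17-row midbody state in three islands, and two flagged
coloration characters (graded male dorsal pattern; sex-limited dark
ventral line).

What the generator does *not* emulate: coalescent genealogy within
populations (tips hang off a star, so within-island pairwise distances
are sums of two independent Poisson draws), recombination, indels,
rate variation among sites, correlated characters, and measurement
error. Passing tests therefore show that the pipeline's decision logic
recovers the built-in structure at realistic effect sizes — not that the
method is robust to genealogical noise sources absent from the
generator.

## Determinism and problem sizes

Every stochastic component is driven by numpy `default_rng` seeded from
the scenario seed (per-marker streams derive from a `SeedSequence` of
seed + a marker tag), so a config + seed reproduces byte-identical FASTA
and JSON. The acceptance script estimates the end-to-end recovery rate
over 100 replicate datasets (~0.1 s each) and the MANOVA null rejection
rate over 500 simulated 4 × 10 × 2 datasets; both sizes keep Monte-Carlo
error a few percent while the whole script runs in well under a minute.

## Known limitations

- The parsimony-probability estimator is a documented reconstruction of
  an undocumented historical computation; limits can differ from TCS
  v1.21 by a few steps (surfaced via the exported probability table).
- Rank assignment places a clade with exactly one line of evidence in
  the pooled below-species group; with several species-level clades plus
  such a weak clade, its attachment is reported but taxonomically
  under-determined.
- The nuclear line counts fixed (disjoint-state) substitutions against
  the pooled other candidates; shared ancestral polymorphism inside a
  candidate reduces the count conservatively.
- Morphological diagnosability by observed ranges is sensitive to small
  samples (a range gap can arise by chance — visible as the rare
  non-recovery seeds in the acceptance rate).
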