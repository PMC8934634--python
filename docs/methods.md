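# Methods

## Profile models and scoring

Each RT class is summarized by a position-specific log-odds profile
over the 20 canonical residues, built from a per-class multiple
alignment of the RT core domain. Alignment columns with a gap fraction
above 0.5 are dropped; fewer than 5 surviving columns is an error.
Per-column scores use Laplace-style pseudocounts against a uniform
background:

    score_c(a) = log2( (n_c(a) + k·b·20) / (n_c + k·20) / b ),  b = 1/20

with pseudocount weight k = 1 by default. By construction
Σ_a 2^score·b = 1 per column. Queries are aligned locally
(Smith–Waterman over profile columns) with affine gaps: the first
unmatched residue or skipped column costs `gap_open` = 10 bits, each
further one `gap_extend` = 1 bit. Unknown residues (X) score 0 in
every column, so masked or ambiguous sequence neither helps nor hurts
a local alignment. The production scorer is vectorized across
sequences; the test suite keeps an independent naive three-state DP
and checks exact agreement on random instances.

Exact-duplicate removal before profile building collapses identical
sequences (case-insensitive), the limiting case of identity-1.0
clustering; nothing finer is needed for profile construction.

## E-value calibration

Raw bit scores are converted to E-values through an explicit empirical
null: each profile scores 200 i.i.d. uniform-residue sequences of
length 350, and a Gumbel distribution is fitted by the method of
moments (λ = π/(σ√6), μ = mean − γ/λ). Then

    E(s) = N · (1 − exp(−exp(−λ(s − μ))))

for a scan over N proteins. The fit is deterministic per seed, and
calibration random streams are domain-separated from every other
seeded stream in the package (SeedSequence with a purpose tag), so a
user seed can never make a "random" null replay a sequence generated
elsewhere from the same seed — an aliasing failure mode we hit in
testing, where one colliding null inflated a profile's null σ by an
order of magnitude. On held-out nulls the fitted tail tracks the
empirical CDF to within 0.15, and scanning 1,000 fresh random
sequences at E ≤ 1 yields about the single expected false hit.

The default hit threshold is E ≤ 10⁻³ at every stage (candidate
detection, refinement, neighborhood annotation); it is configurable.

## Decision cascade

Hits on one protein are collapsed to the best E-value per class
(ranking raw hits would let one class occupy all top slots). The class
is assigned directly when only one class hits, or when the runner-up
E-value is at least 10⁵-fold higher than the best (boundary
inclusive); E-values are floored at 10⁻³⁰⁰ so the ratio is defined,
and an exact tie is ambiguous. Ambiguous cases keep the best three
classes and defer to phylogenetic placement; a placement class among
those three is accepted with the placement's confidence (including
confidence 0), anything else leaves the gene unresolved with all
candidate classes reported.

## Phylogenetic placement

Placement is distance-based rather than likelihood-based: the query is
mapped onto the reference-alignment columns through its profile
alignment (fewer than 10 aligned columns aborts placement), p-distances
to every leaf are computed over shared columns, and for each edge the
attachment offset x ∈ [0, edge length] and pendant length p ≥ 0
minimizing Σᵢ (p ± x + cᵢ − dᵢ)² are solved in closed form (2-variable
convex QP with box constraints; candidate solutions at the interior
optimum and each boundary). Edge weights are a softmax of the
residuals, w_e ∝ exp(−(s_e − s_min)/T) with T = mean(s) − s_min (1 if
degenerate), normalized over all edges — the stand-in for a placement
method's like-weight ratio. The fit is invariant under joint scaling
of branch lengths and distances.

Consensus rules on top of the placement: a leaf edge contributes the
leaf's class; an internal edge contributes the majority class of the
distal (root-away) subtree when at least 90% of its leaves agree
("subtree rooted at the query" is read as the distal clade of the
attachment edge — the only reading that yields a proper subtree).
Confidence is the best edge weight, zeroed when the top two weights
differ by less than 0.25 (applied to the top two only). On trees with
many near-equivalent edges the softmax spreads weight thinly, so
confidence 0 with a correct class is the common outcome; the class
still participates in the consistency check. Reference trees are
neighbor-joining (via dendropy) over p-distances; unrooted input is
midpoint-rooted and flagged.

## Neighborhood analysis

Neighbor selection walks outward from the RT, up to two genes per
side, requiring each successive intergenic gap ≤ 2,000 bp (overlapping
genes clamp to gap 0); the walk stops at the first violation, so a
nearer compliant gene never rescues a farther one. Selection uses
contig coordinates (left/right); strands are recorded so a
strand-relative convention remains recoverable downstream. Fused
domains are broad-library envelopes on the RT protein overlapping the
RT-domain envelope by less than 50% of the shorter envelope;
multi-envelope detection re-scans each protein with the previous best
envelope masked (up to 4 rounds). The broad scan's E-value database
size is the number of proteins in the scan at hand. A confident CRISPR
call with no cas-named domain (configurable list; default any name
starting "Cas"/"cas") among neighbors or fusions becomes CRISPR-like.

## Co-occurrence statistics

Counting is RT-instance-based: a (class, domain) pair counts once per
non-redundant RT even if several neighbors carry the domain;
`level="genome"` switches the unit to genomes. The published worked
example for the specificity score (a domain near 207 Retron + 2 GII +
1 UG7 RTs → 0.99) is instance-based, which fixed this default; the
denominator definition is otherwise ambiguous between genomes and
instances. Redundancy removal is greedy longest-first clustering at
90% identity, where identity is the maximal number of matched residues
in a global alignment (match 1, mismatch/gap 0 — an LCS-style count)
divided by the shorter length. Reported scores round half-up to two
decimals; raw floats are kept in JSON.

## Synthetic study conditions

The generator's defaults are the fixture the acceptance checks run
on: 5 classes × 15 members, class ancestors rejection-sampled at
pairwise divergence ≥ 0.55 around a shared base (length 200–300, one
frame, no indels — so the family union is itself the reference
alignment), members i.i.d.-mutated at 0.10; 3 contigs × 30 genes with
intergenic gaps of 20–200 bp unless a plant overrides them; 10
planted RTs covering all classes, including one CRISPR with planted
Cas1/Cas2 neighbors, one cas-less CRISPR, one out-of-range (2.5 kb)
neighbor, and one stop-at-violation layout (gaps 100 bp then 3 kb).
The broad library holds seven named domain families plus a
deliberately diffuse cross-class RT core model (one representative
per class) — full-length RTs exceed its null by hundreds of bits
while short motifs do not. The decoy is an HTH DNA-binding consensus
carrying a 25-residue GII-derived motif mutated at 40%: strong enough
to bait the sharp class profile in most seeds, too degenerate to pass
the RT-related refinement test. Reverse translation uses the
alphabetically first codon per residue (determinism over realism).

What the fixture does not emulate: indel-rich families, realistic
codon usage and amino-acid composition, overlapping genes,
contamination, or fragmented assemblies. Passing on it shows that the
decision cascade, the thresholds and the neighborhood logic behave as
specified when classes are separable — not that the bundled toy
profiles match real RT diversity; for real data, build profiles from
curated class alignments.

## Numerical and design choices

- Internal coordinates 0-based half-open; all file formats 1-based
  inclusive (GFF3 convention).
- Deterministic output everywhere: hits sort by (protein, E-value,
  profile name); NJ input order fixed; every random stream derives
  from an explicit seed.
- The naive six-frame stop-to-stop ORF caller is a deliberately simple
  fallback flagged in gene ids (`_orf`); supply GFF gene calls for
  real assemblies.
- Problem sizes in tests (200-sequence calibration nulls, 500 random
  trees, 300 alignment-oracle instances, a 90-gene genome) were chosen
  so the whole suite runs in well under a minute of compute per
  module while keeping binomial/Poisson fluctuations far from the
  asserted margins.

## Limitations

- The profile scorer has no insert-state emission model or
  multi-domain envelope likelihood; it is a single-best-envelope local
  aligner with greedy re-scan for additional envelopes.
- Distance placement is a stand-in for likelihood placement; its edge
  weights are comparable within a query but are not probabilities
  across queries.
- Rescue of RT domains split across two envelopes (seen in some
  unusual RT groups) is out of scope.
- Class calls are only as good as the class alignments behind the
  profiles; novel RT classes surface as ambiguous/unresolved calls,
  not as new classes.
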