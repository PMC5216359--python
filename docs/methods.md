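# Methods

## Model and procedure

The package treats species authentication as four coupled problems on a
reference library of aligned ITS2 barcodes labelled by sample, species and
group (target / congener / adulterant).

**Distances.** Pairwise divergence uses the Kimura 2-parameter model,
d = −½·ln[(1 − 2P − Q)·√(1 − 2Q)], where P and Q are the transition and
transversion proportions over a pair's comparable sites.  A site is
comparable only if both sequences carry an unambiguous A/C/G/T there; gap
and ambiguity sites are excluded per pair (*pairwise deletion*, the MEGA
default) or globally (*complete deletion*) — both policies are implemented
because published tables rarely state which was used, and the two can differ
whenever an indel segregates within a species.  Pairs with no comparable
sites or with a saturated correction (log/√ argument ≤ 0) yield NaN markers
rather than exceptions, so a matrix build always completes; downstream
consumers either skip the markers (summaries, with the skipped count
reported) or refuse them explicitly (tree building).

**Trees.** Neighbor joining follows Saitou–Nei with the Studier–Keppler
criterion Q(i,j) = (r−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k); ties in Q are broken
toward the smallest (i,j) index pair in the current label order, and negative
branch-length estimates are clamped to zero with the clamped total logged.
Trees are unrooted (trifurcating root for serialization).  Bootstrap supports
are mapped onto the full-data topology: each replicate resamples alignment
columns with replacement, rebuilds the K2P matrix and NJ tree, and an
internal edge's support is the percentage of replicates containing the same
bipartition.  Replicates whose resampled matrix contains undefined entries
are discarded and redrawn (with a hard cap and a logged count) so the
requested number of effective replicates is always aggregated.

**Diagnostic characters.** A column is diagnostic for the target against a
scope when every target sequence carries the same state x ∈ {A,C,G,T,−} and
x is not observed in any scope sequence there.  Ambiguity codes in the scope
disqualify the column whenever they could encode x (conservative); ambiguity
in the target disqualifies it outright under the default strict mode.  A
relaxed mode (x fixed in ≥ f of target sequences, default f = 1.0) exists for
libraries with suspect members.  Indels are single-column states; a
multi-column deletion yields one site per column.

**Assay design.** In-silico PCR scans a forward primer against the plus
strand and a reverse primer against the minus strand, accepting a binding
with at most `max_mismatch` mismatches (default 1) and none in the 3'-terminal
`clamp` bases (default 3); degenerate template bases count as mismatches for
primers but never satisfy a restriction motif (a site must be certain to be
cut).  Products carry the primer bases verbatim over the primer footprints —
this is what the physical amplicon contains and is what makes mismatch
engineering work.  Digestion cuts the top strand after `cut_offset` motif
bases at every hit (*Bgl* I ships as GCCNNNN^NGGC, offset 7); fragment
lengths are top-strand only, matching what a gel shows.  The primer engineer
enumerates substitutions (up to a budget, default 1, clamp positions
excluded) in the footprint-matching reverse primer and accepts a candidate
only after a closed-loop re-check: every species' product must lose all
enzyme sites overlapping the primer footprint, amplification must survive the
added mismatch, and no new site may appear anywhere in any product.
Proposals are ranked by fewest substitutions, then by distance of the
substitution from the 3' end (farther preferred, to protect extension).
Assay selection ranks clean designs (no engineering) before engineered ones,
then by minimum fragment-size separation.

**Identification.** "Maximum identity" follows BLAST top-hit semantics:
global Needleman–Wunsch with free end gaps (match +1, mismatch −1, gap −2),
identity = matches / aligned columns excluding terminal overhangs, reported
at 1 decimal (half-up, the granularity of published survey tables).  The
best single reference per species is reported; species tied at the top are
listed together and never silently broken.  An 8-mer shared-count prefilter
skips references sharing no 8-mer with the query and falls back to a full
scan when it would skip everything.  The filter is exact in the regime the
tool targets (near-full-length barcode matches): a reference sharing no 8-mer
cannot be a credible best match there.  Note that for *unrelated* random
pairs a free-end-gap optimum can be a short perfect overlap, so identity
values are only meaningful above the call threshold; final calls therefore
require top identity ≥ 99.0% and, for the target species, all diagnostic
sites matched (identity without diagnostic confirmation downgrades to a
genus-level call; anything below threshold is "unresolved").  Mixtures are
detected only via multiple input sequences per product id (the cloning
scenario); base-calling deconvolution is out of scope.

## Synthetic data: what it emulates and what it does not

The generator builds every sequence in a fixed 301-column frame: 45-nt
flank, 211-nt barcode, 45-nt flank.  Planted features, written first and
protected from all subsequent mutation:

- a universal forward-primer landing site in the 5' flank and a conserved
  reverse footprint in the 3' flank (the specific amplicon is 292 bp in the
  target, 293 bp in congeners);
- a 1-nt deletion in the target at barcode column 68 and a substitution at
  column 133 — the two diagnostic characters;
- a *Bgl* I site completed only by the target's diagnostic substitution,
  placed so the cut splits the target amplicon into 168 + 124 bp;
- a confounding *Bgl* I site, shared by target and congeners, under the
  reverse-primer footprint — destroyable by a single primer substitution
  (a G→T at primer base 13, 5'-counted), the situation the engineer must
  solve;
- adulterants have the reverse-primer 3'-clamp landing disrupted, so the
  specific pair cannot amplify them.

Evolution is a per-site independent K2P substitution process (transition
probability κ/(κ+2), κ = 4 by default): a genus stem edge
(`genus_stem_divergence`, default 0.08 substitutions/site) unites target and
congeners against the adulterants; congener ancestors then diverge from the
genus ancestor by factors 0.5–2.5 × `congener_divergence` (default 0.02),
adulterants from the root ancestor by `adulterant_divergence` (default 0.25);
within species, each sample adds Poisson(`intra_subs`) private substitutions
(default 0.6, chosen so the mean pairwise intraspecific K2P ≈ 2·0.6/211 ≈
0.006, the value typical of a plant barcoding target species).  Between-
species divergence is applied as a deterministic substitution count
(round(d × free sites)) so the configured study conditions are realized at
every seed, not merely in expectation; only within-species variation is
stochastic.  Restriction sites that arise by chance outside the planted
coordinates are repaired deterministically (first free motif-defined base,
first transversion), so all sequences sharing a chance hit receive the
identical repair and no artificial polymorphism is introduced.

Deliberate simplifications: no rate heterogeneity across sites, no indel
process beyond the single planted deletion, no sequencing error, no
alignment uncertainty (the true alignment is emitted alongside the ungapped
templates), and adulterant divergence is kept at 0.25 rather than the
0.6–0.75 seen between real distant genera, where alignment itself becomes
unreliable.  Passing tests on this generator therefore demonstrate the
pipeline's bookkeeping and decision logic under known truth; they do not
demonstrate robustness to alignment error, degraded-DNA artifacts or
chimeric reads in real market samples.

## Numerical and design choices

- Coordinates are 1-based and inclusive everywhere: alignment columns,
  template positions, motif starts, cut positions.
- The built-in progressive aligner (pairwise NW guide distances with match
  +1 / mismatch −1 / gap open −5 / extend −1, UPGMA guide tree, Gotoh
  profile–profile merges with sum-of-pairs scores) is a deterministic
  fallback for unaligned input; curated alignments are trusted as given
  (`--aligned`, the default) and never silently re-aligned.  Traceback ties
  prefer match, then gap-in-second-profile, placing gaps deterministically.
- Haplotype classes use exact string equality including gap columns, so an
  indel haplotype stays distinct.
- Bootstrap supports are integers (percent, rounded half-to-even by the
  platform); supports below 50 are retained in the data and suppressed only
  in rendering.
- Identity rounding is half-up at 1 decimal; 210/211 reports as 99.5.
- The enzyme table is editable config seeded with *Bgl* I only; no external
  enzyme database is consulted.
- Seeds: every stochastic step (simulation, bootstrap, query generation)
  takes an explicit seed, defaulted to 1; identical config + seed gives
  byte-identical output.

Problem sizes used by the test suite and the acceptance script — 110-sequence
libraries, 100 bootstrap replicates, 220 identification queries, additive
matrices of 4–8 leaves against exhaustive topology enumeration (≤ 6 leaves)
— were chosen so the full study re-runs in well under a minute while keeping
every per-species count at least as large as the smallest groups in typical
published surveys.

## Known limitations

- The NJ implementation is O(n³) pure NumPy; libraries beyond a few hundred
  sequences will make 1000-replicate bootstraps slow.
- `identity_percent` semantics degrade for unrelated sequences (see above);
  the call threshold guards the reports, but raw identity values below
  ~90% should not be interpreted as alignment coverage.
- Mixture detection requires the caller to provide multiple sequences per
  product; chromatogram double peaks are not modelled.
- Engineering explores substitutions only (no primer shifting or length
  changes), and fragment sizes ignore the 3-nt overhang chemistry — lengths
  are top-strand, as on a gel.
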