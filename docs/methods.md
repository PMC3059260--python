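# Methods

This note documents the models, detectors and numerical conventions behind
`centroscan`, the design choices taken where several were defensible, and
what the synthetic benchmark does and does not establish about real data.

## The element model

A full-length CRM-clade insertion is modeled as

```
TSD | 5'LTR | PBS | (A-rich) 5'UTR | GAG PRO RT RH INT [tail] | PPT | 3'LTR | TSD
```

with the group-specific integrase tail downstream of the GPY/F motif:
group A carries a CR motif and its reading frame continues through the PPT
region into the 3′ LTR before terminating; group B terminates a few residues
after GPY/F with no targeting domain; group C carries a type II chromodomain
and terminates before the 3′ LTR. The two LTRs are identical at insertion
and diverge independently afterwards, which is both a detection obstacle
(exact-repeat finders miss aged pairs) and the dating signal.

Defaults throughout are the observed survey ranges for this element class:
element length 5,100–10,200 bp; LTR length 299–1,225 bp; `TGATG…CATCA` LTR
termini; 5-bp TSD; PBS complementary to 12–18 nt of the tRNA-Met 3′ end;
PPT of 4–13 bp. They are soft, user-configurable bounds — observed ranges of
a survey, not hard biological limits.

## Detection (ltr_detect)

Seed–chain–extend over direct repeats: exact k-mer seeds (k = 13) shared by
two forward-strand positions separated by `[min_elem − max_ltr, max_elem]`
are bucketed per diagonal, chained into runs (max intra-run gap 400 bp), and
extended by ungapped X-drop alignment (match +1, mismatch −2, drop 20).
Boundaries are then refined within ±25 bp so the element starts `TG` and
ends `CA` (required by default), choosing the start/end pair that maximizes
first the 10-point terminal-motif match (`TGATG` + `CATCA`) and then the
ungapped LTR identity. Candidates failing the length, identity (default
floor 0.80 — a detector parameter, not an observed value) or separation
constraints are dropped; overlaps are resolved greedily by detection score
(identity × LTR length + 10 × motif score), preferring the plus strand and
the leftmost start on ties. Both strands are scanned; a direct-repeat pair
is its own strand mirror (`revcomp(TGATG) = CATCA`), so strand is reported
but is not evidential for symmetric candidates.

Substitution divergence is what the extender tolerates; small indels split a
repeat across diagonals and are recovered only as the better-scoring
fragment. The simulator is substitution-only by default for the same reason
the dating literature treats LTR pairs as cleanly alignable.

## Structural detectors (structure)

All detectors operate in the element's 5′→3′ orientation and report forward
genome coordinates.

- **TSD**: the `tsd_len` (5) bp immediately left of the element compared
  with the 5 bp immediately right; equal within `tsd_max_mismatch` (0) is a
  duplication. Elements abutting a contig end return none.
- **PBS**: within 30 bp downstream of the 5′ LTR, the longest stretch equal
  to the reverse complement of a 3′-terminal segment of the packaged
  tRNA-Met terminus (18 nt, configurable — real PBSs correspond to several
  tRNA-Met variants); reported at ≥ 12 nt, ties to the smallest offset.
- **PPT**: the longest unbroken A/G run within 40 bp upstream of the 3′ LTR,
  reported at ≥ 4 bp, ties broken toward the LTR.
- **A-rich stretch**: the longest 5′-UTR window of ≥ 20 bp with ≥ 70% A
  (then trimmed of non-A edges). "A-rich" is nowhere quantified for this
  element class; these thresholds are this package's operationalization.
- **Search windows** (30/40 bp) are likewise package conventions: in every
  published schematic of this element class both features abut their LTRs.
- **Domain cassette**: the internal region plus the 3′ LTR is translated in
  all three forward frames and scanned with per-domain log-odds profiles;
  the best window above each profile's threshold is the hit, with stop
  codons inside the hit counted as disruptions. `intact_orf` requires all
  five domains in cassette order, one frame, zero disruptions.
  `coding_into_3ltr` continues the integrase frame from the end of the INT
  hit to its stop codon and tests whether that end lies past the 3′ LTR
  start — the group A signature. Using the ORF continuation rather than the
  raw profile-hit end makes the flag independent of how long the INT profile
  happens to be.

## Profiles and classification (ptd)

Profiles are position-specific log2-odds matrices. Per kept column
(columns > 50% gaps are dropped), frequencies are
`(count + pc·bg) / (n + pc)` with pseudocount pc = 0.5 and uniform
background; scores are `log2(freq/bg)`. The acceptance threshold of each
profile is calibrated from its own training members as mean − 2 SD of their
profile scores — no external cutoff exists for "similarity to the CR motif",
so the training distribution defines one. Packaged training alignments span
5–25% divergence from the consensus so the threshold inherits a realistic
spread; with uniform-divergence training the 2-SD band collapses and
legitimately diverged queries fall outside it. Sequence-logo information
content is `log2(20) − H` per position from the stored frequencies.

`classify_ptd` anchors on the first GPY/F (G-P-Y or G-P-F) in the integrase
tail, scans the downstream region with both the CR and chromodomain-II
profiles, and maps CR hit → group A, chromodomain-II hit → group C, no hit →
group B (with a low-confidence warning when the tail exceeds 40 aa, the
bound chosen to operationalize "terminates shortly after GPY/F"). A missing
anchor downgrades to whole-tail scanning with a warning. The tail itself is
the translation from the end of the integrase core to the frame's next stop
codon — the ORF's own terminator.

`assign_clade` is a best-hit screen: the query RT is locally aligned
(BLOSUM62, gap open −11 / extend −1) against every member of every
reference panel; the best-scoring member's clade wins, with the margin over
the best competing clade replacing an E-value. Ties break alphabetically so
the result is independent of panel ordering and duplicates. In the pipeline
the screen runs even when the RT profile produced no above-threshold hit
(the best RT-like window is used instead): the screen, not the profile
threshold, decides CRM membership, and a decoy must be screened out rather
than silently skipped.

## Families and dating (families)

Family assignment implements the survey rule: partition by species, then
single-linkage clustering of pairs with global-alignment LTR identity
≥ 70% **and** alignment coverage ≥ 0.8. "Similarity" is operationalized as
percent identity over all alignment columns under match +1 / mismatch −1 /
gap open −5 / gap extend −1; the coverage bound encodes "alignable over the
whole length", whose exact value the rule's source never states.
Single-linkage is the natural closure of a pairwise rule used transitively.
Family ids are deterministic (species + first-seen ordinal).

Dating aligns the two LTRs the same way, counts transitions (P) and
transversions (Q) per ungapped column, and applies the Kimura two-parameter
correction `K = −½ ln(1−2P−Q) − ¼ ln(1−2Q)` (raw `K = P+Q` by flag), then
`T = K/(2r)`. The default rate r = 1.3e-8 substitutions/site/year is the
convention of the LTR-dating literature for plant nuclear DNA; it is
configurable and echoed in the output. Saturated pairs
(`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) and unalignable pairs (coverage < 0.5) raise
errors rather than returning pseudo-ages.

## Phylogeny (phylo)

Distances are observed p-distances with pairwise deletion of gapped columns
(complete deletion by flag) — the "observed distances" convention of classic
tree GUIs; whether those tools deleted gaps pairwise or globally is not
documented, so both are offered with pairwise as default. NJ is canonical
Saitou–Nei with the standard Q criterion, deterministic tie-breaking by the
lexicographically smallest label pair, and zero-clamping of negative branch
lengths with the deficit moved to the sister branch; on additive matrices
the output path metric reproduces the input to 1e-9, and the test suite
checks NJ against a brute-force least-squares fit over all 4- and 5-taxon
topologies. Bootstrap supports come from seeded column resampling; supports
are attached to the full-data tree (not a consensus), matching how such
trees are displayed.

## Small RNAs (smallrna)

Reads of 18–27 nt are matched exactly (default) or with ≤ m substitutions
against both element strands; positions are reported in forward element
coordinates. The distinct-read count de-duplicates identical read sequences,
and TPQ = distinct matches / library size × 250,000. Matching is
strand-symmetric by construction.

## The generator (simulate) — what it emulates and what it does not

`generate_element` assembles a pristine element per the model above:
deterministic reverse-translated cassette (one shared synthetic cassette for
all elements, committed as code, so the repository ships no downloaded
sequence), per-element random LTRs/UTRs, a drawn PBS length (12–18), PPT
length (4–13) and group-conditional A-rich probability (0.8 for group A,
0.1 for B/C — the stretch is common in group A and absent from most B/C
members). For group A the PPT is built from purine-only codons inside the
reading frame and the frame is phased so it enters the 3′ LTR one base after
`TGATG` (avoiding the `TGA` in the motif itself), stays open for 15 codons
and terminates — giving a literal coding-into-the-LTR architecture whose
flag can be asserted. Aging mutates each LTR copy independently at
rate × age expected substitutions per site, transition-biased with
ti/tv = 2. `internal_divergence` additionally mutates the ORF codon-aware
(stop-creating substitutions vetoed, emulating purifying selection); 0.02
substitutions/site yields roughly 5% amino-acid divergence, the level used
by the classification benchmark.

`implant_elements` duplicates the 5 bp 3′ of each cut to create the TSD and
returns final coordinates. `generate_benchmark` produces the standard
fixture: 25 elements (9 A / 8 B / 8 C) in families of size 1–3 (members
share a template; each member's LTR pair is aged independently), one non-CRM
decoy (chromodomain-II tail, Tekay-like RT), and a 1,200-read small-RNA
library (500 element-derived + 700 background) with a 24-nt modal length.
Benchmark implants are spaced ≥ 9.5 kbp apart: family members carry
near-identical LTRs, and a cross-element LTR pair at a separation inside
the detector's element-length window would constitute a false direct-repeat
candidate that passes every filter (it starts `TGATG` and ends `CATCA`);
a gap above the maximum element length keeps every cross-element pair out
of the separation range by construction. `implant_elements` itself only
enforces the 1 kbp minimum.

What the benchmark does **not** emulate: nested insertions, solo LTRs and
truncated elements (out of scope for the detector too), tandem-repeat host
background (host DNA is i.i.d. uniform), indel mutation (optional in
concept, off by default), transduplication or family-level sequence
turnover. Passing the recovery tests therefore shows the detectors are
correct against the stated element model, not that they are robust to every
artifact of real plant genomes — repeat-dense backgrounds in particular
would demand masking steps this package does not include.

## Problem sizes and determinism

The test suite and acceptance script run the benchmark at its default 25+1
elements (~460 kbp genome, ~10 s for the full chain), 100 oracle matrices
for NJ, 200 replicates for dating calibration and 100 bootstrap replicates
— sizes chosen so the whole suite completes in well under a minute per
module on one core while keeping binomial noise far from the asserted
tolerances. Every stochastic path takes an explicit seed (Python
`random.Random` or `numpy` generators), and pipeline outputs are a pure
function of (inputs, configuration, seed); byte-identical reruns are
asserted in the tests.

## Known limitations

- Boundary refinement depends on the `TG…CA` termini; an old insertion that
  has mutated a terminal base is recovered with a shifted boundary (and
  then typically without its TSD). The recovery criteria are quoted at
  ≥ 90% within ±5 bp for ~1 My-old elements for this reason.
- The clade screen's margin is a score difference, not a significance
  measure; it replaces database E-values, which are meaningless against
  small packaged panels.
- `ltr_identity` coverage uses aligned (both-non-gap) columns over the
  longer sequence; heavily end-truncated LTRs therefore read as
  low-coverage rather than low-identity, and fall to the "cannot be
  aligned over the whole length" branch of the family rule.
- Group B classification does not test for an intact downstream stop codon;
  a long PTD-free tail is still called B, with a warning.
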