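# Methods

`vhhkit` curates heterogeneous single-domain antibody (sdAb/VHH) records
into a harmonized dataset and profiles it: per-region conservation and
Shannon entropy, amino-acid composition with a lysine/cysteine focus,
region-length statistics, and non-parametric species comparisons. This
note documents the models, conventions, and numerical choices, and what
the synthetic repertoire generator does and does not emulate.

## The record model and curation funnel

A record is one sdAb: an identifier, a species of origin, a full
amino-acid sequence, and the seven region strings FR1, CDR1, FR2, CDR2,
FR3, CDR3, FR4 whose concatenation equals the full sequence. Species
labels are consolidated into four categories — *Lama glama*, *Vicugna
pacos*, *Camelus dromedarius*, *Camelus bactrianus* — through an editable,
case-insensitive synonym table; generic or underspecified labels
("camelid", "mixed library", bare "Camel", which cannot distinguish
Bactrian from dromedary origin) map to an `AMBIGUOUS` sentinel and are
removed at eligibility checking. Placeholder strings ("NA", "N/A", "-",
empty) are normalized to absent before any eligibility decision, so
missing optional metadata (antigen, DOI, PDB code, affinity) never poses
as a value, and records missing *only* optional metadata are retained.

Curation is a fixed-order funnel — species harmonization, mandatory-field
eligibility, sequence reconstruction/delineation, canonical-alphabet
check, completeness check, exact-duplicate removal (full sequence as the
key; survivor chosen by source priority, then lexicographic identifier,
so the outcome is order-independent), and artificial-sequence removal.
Every step appends `(step, records in, records removed)` to the funnel,
and `|survivors| + Σ removed = |ingested|` holds for every run. The order
is fixed so funnel counts are reproducible; each removed record also gets
a per-rule verdict.

### Artificial-sequence rules

Some deposited entries obscure the real sequence (confidentiality,
IP): residues sorted alphabetically, or homopolymer/low-complexity
strings. Two rules with deliberately disjoint footprints:

* **alphabetical order** — the whole string is non-decreasing in the
  one-letter alphabet *and* has ≥ 5 distinct residues (default). The
  distinctness floor keeps this rule off homopolymers so each artifact is
  attributed to exactly one rule.
* **low complexity** — longest single-residue run ≥ 10, or the modal
  residue strictly exceeds 50% of the sequence. Genuine VHHs rarely show
  runs above 5, so the defaults are conservative; both thresholds are
  configurable. A string that is exactly half one residue with runs of 1
  (e.g. alternating GA) deliberately passes.

Ambiguity codes (X/B/Z, stops) reject a record at QC; gap-masking of
stray non-canonical characters happens only inside alignment building,
where the two concerns are different (QC decides admission, alignment
decides column accounting).

## Region delineation

The reference path for FR/CDR boundaries is external numbering (e.g.
IMGT-style tools), ingested as per-record `(start, end)` pairs (1-based
inclusive in files, 0-based half-open internally) and applied verbatim
under the scheme tag `imgt-external`. Deposited region strings are kept
as `as-deposited`; when a deposited full sequence disagrees with the
regions' concatenation, the regions win (all downstream analyses are
region-keyed), the sequence is replaced by the concatenation and the
record flagged.

When only a full sequence is available and no external numbering is
supplied, a deterministic motif-anchored fallback exploits the
near-invariant VHH architecture:

1. FR1 ends 3 residues after the first Cys in window [15, 35) (the
   canonical FR1 cysteine);
2. FR2 starts at the first Trp within 20 residues of CDR1's start and has
   near-fixed length 17;
3. FR4 starts at the C-terminal-most W-G-x-G match;
4. the FR3/CDR3 junction falls 3 residues after the Cys *closest to its
   expected canonical position* (CDR2 start + 8 + 34). Choosing the
   closest — rather than the last — Cys candidate keeps the junction
   stable when a non-canonical cysteine sits inside CDR3, which is the
   common case in camel-derived sdAbs;
5. FR3 is assigned its near-fixed length 38, which fixes the CDR2/FR3
   junction (the one junction with no local anchor).

All windows, lengths, and the motif are configurable
(`AnnotatorConfig`). Fallback-annotated records carry the
`anchor-heuristic` scheme tag and a `fallback_annotation` flag: the
heuristic is a convention of this package, not IMGT numbering, and region
boundaries from different schemes should not be mixed silently. Sequences
where an anchor cannot be found (no Cys in the FR1 window, no FR4 motif,
degenerate segmentation, length outside [90, 180]) fail annotation and
are dropped with a funnel entry.

## Conservation and entropy

No multiple sequence alignment is performed — gap-opening heuristics
create artifacts in hypervariable loops. Instead each region is analyzed
independently: the cohort's region strings are padded with `-` to the
longest member's length (right-padding by default, preserving N-terminal
anchoring; left/center available), forming a rectangular matrix. For
column *j*, with n(a, j) the gap-excluded count of residue *a* and
N(j) = Σ_a n(a, j):

* consensus_j = argmax_a n(a, j), ties broken alphabetically (the data
  cannot distinguish tied residues; determinism requires a rule);
* consensus frequency = max_a n(a, j) / N(j);
* entropy H_j = −Σ_a (n/N) log₂(n/N), in bits, ranging 0 (perfect
  conservation) to log₂ 20 ≈ 4.322 (uniform over the 20 residues).

All-gap columns report missing statistics (NaN), not zeros — a column
with no observations has no consensus. Per-region summaries average over
columns with N(j) ≥ 1, optionally coverage-weighted so sparsely populated
tail columns (created by length variation) count less. The same machinery
runs pooled and per species; column counts are additive across disjoint
cohorts by construction. The vectorized implementation is checked against
an independent pure-Python tally to 1e−12.

Statistics are computed for all seven regions by default; for CDRs the
padded columns conflate length variation with substitution variation, so
CDR columns should be read jointly with the length statistics.

## Composition, Lys/Cys, lengths, molecular weight

Composition is length-weighted pooling, f(a) = Σ_i n(a, i) / Σ_i L_i —
not a per-sequence average — reported as percentages. Global frequencies
therefore equal the region frequencies recombined with region residue
counts, which is tested.

Lysine and cysteine get a dedicated per-(cohort, region) table with three
metrics — the residue's share of the region's residues, mean copies per
sequence, and the fraction of sequences with ≥ 1 copy — because
enrichment (a frequency statement) and presence (a per-molecule
statement) answer different bioconjugation questions (amine-directed NHS
chemistry targets lysines; thiol chemistry and unwanted disulfides turn
on whether *any* extra cysteine is present). All three are emitted rather
than collapsing to one.

Length statistics use the sample (n−1) standard deviation and
RSD = 100·SD/mean. Molecular weight uses average (not monoisotopic)
residue masses plus one water, in kDa — at ~110 Da per residue a typical
124-residue VHH weighs ≈ 13.6 kDa.

## Group comparisons

Region-length (and other scalar) contrasts between species use the
conventional battery for non-normal cohort data: Shapiro–Wilk per group
(reported, not gated on), Kruskal–Wallis omnibus, and all pairwise
two-sided Mann–Whitney tests with Holm adjustment, labelled at the
0.05/0.01/0.001 tiers. Groups below `min_n` (default 50) are excluded
from testing but always listed with the reason — a 35-member cohort from
a single source is too fragile to test but should not vanish silently.
The tests come from scipy/statsmodels; this module's contribution is the
orchestration, the exclusion rule, and the adjustment bookkeeping.

## The synthetic repertoire generator

The generator emulates the curated-data regime the analyses target, with
species counts defaulting to the reference census proportions
(1316/325/377/35 for llama/alpaca/dromedary/Bactrian):

* **Frameworks**: fixed-length consensus strings per species (25/17/38/11
  residues), shipped as data, carrying the canonical FR1/FR3 cysteines,
  the FR2-opening Trp, a hydrophilic FR2 with the VHH hallmark residues,
  lysines concentrated in FR3 (3 of 38 positions) with a secondary FR2
  lysine, and the FR4 W-G-x-G motif. Each unprotected position is
  substituted with probability 0.02 by a residue drawn from a background
  that excludes Cys and Trp (reserved as anchors) and up-weights Lys in
  FR2/FR3. Anchor positions are never substituted — real repertoires
  conserve these residues at essentially 100%, and the generator's noise
  model is not meant to simulate loss of the immunoglobulin fold.
* **CDR lengths**: rounded normals floored at 3, with per-species
  means/SDs set to the published repertoire summaries (e.g. alpaca CDR3
  15.2 ± 4.4, llama CDR1 8.8 ± 2.1). The law's exact discrete moments are
  exposed (`RoundedNormalLaw.mean()/sd()`), so recovery tests target the
  true generating values, not the nominal Gaussian parameters.
* **CDR composition**: i.i.d. draws from a Gly/Ser/Tyr-rich weight table
  excluding Cys and Trp.
* **Non-canonical cysteines**: with per-species, per-region probability
  (0.8 for Bactrian/dromedary CDR1 and CDR3, 0.1 for llama CDRs, 0.4 for
  alpaca FR2), one position is *replaced* by Cys — a uniformly chosen CDR
  position, or a fixed FR2 position. Substitution rather than insertion
  keeps the length laws exact and the presence fraction equal to the
  configured probability, and matches the framework case, where the extra
  cysteine occupies a fixed scaffold position.
* **Decoys and duplicates**: exact full-sequence clones under fresh
  identifiers (2% by default), plus alphabetical and homopolymer decoy
  records carrying deposited-style bogus region strings, all listed in a
  truth manifest alongside per-record boundaries and per-species analytic
  parameter values.

One RNG stream seeded from a single integer (default 20251125) drives all
sampling; identical config gives byte-identical output.

What the generator does **not** emulate: germline V-gene usage and
somatic hypermutation structure, positional (non-i.i.d.) CDR composition,
residue covariation, length-composition coupling, CDR tryptophans,
indels in frameworks, sequencing error, or inter-database numbering
disagreements. Passing recovery tests therefore demonstrates that the
pipeline correctly measures what the generator encodes — length laws,
conservation levels, residue enrichments, presence fractions — not that
real repertoires satisfy those laws.

## Problem sizes and numerical choices

Unit and property tests run cohorts of 150–300 records per species;
parameter-recovery checks use 1,000 per species (recovery tolerance is 3
standard errors of the relevant estimator, with binomial SEs for
presence/frequency metrics and the law SD for length means); the
operating-characteristics check uses 200 replicate null pairs at n = 100
per group. The entropy oracle comparison covers 1,000 random columns of
≤ 8 rows at 1e−12 absolute tolerance. Consensus ties break
alphabetically; all-gap columns are NaN; Holm adjustment uses the
standard step-down ordering. The acceptance script regenerates the
census-proportioned cohort from its `--seed`, curates it, and recomputes
every reported quantity at run time.

## Known limitations

* The fallback annotator is a heuristic tied to the canonical anchors; on
  real sequences with unusual FR1 cysteine spacing, CDR tryptophans, or a
  missing FR4 motif it will drop or mis-split records (it drops rather
  than guesses). External numbering remains the reference path.
* Deduplication is exact-match only; near-duplicates (one substitution
  apart) are retained by design.
* The delineation convention of deposited regions is generally unknown;
  the `scheme` tag preserves that uncertainty but cannot resolve it, and
  mixed-scheme cohorts blur column statistics near region boundaries.
* Species categories are taken at face value from depositor labels after
  synonym mapping; mislabelled depositions pass through.
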