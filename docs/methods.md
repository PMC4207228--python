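# Methods

## The curation model

`regumine` treats literature curation of transcriptional regulation as a
pipeline over *sentences*, not documents.  The unit of extractable knowledge
is the regulatory interaction (RI): a tuple of transcription factor (TF),
effect (activation or repression), target gene or transcription unit, and —
when stated — the growth condition (GC) under which the effect was observed
(an experimental condition paired with its control, e.g. hydrogen peroxide
treatment versus untreated).  The working hypothesis is that sentences
mentioning a target gene together with an effect word also carry the GC when
one exists, so a gene-AND-effect sentence filter loses little while
discarding the large majority of a paper's text.

Each informative sentence maps to one of three normalized forms, always the
most complete form its components allow:

* `TF [effect] gene [GC]` — complete;
* `TF [effect] gene` — condition not stated;
* `[effect] gene [GC]` — regulator not stated (effects are displayed as
  "induction"/"inhibition" in this form, since the mechanism is unknown).

A structure with neither TF nor GC matches none of these and is not emitted:
a bare `[effect] gene` assertion adds nothing a later full statement would
not supersede.

## Dictionary matching

Entity recognition is gazetteer-based: lexicon entries (gene, TF, operon,
effect, growth condition) are matched at word boundaries with orthographic
variants (hyphen/space interchange for multi-token terms).  Numbers that
matter:

* **Short-name threshold, 4 characters.**  Entries of ≤ 4 characters match
  case-sensitively; longer entries case-insensitively.  Most *E. coli* gene
  names are exactly 4 characters and collide freely with English ("fold",
  "flu"), while strict capitalization everywhere would miss authors who do
  not follow nomenclature conventions.  The threshold splits the difference
  and is a property of the entry, not a config knob.
* **Stoplist.**  Known-ambiguous short surfaces ("fold") are additionally
  suppressed in numeric contexts ("two-fold", "2-fold").  The stoplist ships
  as data and is user-extensible.
* **Overlap resolution: longest match wins, leftmost on ties** — the
  standard gazetteer convention; "hydrogen peroxide treatment" beats
  "hydrogen peroxide".
* **Gene/TF dual membership.**  Every TF is also a gene.  A surface
  registered in both dictionaries is classed by orthography: capitalized
  protein form ("OxyR") annotates as TF, lower-case gene form ("oxyR") as
  gene.  For ≤ 4-character names the case-sensitivity rule makes this
  automatic.

Synonym sets share one canonical *reference term* (chosen as the most
frequent corpus form, e.g. "oxidative stress" over "oxidizing conditions");
normalization is idempotent.  GC entries may carry a parent link one step up
a general/specific hierarchy (hydrogen peroxide treatment → oxidative
stress), used by the relaxed GC-matching mode of the evaluator.  Regulatory
*system* names (ArcAB) resolve to their DNA-binding member (ArcA) through
explicit alias rows; shortened operon forms ("suf") are explicit alias rows
too — no automatic expansion is attempted.

## Effect and condition scoping

Curators resolve scope by reading; the package approximates it with rules
whose regression anchor is the two-clause worked example shipped in the
example corpus:

* Clauses split at contrast markers ("while", "whereas") and semicolons.
* Within a clause, every target gene takes the *nearest* effect annotation;
  coordinated gene lists distribute that effect over every listed target.
* A GC annotation attaches to all structures of its own clause only — a
  condition mentioned in the repressing clause never leaks into the
  activating clause.
* The TF of a structure is the TF annotation of its clause; when a clause
  names none, the sentence-level TF set is inherited (contrast clauses
  routinely elide the regulator).  With several TFs, one structure per TF is
  emitted.
* Unannotated gene-like tokens coordinated with a recognized gene ("the oxyR
  and mom promoters") are carried as candidate targets so the exclusion step
  can record them as out-of-dictionary rather than silently losing them.

## Exclusion rules

Applied independently per structure, each with a reason code:

| rule | behaviour |
|---|---|
| target not in dictionary | excluded (not a gene of the organism) |
| ambiguous shortened operon | excluded |
| sigma factor with negative effect | excluded — sigma factors recruit RNA polymerase, so a negative effect is necessarily indirect |
| underspecified GC (bare "pH") | excluded |
| uninformative GC ("normal growth", "during growth") | GC dropped; structure demoted to the no-GC form |
| non-directional effect ("regulated", "not repressed") | kept, `validation_only` — tallied but never voting |
| explicit "no effect" | kept as a negative-result record, never merged into directional counts |

The uninformative and underspecified term lists ship as defaults on
`ExtractionConfig` and are configurable.  Mutant cues (Δ-prefixed tokens,
"mutant", "deletion of") only set a provenance flag; mutant semantics (an
effect observed in a deletion strain is inverted) are not modeled.

## Aggregation and conflict resolution

Records are keyed by (TF, target) after normalization, with support counts
per polarity and GC lists as counted unions; aggregation is order-independent
by construction.  **Majority ratio 0.9**: a polarity holding ≥ 90% of the
directional support wins, any minority keeps the record `conflicting`, below
the threshold the effect is `dual`.  The value reproduces both canonical
conflict cases in the benchmark (65-vs-1 and 18-vs-1) with margin and is a
keyword argument.  Non-directional and no-effect counts never vote.

Complementarity: a `TF [e] gene` record plus an `[e] gene [GC]` partial with
matching target and polarity yields a *hypothesized* full record, unless a
full-form sentence already attests that GC — a hypothesis never overwrites
observed support.

## Source attribution

Sentences are tagged by their strongest evidence cue, precedence
figure/table > experimental phrasing > citation, because a pointer to the
paper's own figure is the most direct sign of the authors' experiment.
Candidate papers score additively (weights on `AttributionWeights`):

* +1 per distinct supporting sentence;
* +2 if any of the paper's supporting sentences is evidence- or
  figure/table-tagged;
* +3 if the paper asserts the interaction in ≥ 3 sentences (the
  "mentioned more than three times" heuristic, read inclusively because the
  benchmark's worked case has exactly three assertions and is attributable);
* +2 per supporting sentence that *cites* the paper (candidate originals
  surface this way even when outside the corpus; the weight makes a cited
  original outrank a one-sentence citing paper).

The scheme is an invented operationalization of qualitative strategies; the
katG benchmark is its regression anchor.

## Evaluation

Matching key is (TF, target) after normalization; gene targets match operon
targets only through an explicit operon-membership table (shipped for the
benchmark's transcription units).  Effect agreement counts gold effect =
resolved effect, with `dual` resolutions counted as disagreement.  GC
coverage is the fraction of gold records with at least one matching
extracted condition; `general_ok` mode also accepts a term one parent-link
step away.  Percentages are reported to the nearest integer, matching
curation-report convention.

## Synthetic corpora

The generator plants known (TF, effect, target, GC) tuples into template
sentences that mirror the phrasings the scoping rules must handle: passive
single-target statements, coordinated lists under one governing verb, and a
contrast template whose second clause elides the TF.  Defaults emulate the
scale of a single-TF curation corpus — 48 documents × 250 sentences with
distractor rate 0.886 (≈ one informative sentence in nine) and synonym noise
0.2; tests use smaller corpora (3–6 documents × 30–60 sentences) with the
same structure, sized so the full suite runs in seconds.

Noise dials and what they demonstrate:

* `synonym_noise_rate` — planted terms render as non-reference synonyms;
  extraction must normalize them away (exactness is preserved at any rate).
* `unknown_synonym_rate` — terms render as out-of-dictionary surfaces;
  recall must degrade monotonically (verified at rates 0/0.25/0.5/1).  Every
  rate decision consumes a random draw whether or not it fires, so runs at
  different rates under one seed are aligned event-for-event and the
  monotonicity check is exact rather than statistical.
* `conflict_rate` — tuples re-emit with flipped polarity, logged in the
  truth table; aggregation support counts must match the generator's own log
  and majority voting must recover planted polarities whenever the empirical
  flip share is below 1 − majority_ratio.

What the generator does *not* emulate: real linguistic variety (anaphora,
cross-sentence context, hedging, interrogatives), section structure, and
citation networks.  Passing synthetic tests therefore demonstrates the
mechanics of matching, scoping, exclusion and aggregation — not linguistic
generality; the curated benchmark tables cover the realistic phrasings the
rules were designed against.

## Numerical and degenerate-input choices

* Character offsets are 0-based half-open; sentence IDs default to
  "S"+ordinal; text is NFC-normalized before matching.
* Sentence segmentation protects a fixed abbreviation list ("E.", "Fig.",
  "et al.", ...); degenerate input (no terminal punctuation) is one segment.
* An empty corpus is an error for statistics; an empty gold set is an error
  for comparison; an empty extraction scores precision 1.0 by convention.
* Attribution ties break by ascending document ID for determinism.
* In the attribution benchmark, the headline sentence count is the number of
  printed assertion rows (a sentence recorded with two structures is two
  assertions), while per-paper frequency counts deduplicate by sentence ID.

## Known limitations

Single-sentence scope: anaphora ("this gene"), cross-sentence mutant
descriptions, and interrogative/hypothetical classification are out of
scope.  The effect-word list covers the benchmark's vocabulary and is
extensible as data, but is not exhaustive.  The clause/nearest-effect
scoping is an approximation that can mis-scope sentences with long-distance
dependencies; dependency parsing is deliberately not used.
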