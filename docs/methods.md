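# Methods

## Pipeline

A report is processed in six stages.

**1. Section segmentation.** Headers are matched case-insensitively at line
starts or after sentence boundaries, with an optional trailing colon, and
mapped to five canonical sections (Comparison, Technique, Clinical History,
Findings, Conclusions — "Impression" and "Conclusion(s)" both map to the
last; "History"/"Indication" to Clinical History). Text before the first
recognized header becomes an `OTHER` section. Measurements are extracted
from the Findings section(s); a report with no recognized header at all
(common in mammography dictation) falls back to processing the whole body.
All spans are 0-based half-open intervals over the decoded unicode text.

**2. Sentence splitting.** A rule-based splitter breaks on `.!?` followed by
whitespace, except inside parentheses, after a decimal digit on both sides
of a period, or after single-letter/known abbreviations. This keeps long
Findings sentences with internal parentheticals and semicolons intact —
which matters, because multi-measurement sentences are exactly where
sub-sentence division is needed.

**3. Measurement, temporality and scan-reference tagging.** The measurement
grammar accepts an integer or decimal number, an optional range
("4-5 mm", valued at the larger endpoint), units in {mm, cm,
millimeter(s), centimeter(s)} normalized to mm/cm, and up to three
dimensions joined by "x"/"×" with per-dimension or trailing shared units.
The final dimension must carry a unit, so bare number pairs never trigger.
Temporality defaults to `CURRENT`; a mention is `PRIOR` when the nearest
preceding cue is a prior cue (previously, previous, prior, was, compared
to/with, from <date>) whose scope still covers it — a scope ends at the next
cue of either polarity (now, currently, today are current cues), at the
parenthesis closing around the cue, or at sentence end. Image, series and
segment references accept common dictation variants (image(s)/img/im,
series/ser/se, segment(s)/seg, optional "#"/":") and require a numeric tail,
so "imaging was performed" never fires. Units are reported as written; no
unit conversion or date normalization is performed.

**4. Sub-sentence division.** A sentence with *k* measurements is split into
exactly *k* contiguous fragments, one measurement each, partitioning the
sentence. Between consecutive mentions the boundary is chosen from delimiter
candidates (after ")", "," or ";", before "("), with two cue-driven
constraints that keep a prior cue with its prior mention: if the following
mention is PRIOR with its cue inside the gap, the *latest* delimiter before
the cue is taken (so "(image 127," stays with the current 4 mm, and
"previously 7 mm)" forms the historical part); if the preceding mention's
prior scope closes inside the gap, the *earliest* delimiter after the scope
end is taken. With no applicable constraint, parenthesis delimiters are
preferred, then commas/semicolons, then the whitespace nearest the midpoint.
An entity straddling a boundary cannot occur for linking purposes because
every character belongs to exactly one sub-sentence.

**5. Entity tagging.** Sub-sentence text is lowercased and stripped of
punctuation *after* measurement and reference tagging, with those spans
protected verbatim and an offset map kept so entity spans always resolve
back to the original sentence. Two interchangeable taggers label anatomical
entities, imaging observations and RadLex-style descriptors:

* *Dictionary baseline*: greedy leftmost-longest case-insensitive lookup in
  three packaged term lists (~100 anatomy terms with laterality compounds,
  ~50 observations, ~50 descriptors; user-replaceable, with naive plural and
  punctuation-stripped fallbacks). Also used to pre-annotate corpora for the
  light-annotation workflow (automatic pre-annotation followed by manual
  correction).
* *Linear-chain CRF*: trained by L-BFGS on the exact conditional
  log-likelihood with an L2 penalty (c2 = 1.0, max 100 iterations — the
  conventional defaults of CRF toolkits), decoding by Viterbi. Token
  features are the lowercased form, the POS tag from a compact rule/lexicon
  tagger, per-lexicon dictionary-map flags, 3-character affixes, a digit
  flag, and the same features for ±2 neighbors with BOS/EOS sentinels;
  deliberately no NP-chunk or parse features. Label sequences are repaired
  to BIO validity (headless I-X becomes B-X). Models serialize to JSON and
  reload with bit-identical predictions. The CRF is implemented in this
  package on numpy/scipy; forward-backward runs in log space, so the
  gradient is exact and training is deterministic.

  By default the CRF label set covers only the three entity types;
  measurement/image/series/segment/temporality spans are rule-tagged. For
  transition-score analysis they can be included as labels
  (`include_rule_labels`), and the learned transition table is exported raw,
  with an optional softmax view per source label that is explicitly a
  rescaling, not a true conditional probability.

**6. Frame assembly.** Each sub-sentence produces one frame. Entity surfaces
in the sub-sentence fill the three text slots; image/series/segment take the
nearest in-sub-sentence reference, else the nearest *sentence-scope*
reference (one appearing before the first measurement, like a leading
"series 11", shared by all frames of the sentence). A PRIOR frame whose own
fragment names no entities inherits anatomical entity and imaging
observation from the nearest preceding CURRENT frame, since a quoted prior
size describes the same finding; image numbers are not inherited, because a
prior size was not measured on the current scan's images.

## Evaluation scheme

System and gold frames align when their measurement spans overlap and their
value and unit agree; among multiple candidates the pairing with the most
matched descriptors wins, leftmost on ties. Per information type
(measurement + 7 descriptors), precision/recall/F are computed from TP/FP/FN
with text slots compared exactly after lowercasing and whitespace collapse,
numeric slots by equality and temporality by label; undefined denominators
yield an explicit undefined marker, never a silent zero. Per measurement,
the match category is FULL when every gold descriptor is matched (a
descriptor absent from both sides is vacuously satisfied; extra system
values never demote a category), NO_MATCH when none is, and PARTIAL
otherwise. A descriptor-combination table counts frames whose matched set
covers each requested combination; it is antitone in combination inclusion
by construction. Scoring is entity-level, not token-level.

## Synthetic data

The generator emulates Findings-section dictation with four template
families — observation-first ("There is a scattered nodule in the left
upper lobe measuring …"), measurement-first ("4 mm left frontal nodule
(image 127, previously 7 mm)"), series-prefix enumerations ("On series 11,
for example …, …"), and segment sentences ("Segment 5 lesion measures …") —
mixed with measurement-free filler sentences under conventional report
headers. Defaults: 100 reports of 3–6 measurement sentences each; 1/2/3
measurements per sentence with probability 0.7/0.2/0.1 (multi-measurement
sentences are the system's hardest documented case); a prior-pair
probability of 0.3, matching roughly one historical reference per three
measurements in clinical follow-up reporting; 1/2/3 dimensions with
probability 0.6/0.25/0.15; mm:cm mix 0.7:0.3. Every measurement sentence
carries three mutually consistent gold views: frames (JSONL), standoff
entity spans (JSONL), and token-level BIO (TSV). All randomness flows from
one integer-seeded `random.Random`; lexicon draws are from sorted term
lists, so corpora are identical across platforms and hash seeds.

Surface-variant injection (rate 0.1) introduces benign typos into entity
words — the only source of out-of-lexicon forms — to emulate the lexical
variation that motivates a trainable tagger. A corruption utility
additionally drops or shrinks gold entity spans to simulate uncorrected
dictionary pre-annotation for light-annotation robustness studies.

What the generator does **not** emulate: institution-specific templates and
macros, dictation disfluencies and truncated sentences, negated or
hypothetical measurements, cross-sentence coreference, and realistic report
length distributions. Tests passing on synthetic corpora therefore
demonstrate internal consistency (grammar containment, count conservation,
learnability of the closed vocabulary) — not clinical-grade accuracy on real
reports, which would require annotated clinical data.

## Numerical and design choices

* CRF training objective and gradient are exact; L-BFGS runs to `ftol`
  1e-8 or 100 iterations. Viterbi ties break toward the lower label index;
  the label order is fixed at training time, so decoding is deterministic.
* Experiment scale: the recovery experiment trains on 800 annotated
  sentences and evaluates on 200 held-out sentences from the same
  generator, sizes chosen to mirror a realistically annotatable corpus while
  keeping the experiment desk-runnable; held-out entity F at these sizes is
  effectively 1.0 (asserted ≥ 0.9 with a ±0.05 stochastic band).
* Sub-sentence boundary preference deviates from a plain
  "parenthesis-first" rule: cue-constrained delimiter choice (latest before
  a prior cue / earliest after a prior scope) is required so that a
  parenthetical carrying both an image reference and a prior size splits
  between them, keeping the image number with the current measurement — the
  behavior the multi-nodule worked example documents.
* Ranges ("4-5 mm") are a single mention valued at the larger endpoint; the
  full range is retained in the surface string.
* Greedy dictionary ties at equal length break anatomy > observation >
  descriptor; this only matters for pathological lexicons that share terms.
* Degenerate inputs: empty reports yield empty section lists; sentences
  without measurements yield no frames; an empty training corpus or a label
  outside the declared label set raises an error; overlapping protected
  spans during normalization raise, signalling a tagger inconsistency.

## Known limitations

* Temporality uses in-sentence cues only; a Comparison-section context
  ("compared to CT of 3/2/2019") does not propagate into Findings
  sentences.
* Descriptor linking is purely positional within the sub-sentence; no
  relation classifier filters spurious associations, so a modifier stated
  once for an enumerated list attaches only to the nearest measurement.
* Image/series inheritance is sentence-scoped, not paragraph-scoped.
* The packaged lexicons are deliberately small; production use should
  substitute institution-curated RadLex/anatomy dictionaries via the config.
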