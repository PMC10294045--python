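# Methods

This note documents what each assessment computes, the defaults and why,
the numerical and design choices made where the design was open, what the
synthetic-text generator does and does not emulate, and known limitations.

## Text model

All assessments run over a single immutable `Document`: normalized text
(Unicode NFC, LF line endings, smart quotes/dashes mapped to ASCII), tokens
with 0-based half-open character spans, sentence and paragraph spans, and a
coarse grammatical tag per word token. The pipeline is fully rule-based, so
identical input bytes always produce an identical document — a property the
whole feedback loop (assess, edit, re-assess, compare) relies on.

**Tokenization.** Words keep internal apostrophes and hyphens ("don't",
"X-rays" are single tokens); numerals and punctuation are separate tokens.
Words and numerals both count toward sentence length. All-caps alphabetic
tokens of 2–5 characters are treated as acronyms: they count as words for
sentence length but are excluded from syllable-based counts, since a letter
string like "CVD" has no stable syllable reading.

**Sentences.** A sentence closes at `.`, `!` or `?` followed by whitespace
and a capital/digit/quote (or end of text), with a shipped, editable
abbreviation list ("Dr.", "e.g.", single initials) guarding false splits —
segmentation errors feed straight into the SMOG denominator, which is why
the list is a user-replaceable resource. Any line break also closes a
sentence, so headings and bullet items without terminal punctuation form
their own sentences. This over-splits hard-wrapped prose; health texts are
normally soft-wrapped, and the behaviour is the documented contract.

**Syllables.** Dictionary first: a shipped pronunciation table (~70 entries)
covers words the fallback mis-counts, with an emphasis on health vocabulary
("diabetes" → 4, "cardiovascular" → 6). Otherwise a deterministic fallback
counts vowel groups (y vocalic after a consonant) with silent-e suppression,
syllabic `-es` after sibilants ("choices" keeps it, "makes" does not),
`-ed` kept only after t/d ("wanted" vs "walked"), and consonant+`-le(s)`
restoration ("people", "tables"). Hyphenated compounds sum their parts;
counts are case-insensitive and never below 1.

**Coarse tags.** A closed-class cascade: be/get forms plus modals and
have/do are `aux`; determiners, prepositions, conjunctions and pronouns are
`other`; irregular past participles are `participle`; then small
common-verb/adjective lists and suffix rules (`-ly` adverb, `-ed`
participle, `-ing` verb, `-ous/-ful/-ive/...` adjective), defaulting to
noun. This is deliberately not a statistical tagger: it is deterministic,
inspectable, and accurate enough for the two downstream uses (passive
detection and content-word identification).

## Readability

The all-sentence SMOG generalization `1.043·√(P·30/S) + 3.1291` with
`P` = polysyllabic words (≥ 3 syllables, acronyms excluded) and `S` =
sentences. The 30-sentence normalization makes the score length-invariant;
the formula floor is 3.1 at `P = 0`. Scores display at one decimal place,
rounded half-up, so users can watch the score move as they edit; all
comparisons and the grade-target check use the raw value.

Span-level feedback folded into readability:

* **Long words** — every word of ≥ 3 syllables, with a
  use-a-shorter-word message. Excluded words are still flagged here: the
  exclusion mechanism adjusts scores, not visibility.
* **Long sentences** — more than 15 words (configurable). The tool's
  source material gives no cut-off; 15 was chosen so that the documented
  18-word example sentence flags while its 12- and 9-word revision is
  clean.
* **Long lists** — more than 4 items inside one sentence (configurable),
  with advice to use dot points. Items are comma-separated segments plus
  one extra item when the final segment contains a mid-segment "and"/"or";
  a leading coordinator after an Oxford comma does not double-count. A
  sentence with no comma is never a list.

**Exclusions and the revised grade.** Up to five single words (a hard
limit) can be excluded, stored lowercase. They suppress complex-language
flags for those terms and remove their occurrences from `P` in the
*revised* grade; the sentence count is unchanged, so revised ≤ headline
always, with equality exactly when no excluded word occurs. The headline
grade never applies exclusions, and the revised grade is rendered only in
the printable summary.

## Style assessments

**Complex language.** Case-insensitive leftmost-longest matching of the
shipped lexicon (~170 terms: medical jargon, public-health terms, uncommon
general words, each with ordered plain-language alternatives, possibly
none). Single words match on a crude lemma family (inflectional suffix
strips: "adequately" → "adequate"); multiword terms ("myocardial
infarction") match as token n-grams. Suggestions are display-only — the
package never rewrites the user's text, because auto-replacement changes
meaning in ways a rule system cannot vouch for. The global score is the
count of flagged occurrences.

**Passive voice.** A be/get auxiliary followed within three word tokens of
the same sentence by a past participle, allowing intervening auxiliaries
and adverbs ("was quickly tested", "may be changed"); each matched
participle is consumed so chained auxiliaries yield one flag. There is no
parser behind this: adjectival participles ("the nurse was tired") will
false-positive. That trade-off is accepted and documented — a real-time
rule-based tool favours recall and speed over parse-level precision.

**Person-centred language.** Word-boundary, case-insensitive phrase rules
from an editable TSV (pattern → preferred phrasing → one-line rationale),
longest pattern winning on overlap. The shipped starter set covers
person-first phrasing ("person with diabetes" for "diabetic"), age and
disability labels, and suffering/victim framing.

**Lexical density** is content words (nouns, non-auxiliary verbs,
participles, adjectives, adverbs) over all word tokens. **Lexical
diversity** is the moving-average type-token ratio with window 50 over
lowercased word tokens; texts shorter than the window fall back to the
plain type-token ratio. MATTR was chosen because the raw ratio is
length-biased; the fallback keeps tiny documents well-defined, where the
score is 1.0 exactly when all words are distinct. Both lie in [0, 1].

**Text structure** reports paragraph count (maximal runs of non-blank
lines), mean words and sentences per paragraph, and flags paragraphs over
100 words (configurable).

## Orchestration

A frozen `EditorConfig` (TOML-loadable, schema-versioned) selects enabled
assessments, thresholds, the grade target and resource paths. The default
enabled set is readability + complex language + passive voice; the rest are
opt-in, to limit feedback overload for new users. `assess()` is explicit —
no incremental re-parse — and is a pure function of (text, config, resource
files): reports are field-identical across repeated calls apart from the
timestamp. Disabled assessments are absent from the report, not
zero-filled.

The grade target defaults to 8.0 (ages 13–14, the ceiling recommended for
general-public health materials) and is met when raw grade ≤ target;
the boundary is inclusive and the target configurable, since guidance
documents differ on strictness.

**Pinning and comparison.** A single-slot pinboard stores an immutable
baseline report; pinning again replaces it. `compare()` differences raw
values (grade, passive count, complex-language count, density, diversity)
as current − baseline, only for metrics present in both reports. All five
metrics are treated as lower-is-better for the improved/unchanged/worsened
flags: the grade target, fewer passive and jargon constructions, lighter
density, and more repetition (lower diversity — repeating one term for one
concept aids comprehension) all ease reading. Grade is the only metric
with a pass/fail status.

**Reports and summaries.** The structured format is schema-versioned JSON
with a lossless round trip. The printable summary (plain text or Markdown)
shows global scores only — no highlight spans — matching its
record-keeping purpose; it is the only rendering that shows the revised
grade, and it names the exclusion list and resource versions (short content
hashes of the lexicon/ruleset files) so a saved summary is auditable.

## Synthetic-text generator

`generate_fixture(FixtureSpec)` produces health-flavoured prose with exact
ground truth: sentence count, words per sentence, planted polysyllables
(per sentence, or a total spread round-robin), planted passive
constructions ("was" + participle), and planted jargon terms. The word
banks are curated so the planted counts stay independent: filler words
have ≤ 2 syllables, are no be/get forms or participles, and are absent
from the shipped lexicon; the polysyllable bank is ≥ 3 syllables and
absent from the lexicon; the jargon bank consists of shipped-lexicon terms
of ≤ 2 syllables (custom jargon with a 3+-syllable word is rejected, since
it would change the polysyllable count). Bank hygiene is itself under
test, so future edits cannot silently break the independence.

What the generator does *not* emulate: real clause structure and
punctuation variety (every sentence is a simple period-terminated word
sequence), ambiguous sentence boundaries, morphology that stresses the
lemma matcher, adjectival participles, and genuinely hard syllabifications
outside the banks. Passing the planted-recovery and closed-form-grade
properties therefore shows the counting and scoring machinery is exact on
controlled input; accuracy on real prose is bounded separately by the
rule heuristics documented above, not by these tests.

Problem sizes used in the test suite and acceptance script — up to ~40
sentences per fixture, 50–100 generated fixtures per property — were
chosen as comfortably sufficient to exercise every code path of a
deterministic rule system, where more repetitions add no information.

## Known limitations

* Passive detection and tagging are heuristics; no dependency parse,
  so agent-less nominalizations and adjectival participles are
  mis-handled in predictable ways.
* The syllable fallback is English-orientated; loanwords not in the
  table may be off by one.
* Grammar and spelling are out of scope, as is any automatic rewriting.
* The lexicon and rulesets are starter resources meant to be extended;
  matching is lexical, so sense ambiguity ("oral tradition") is flagged
  regardless of context.
* Line breaks always close sentences, so hard-wrapped paragraphs inflate
  the sentence count (and deflate the grade); feed soft-wrapped text.
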