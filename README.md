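# healthlit

Plain-language assessment of written health information.

Health information is routinely written 2–4 school grades above the level
recommended for the general public, and health staff who draft patient
materials rarely get concrete, real-time feedback about *why* a text is hard
and *what to change*. `healthlit` is a library and command-line tool that
scores a document against health-literacy guidance and flags the exact
character spans that triggered each score, with actionable advice: a grade
reading score with a grade-8 target, medical/public-health jargon with
plain-language alternatives, passive voice, person-centred language, lexical
density and diversity, and text structure. It supports excluding up to five
unavoidable topic words (for example "diabetes" in a diabetes leaflet),
pinning a baseline assessment to show incremental improvement while editing,
and rendering a printable summary for record-keeping.

## The score at the core

Readability is the all-sentence SMOG generalization

```
grade = 1.043 · √(P · 30 / S) + 3.1291
```

where `P` is the number of polysyllabic word tokens (≥ 3 syllables; acronyms
such as "CVD" are excluded because letter strings have no stable syllable
reading) and `S` is the number of sentences. Scores are displayed to one
decimal place (half-up) so small edits visibly move the score; comparisons
always use the raw value. The headline grade counts *every* word; excluded
words reduce `P` only in a supplementary "revised" grade that appears solely
in the printable summary, because excluding words from a grade score is not
standard practice.

Syllables come from a shipped pronunciation table with a deterministic
vowel-group fallback; sentence segmentation, the coarse part-of-speech
cascade behind passive-voice and lexical-density scoring, and the jargon
lexicon (~170 terms with plain-language alternatives) are all rule-based,
deterministic, and editable as plain-text resource files.

## Worked example

```python
from healthlit import EditorConfig, assess, compare

original = ("Preventing cardiovascular disease (CVD) means making smart "
            "choices now that will pay off the rest of your life.")
revised = ("To stop heart disease from happening we need to make smart "
           "choices. That will pay off the rest of your life.")

before = assess(original, EditorConfig())
after = assess(revised, EditorConfig())
print(before.readability.grade)                 # 11.2
print([h.text(before.text)
       for h in before.readability.long_word_highlights])
#  ['Preventing', 'cardiovascular']
print(len(before.readability.long_sentence_highlights))  # 1  (18 words)
print(after.readability.grade)                  # 7.2
print(compare(before, after).deltas["grade"])   # -4.039513...
```

The original sentence scores grade 11.2: one 18-word sentence and two long
words ("Preventing", "cardiovascular") drive it. Splitting the sentence in
two and swapping the long words drops the raw grade by 4.0 to 7.2, under the
grade-8 target — the comparison delta is negative, i.e. improved.

From the shell:

```
healthlit assess leaflet.txt                       # printable summary to stdout
healthlit assess leaflet.txt --format json         # machine-readable report
healthlit assess leaflet.txt --exclude diabetes --summary summary.md
healthlit assess edited.txt --pin baseline.json    # before/after comparison
healthlit fixture --sentences 30 --polysyllables-per-sentence 1 --seed 7
```

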