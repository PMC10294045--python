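Assessment summary
==================

Document fingerprint: d441832238be

Readability (grade reading score)
---------------------------------
Score: 8.8 (target: grade 8.0, not met)
Grade 8.8 is above the grade 8.0 reading target.

Excluded words
--------------
Excluded from complex language counts: diabetes
Revised grade reading score without these words: 7.2 (headline score: 8.8)
Note: excluding words from grade reading scores is not standard practice; the headline score above counts every word.
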