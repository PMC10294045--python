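# Person-centred language ruleset: pattern<TAB>preferred<TAB>rationale
# Patterns match case-insensitively at word boundaries.
diabetic	person with diabetes	Put the person before the condition.
diabetics	people with diabetes	Put the person before the condition.
asthmatic	person with asthma	Put the person before the condition.
asthmatics	people with asthma	Put the person before the condition.
epileptic	person with epilepsy	Put the person before the condition.
schizophrenic	person living with schizophrenia	Put the person before the condition.
the disabled	people with disability	Put the person before the condition.
disabled person	person with disability	Put the person before the condition.
handicapped	person with disability	Avoid outdated labels for disability.
the elderly	older adults	Avoid labelling a group by age.
the aged	older adults	Avoid labelling a group by age.
suffers from	has	Avoid language that casts illness as suffering.
suffering from	living with	Avoid language that casts illness as suffering.
afflicted with	has	Avoid language that casts illness as suffering.
victim of	person who has experienced	Avoid framing people as victims.
drug addict	person with a substance use disorder	Put the person before the condition.
addict	person with a substance use disorder	Put the person before the condition.
alcoholic	person with an alcohol use disorder	Put the person before the condition.
committed suicide	died by suicide	Avoid framing suicide as a crime.
wheelchair-bound	person who uses a wheelchair	Describe equipment use, not confinement.
confined to a wheelchair	uses a wheelchair	Describe equipment use, not confinement.
the obese	people with obesity	Put the person before the condition.
obese patient	patient with obesity	Put the person before the condition.
mentally ill	person living with a mental illness	Put the person before the condition.
the blind	people who are blind	Put the person before the condition.
the deaf	people who are deaf	Put the person before the condition.
noncompliant patient	patient who has difficulty following the plan	Avoid blaming labels.
failed treatment	treatment that did not work	Attribute outcomes to treatment, not the person.
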