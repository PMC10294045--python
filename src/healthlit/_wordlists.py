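"""Closed-class word lists backing the rule-based coarse tagger.

These are deliberately small, closed sets: the tagger needs to separate
function words from content words and to recognise auxiliaries and past
participles, not to reproduce a full part-of-speech tagger. Open-class
words default to noun, with suffix rules for verbs, adverbs and
adjectives layered on top (see text.annotate_tokens).
"""

from __future__ import annotations

BE_FORMS = frozenset(
    "be am is are was were been being isn't aren't wasn't weren't".split()
)

GET_FORMS = frozenset("get gets got gotten getting".split())

# Modals and have/do auxiliaries are tagged aux so they never count as
# content words; only BE/GET forms trigger passive-voice detection.
OTHER_AUX = frozenset(
    """have has had having do does did done doing
    can could may might must shall should will would ought
    cannot can't couldn't won't wouldn't shouldn't mustn't don't doesn't
    didn't haven't hasn't hadn't""".split()
)

# Determiners, prepositions, conjunctions, pronouns, particles: never
# content words for lexical density.
FUNCTION_WORDS = frozenset(
    """the a an this that these those which what whose who whom
    i you he she it we they me him her us them my your his its our their
    mine yours hers ours theirs myself yourself himself herself itself
    ourselves themselves
    someone anyone everyone noone nobody somebody anybody everybody
    something anything everything nothing
    and or but nor so yet if because although though while whereas unless
    until since when whenever where wherever whether than as
    of in on at by for with from to into onto upon about above below under
    over between among through during before after against without within
    along across behind beyond near off out up down around past per
    not no nor any some each every either neither both all few many much
    more most other another such own same just only also too very quite
    rather there here then now again once twice
    please yes""".split()
)

# Irregular past participles (base -ed rule covers the regular ones).
IRREGULAR_PARTICIPLES = frozenset(
    """taken given seen done made told shown known written found kept held
    left paid sent built put read said gone been come become begun brought
    bought caught chosen drawn driven drunk eaten fallen felt fought
    forgotten frozen grown heard hidden hurt lost meant met ridden risen
    run set shaken shut slept spoken spent stood stolen swollen thought
    thrown understood woken worn won broken cut hit let lent led lit
    spread sung sunk torn sworn sold sat sought laid dealt bred fed beaten
    bent bound burnt dreamt knelt learnt smelt spelt spilt spoilt wound
    stuck struck strung swept swum taught wept withdrawn born""".split()
)

# Irregular simple-past forms that the -ed rule misses; tagged verb.
IRREGULAR_PASTS = frozenset(
    """took gave saw did went ran ate drank spoke wrote broke chose drove
    fell flew grew knew rose threw wore woke drew rode sang sank swam
    became began came brought bought caught fought thought taught sought
    told said made found kept held left paid sent built read met felt
    heard lost meant stood slept spent won sold sat lent led lit laid
    dealt fed beat bent bound swept wound stuck struck hurt cut hit let
    put shut spread forgot hid""".split()
)

# Common verbs (base/3sg/plural forms) that would otherwise default to noun.
COMMON_VERBS = frozenset(
    """take takes make makes eat eats go goes run runs help helps need
    needs want wants use uses try tries keep keeps stay stays talk talks
    walk walks drink drinks sleep sleeps check checks visit visits call
    calls ask asks tell tells give gives see sees know knows think thinks
    feel feels find finds look looks come comes work works live lives
    bring brings buy buys pay pays speak speaks write writes start starts
    stop stops move moves turn turns play plays show shows mean means
    happen happens stand stands hear hears lose loses add adds allow
    allows avoid avoids reduce reduces prevent prevents improve improves
    manage manages treat treats cause causes affect affects include
    includes provide provides require requires develop develops occur
    occurs remain remains involve involves consider considers ensure
    ensures contact contacts follow follows remember remembers choose
    chooses wash washes wear wears carry carries drive drives fly flies
    grow grows rise rises throw throws benefit benefits happen happens
    breathe breathes swallow swallows exercise exercises rest rests""".split()
)

# Common adjectives with no reliable suffix signal.
COMMON_ADJECTIVES = frozenset(
    """good bad smart healthy unhealthy long short big small new old high
    low easy hard safe unsafe sick ill well fine hot cold warm cool fresh
    clean dirty strong weak clear simple complex important severe mild
    chronic acute common rare major minor early late full empty free busy
    quick slow deep wide narrow heavy light dry wet sore tired hungry
    thirsty dizzy normal regular daily weekly main whole half extra
    local general medical dental mental physical enough young adult red
    yellow green blue purple pink white black great nice happy sad angry
    calm gentle firm soft loud quiet true false right wrong ready able
    unable likely unlikely""".split()
)

# -ing words that are ordinary nouns, not verb forms.
ING_NOUNS = frozenset("morning evening ceiling thing king spring string".split())

ADVERB_EXCEPTIONS = frozenset("family supply reply july italy belly jelly".split())

# Adjective-forming suffixes used when no list matches.
ADJECTIVE_SUFFIXES = ("ous", "ful", "less", "able", "ible", "ive")
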