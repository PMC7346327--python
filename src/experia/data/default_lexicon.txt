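# Default sentiment lexicon for patient-review opinion mining.
# 30 seed adjectives with known polarity, plus a synonym/antonym
# neighbourhood used to propagate polarity to unseen opinion words.
# Format: [seeds] "word polarity"; [synonyms]/[antonyms] "word: w1, w2".

[seeds]
good        positive
excellent   positive
great       positive
helpful     positive
gentle      positive
effective   positive
comfortable positive
pleasant    positive
safe        positive
quick       positive
reassuring  positive
caring      positive
successful  positive
tolerable   positive
mild        positive
bad         negative
terrible    negative
painful     negative
severe      negative
awful       negative
harmful     negative
uncomfortable negative
unpleasant  negative
risky       negative
slow        negative
frightening negative
careless    negative
unsuccessful negative
intolerable negative
harsh       negative

[synonyms]
excruciating: painful, agonizing
agonizing: painful
unbearable: intolerable, excruciating
radical: severe, drastic
drastic: severe
sore: painful
dreadful: terrible, awful
horrible: terrible, awful
fine: good
superb: excellent, great
kind: caring, gentle
soothing: reassuring, gentle
scary: frightening
dangerous: risky, harmful
beneficial: helpful, effective
bearable: tolerable
invasive: harsh

[antonyms]
good: bad
comfortable: uncomfortable
pleasant: unpleasant
tolerable: intolerable
safe: risky
mild: severe
gentle: harsh
helpful: harmful
painless: painful
quick: slow
ineffective: effective
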