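"""Keyword prefilter: select candidate notes before classification.

"scooter" matches inside words (e-scooter, scooters); brand eponyms (Bird,
Lime, ...) and their misspellings (Byrd, Lyme) match whole words only, so
"birdwatching" never matches. Ages outside 10-90 are excluded first.
"""
import scootersurv as ss

corpus = ss.generate_corpus(ss.GeneratorConfig(n_notes=2000, seed=7))

eligible, tally = ss.filter_corpus(corpus, ss.SCOOTER_ONLY, age_min=10, age_max=90)
print("exclusion tally:", tally)
print(f"eligible notes: {len(eligible)} of {len(corpus)}")

injury_frac = sum(n.is_injury for n in eligible) / len(eligible)
print(f"true-injury fraction among keyword notes: {injury_frac:.2f}")
print("(the classifier's job is to concentrate review effort on these)")

for text in ("fell off an e-scooter", "allergic to lime fruit", "birdwatching trip"):
    print(f"  {text!r:35} ->", ss.match_keywords(text, ss.SCOOTER_AND_BRANDS) or "no match")
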