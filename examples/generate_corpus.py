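"""Generate a labeled synthetic clinical-note corpus and inspect it.

The generator emulates the note population an injury-surveillance pipeline
faces: a few true e-scooter injuries, keyword-colliding confusers (push
scooters, knee scooters, lime-fruit allergies, Lyme disease, Dr. Byrd), and
a large keyword-free background.
"""
import collections

import scootersurv as ss

config = ss.GeneratorConfig(n_notes=2000, seed=7)
corpus = ss.generate_corpus(config)

print("class counts:", dict(collections.Counter(n.truth for n in corpus)))
print("\nan injury note:")
print(" ", next(n.text for n in corpus if n.is_injury))
print("\na confuser note:")
print(" ", next(n.text for n in corpus if n.truth == "confuser"))

# Notes persist as JSON Lines; the truth labels live in a sub-object that
# real-data files simply omit.
ss.write_notes("/tmp/demo_notes.jsonl", corpus)
print(f"\nwrote {len(corpus)} notes to /tmp/demo_notes.jsonl")
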