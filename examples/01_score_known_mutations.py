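"""Score known AGAL mutations with the packaged per-mutation score table.

Loads the sparse score table covering the 27 fully specified panel
mutations, scores a handful of them, and classifies each under the
three-zone guideline. A score above -2 predicts responsiveness to the
chaperone DGJ; -2 is the twilight zone; below -2 predicts no response.
"""

import agalchap as ac

scores = ac.load_score_table()

for text in ["p.A230T", "p.L310F", "p.M72V", "p.G183A", "p.C142W"]:
    mut = ac.parse_mutation(text)
    pred = ac.predict(scores, mut, rule=ac.Rule.THREE_ZONE, check_wildtype=True)
    print(f"{text:>9}  score {pred.score:>3}  ->  {pred.call.value}")

print()
print("A mutation scoring 0 (e.g. p.A230T) is predicted responsive even when")
print("it touches the active site; the experimental panel shows exactly such")
print("a false positive, which is why predictions carry a warning flag there")
print("rather than an override.")
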