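"""Build a PSSM from a multiple alignment and score new mutations.

Samples a small synthetic alignment (13 sequences, mixed conservation)
standing in for a set of AGAL homologs, builds an integer half-bit
log-odds profile with Henikoff weighting and BLOSUM62-derived
pseudocounts, writes it to disk, reads it back, and contrasts a
substitution that homologous sequences actually carry with one never
observed at a conserved position.
"""

import tempfile
from collections import Counter
from pathlib import Path

import numpy as np

import agalchap as ac

# conservation rises along the sequence: position 1 is variable, 40 is frozen
profile = ac.GeneratingProfile.from_conservation(np.linspace(0.2, 1.0, 40), seed=42)
aln = ac.sample_alignment(profile, n_sequences=13, gap_rate=0.05, seed=42)
pssm = ac.build_pssm(aln)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "agal_like.pssm"
    ac.write_pssm(pssm, path)
    pssm = ac.read_pssm(path)  # round trip preserves every integer

# at a variable position, pick the substitution the homologs use most often
position = 2
wt = pssm.query_residue(position)
column = Counter(
    seq[position - 1] for _, seq in aln.sequences[1:] if seq[position - 1] != wt
)
seen_res = column.most_common(1)[0][0]
mut = ac.parse_mutation(f"p.{wt}{position}{seen_res}")
score = ac.score_mutation(pssm, mut, check_wildtype=True)
print(f"p.{wt}{position}{seen_res} (seen in homologs):      "
      f"score {score:>3} -> {ac.classify(score).value}")

# at the most conserved position, pick a residue no homolog carries
position = 39
wt = pssm.query_residue(position)
unseen = "W" if wt != "W" else "F"
mut = ac.parse_mutation(f"p.{wt}{position}{unseen}")
score = ac.score_mutation(pssm, mut, check_wildtype=True)
print(f"p.{wt}{position}{unseen} (absent at conserved pos): "
      f"score {score:>3} -> {ac.classify(score).value}")

print()
print("A replacement residue present in homologous species earns a high")
print("(less negative) score and a responsive call; an unobserved residue at")
print("a conserved position scores deeply negative.")
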