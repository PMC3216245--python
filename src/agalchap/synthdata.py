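"""Synthetic alignments and mutation panels with known ground truth.

Columns are sampled independently from a per-position residue distribution
(a :class:`GeneratingProfile`), which is what the profile-construction
machinery assumes; no phylogenetic correlation is simulated. Panels pair
uniformly drawn missense mutations with responsiveness labels drawn from a
logistic model on the PSSM score, emulating the empirical score-response
relationship the predictor exploits.

All sampling is driven by a single integer seed (0 is valid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import RESIDUES, Alignment, MissenseMutation, MutationRecord

_N = len(RESIDUES)


@dataclass
class GeneratingProfile:
    """Ground-truth per-position residue distributions.

    ``distributions`` is (length, 20), rows summing to 1. ``conservation``
    records, per position, how concentrated the row is (1 = point mass);
    it is descriptive metadata set by the constructors.
    """

    distributions: np.ndarray
    conservation: np.ndarray

    def __post_init__(self) -> None:
        self.distributions = np.asarray(self.distributions, dtype=float)
        self.conservation = np.asarray(self.conservation, dtype=float)
        if self.distributions.ndim != 2 or self.distributions.shape[1] != _N:
            raise ValueError("distributions must be (length, 20)")
        if not np.allclose(self.distributions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's distribution must sum to 1")
        if np.any((self.conservation < 0) | (self.conservation > 1)):
            raise ValueError("conservation must lie in [0, 1]")

    def __len__(self) -> int:
        return self.distributions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RESIDUES[i] for i in self.distributions.argmax(axis=1))

    @classmethod
    def from_conservation(
        cls, conservation, seed: int = 0
    ) -> "GeneratingProfile":
        """Profile with one dominant residue per position: the consensus
        residue (chosen uniformly at random) gets mass c + (1-c)/20, every
        other residue (1-c)/20, where c is that position's conservation."""
        cons = np.asarray(conservation, dtype=float)
        rng = np.random.default_rng(seed)
        length = cons.shape[0]
        dist = np.full((length, _N), 0.0)
        for i in range(length):
            base = (1.0 - cons[i]) / _N
            dist[i, :] = base
            dist[i, rng.integers(_N)] += cons[i]
        return cls(distributions=dist, conservation=cons)


def sample_alignment(
    profile: GeneratingProfile,
    n_sequences: int,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Draw ``n_sequences`` i.i.d. from the profile, then inject gaps at
    ``gap_rate`` everywhere except the query (sequence 1), keeping the
    query's coordinate system intact. Deterministic under ``seed``."""
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    if not 0.0 <= gap_rate < 0.5:
        raise ValueError("gap_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    length = len(profile)
    residues = np.array(list(RESIDUES))
    rows = []
    for s in range(n_sequences):
        draws = [
            residues[rng.choice(_N, p=profile.distributions[i])]
            for i in range(length)
        ]
        if s > 0 and gap_rate > 0:
            mask = rng.random(length) < gap_rate
            draws = ["-" if m else c for c, m in zip(draws, mask)]
        rows.append((f"seq{s + 1}" if s else "query", "".join(draws)))
    return Alignment(sequences=rows, query_index=0)


def sample_mutation_panel(
    pssm,
    n: int,
    slope: float = 1.0,
    intercept: float = 2.0,
    seed: int = 0,
) -> list[MutationRecord]:
    """Draw ``n`` labeled mutations from a PSSM.

    Positions are uniform over the query, mutant residues uniform over the
    19 non-wild-type residues; the responsive label is Bernoulli with
    success probability sigmoid(slope·score + intercept). Deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError("need at least one mutation")
    rng = np.random.default_rng(seed)
    length = len(pssm.query)
    records = []
    for _ in range(n):
        pos = int(rng.integers(length)) + 1
        wt = pssm.query_residue(pos)
        choices = [r for r in RESIDUES if r != wt]
        mut_res = choices[int(rng.integers(len(choices)))]
        score = pssm.score(pos, mut_res)
        p = 1.0 / (1.0 + np.exp(-(slope * score + intercept)))
        records.append(
            MutationRecord(
                mutation=MissenseMutation(wt, pos, mut_res),
                pssm_score=int(score),
                responsive=bool(rng.random() < p),
                source="synthetic",
            )
        )
    return records
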