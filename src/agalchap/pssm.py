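"""Position-specific substitution matrix (PSSM) construction.

Builds an integer log-odds profile from a protein multiple alignment using
the standard PSI-BLAST-style recipe:

1. position-based (Henikoff) sequence weighting to discount redundant
   homologs;
2. weighted observed residue frequencies per query position (gaps and 'X'
   excluded from the denominator);
3. pseudocount smoothing that mixes the observed frequencies with a
   BLOSUM62-derived substitution prior, weighted by the effective number of
   independent observations;
4. scaled log-odds against a background distribution, rounded half away
   from zero to integers (half-bit units by default).

The query sequence's ungapped coordinates define the matrix rows; columns
where the query is gapped do not exist in the output coordinate system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, EmptyInputError
from .seqio import RESIDUES, Alignment

logger = logging.getLogger(__name__)

_N = len(RESIDUES)
_INDEX = {r: i for i, r in enumerate(RESIDUES)}

# BLOSUM62 marginal residue frequencies (order = RESIDUES); the standard
# background for half-bit substitution scores.
_BLOSUM62_BACKGROUND = np.array(
    [
        0.074, 0.052, 0.045, 0.054, 0.025, 0.034, 0.054, 0.074, 0.026, 0.068,
        0.099, 0.058, 0.025, 0.047, 0.039, 0.057, 0.051, 0.013, 0.032, 0.073,
    ]
)
_BLOSUM62_BACKGROUND /= _BLOSUM62_BACKGROUND.sum()


def _blosum62_conditional(background: np.ndarray) -> np.ndarray:
    """Conditional substitution probabilities P(b | a) implied by the
    half-bit BLOSUM62 scores and a background: P(b|a) ∝ p_b · 2^(s_ab / 2)."""
    mat = substitution_matrices.load("BLOSUM62")
    s = np.array([[mat[a, b] for b in RESIDUES] for a in RESIDUES], dtype=float)
    cond = background[None, :] * np.power(2.0, s / 2.0)
    return cond / cond.sum(axis=1, keepdims=True)


@dataclass
class PssmParams:
    """Profile-construction parameters.

    ``pseudocount_weight`` is the PSI-BLAST-style constant beta: the prior
    receives weight beta against ``n_eff - 1`` for the observations.
    ``scale`` multiplies log2 odds before rounding (2.0 = half-bit integers,
    the unit in which conserved-position scores land in the familiar
    -7..+1 range). ``score_floor`` caps the log-odds of residues with
    (near-)zero smoothed probability so integer scores stay finite.
    """

    background: np.ndarray = field(
        default_factory=lambda: _BLOSUM62_BACKGROUND.copy()
    )
    pseudocount_weight: float = 10.0
    substitution_prior: Optional[np.ndarray] = None
    scale: float = 2.0
    weighting: str = "henikoff"
    score_floor: int = -16

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (_N,):
            raise ConfigurationError("background must be a 20-vector")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ConfigurationError("background must sum to 1")
        if np.any(self.background <= 0):
            raise ConfigurationError("background frequencies must be positive")
        if self.pseudocount_weight < 0:
            raise ConfigurationError("pseudocount_weight must be >= 0")
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")
        if self.weighting not in ("henikoff", "uniform"):
            raise ConfigurationError(f"unknown weighting scheme {self.weighting!r}")
        if self.substitution_prior is None:
            self.substitution_prior = _blosum62_conditional(self.background)
        else:
            self.substitution_prior = np.asarray(self.substitution_prior, float)
            if self.substitution_prior.shape != (_N, _N):
                raise ConfigurationError("substitution_prior must be 20x20")
            if not np.allclose(self.substitution_prior.sum(axis=1), 1.0, atol=1e-6):
                raise ConfigurationError("substitution_prior rows must sum to 1")


@dataclass
class PSSM:
    """Integer log-odds profile over the query's ungapped positions.

    ``scores[i][r]`` is the integer score of residue ``r`` at 1-based
    protein position ``i + 1``; ``probabilities`` holds the unrounded
    smoothed frequencies when the matrix was built in-process (file
    round-trips carry scores only). Equality compares query and scores.
    """

    query: str
    scores: list[dict[str, int]]
    probabilities: Optional[list[dict[str, float]]] = None
    params: Optional[PssmParams] = None

    def __len__(self) -> int:
        return len(self.query)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PSSM):
            return NotImplemented
        return self.query == other.query and self.scores == other.scores

    def score(self, position: int, residue: str) -> int:
        """Score of ``residue`` at 1-based protein ``position``."""
        if not 1 <= position <= len(self.query):
            raise IndexError(position)
        return self.scores[position - 1][residue]

    def query_residue(self, position: int) -> str:
        if not 1 <= position <= len(self.query):
            raise IndexError(position)
        return self.query[position - 1]


# ---------------------------------------------------------------------------


def sequence_weights(aln: Alignment, scheme: str = "henikoff") -> np.ndarray:
    """Per-sequence weights summing to the effective number of sequences.

    Henikoff position-based weighting: each column distributes one unit of
    mass equally among the residue types present, and each type's share
    equally among the sequences carrying it. Raw weights are rescaled to sum
    to the effective sequence count (mean number of distinct residue types
    per column). The uniform scheme returns all-ones.
    """
    n = len(aln)
    if scheme == "uniform":
        return np.ones(n)
    if scheme != "henikoff":
        raise ConfigurationError(f"unknown weighting scheme {scheme!r}")
    raw = np.zeros(n)
    n_types_per_column = []
    for col in range(aln.n_columns):
        residues = [seq[col] for _, seq in aln.sequences]
        carriers: dict[str, list[int]] = {}
        for i, r in enumerate(residues):
            if r in _INDEX:  # skip gaps and 'X'
                carriers.setdefault(r, []).append(i)
        if not carriers:
            continue
        r_types = len(carriers)
        n_types_per_column.append(r_types)
        for members in carriers.values():
            share = 1.0 / (r_types * len(members))
            for i in members:
                raw[i] += share
    if not n_types_per_column or raw.sum() == 0:
        return np.ones(n)  # no informative columns: fall back to uniform
    n_eff = float(np.mean(n_types_per_column))
    return raw / raw.sum() * n_eff


def column_frequencies(
    aln: Alignment, weights: np.ndarray
) -> list[Optional[np.ndarray]]:
    """Weighted observed residue frequencies for each query position.

    Gap and 'X' characters contribute nothing. A position whose column
    carries no residue mass (possible only when the query character itself
    is unknown) yields ``None`` and a logged warning.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(aln),):
        raise ValueError("weights length must match number of sequences")
    out: list[Optional[np.ndarray]] = []
    for pos, col in enumerate(aln.query_columns(), start=1):
        freq = np.zeros(_N)
        for (_, seq), w in zip(aln.sequences, weights):
            idx = _INDEX.get(seq[col])
            if idx is not None:
                freq[idx] += w
        total = freq.sum()
        if total == 0:
            logger.warning("query position %d has an all-gap column; dropped", pos)
            out.append(None)
        else:
            out.append(freq / total)
    return out


def apply_pseudocounts(
    freqs: np.ndarray, params: PssmParams, n_eff: float
) -> np.ndarray:
    """Mix observed frequencies with the substitution prior.

    smoothed = (alpha·f + beta·g) / (alpha + beta) with alpha = n_eff − 1,
    beta = ``params.pseudocount_weight`` and g the prior push
    g_b = Σ_a f_a · P(b|a). With beta = 0 the observations pass through;
    with a single effective sequence the prior dominates entirely.
    """
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    f = np.asarray(freqs, dtype=float)
    alpha = n_eff - 1.0
    beta = params.pseudocount_weight
    if alpha + beta == 0:
        return f.copy()
    g = f @ params.substitution_prior  # g[b] = sum_a f[a] P(b|a)
    smoothed = (alpha * f + beta * g) / (alpha + beta)
    return smoothed / smoothed.sum()


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def build_pssm(aln: Alignment, params: Optional[PssmParams] = None) -> PSSM:
    """Build an integer log-odds PSSM from an alignment.

    score(pos, r) = round(scale · log2(p_smoothed(pos, r) / background_r)),
    floored at ``params.score_floor``. Positions whose column carries no
    residue mass fall back to the background (all scores 0).
    """
    if params is None:
        params = PssmParams()
    if len(aln) < 1:
        raise EmptyInputError("alignment has no sequences")
    weights = sequence_weights(aln, params.weighting)
    n_eff = float(weights.sum())
    freqs = column_frequencies(aln, weights)
    bg = params.background
    scores: list[dict[str, int]] = []
    probs: list[dict[str, float]] = []
    for f in freqs:
        if f is None:
            p = bg.copy()
        else:
            p = apply_pseudocounts(f, params, n_eff)
        row_scores: dict[str, int] = {}
        row_probs: dict[str, float] = {}
        for i, r in enumerate(RESIDUES):
            row_probs[r] = float(p[i])
            if p[i] <= 0.0:
                row_scores[r] = params.score_floor
            else:
                s = _round_half_away(params.scale * math.log2(p[i] / bg[i]))
                row_scores[r] = max(s, params.score_floor)
        scores.append(row_scores)
        probs.append(row_probs)
    return PSSM(query=aln.query, scores=scores, probabilities=probs, params=params)
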