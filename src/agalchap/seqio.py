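"""Sequence, mutation and table I/O.

This module owns the package's domain containers (:class:`Alignment`,
:class:`MissenseMutation`, :class:`MutationRecord`), the HGVS-style protein
mutation parser, readers/writers for alignments and ASCII scoring matrices,
and loaders for the packaged mutation-panel tables:

``table1``
    Nine Fabry mutations expressed in COS-7 cells and assayed with and
    without 1-deoxy-galactonojirimycin (DGJ), with fold increase, PSSM score
    and structural annotations.
``table2``
    Nineteen Fabry mutations gathered from the literature with PSSM scores,
    structural annotations and the reported DGJ responsiveness.
``table3``
    Mutagenic oligonucleotide pairs used to construct the table1 mutants.

Protein positions are 1-based everywhere in the public API, matching HGVS
notation ("p.A230T"). Alignment columns are 0-based and internal.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import AlignIO, SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

from .errors import (
    EmptyInputError,
    FixtureIntegrityError,
    FormatError,
    ParseError,
    ValidationError,
)

#: The 20 standard residues in NCBI PSSM column order.
RESIDUES = "ARNDCQEGHILKMFPSTWYV"
RESIDUE_SET = frozenset(RESIDUES)

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

# sha256 of the packaged tables; guards against silent fixture corruption.
_FIXTURE_SHA256 = {
    "table1": "4dfc0415f9f96de3af5abd973ddd75a6990f5b2790185d02e5978822ba1f1960",
    "table2": "5a06884bb05983f9792164c12f1741c482aaa282e83c5b0d9efbdaffd9732ef6",
    "table3": "b0e587f965aa3617f38f637bb4229010d92af27ffe54eebd81caa009c2ce1e7e",
    "agal_scores": "2c5a7ed2b1d40226effc783ee5b13171fe42b94f8b91ae694a8b2e38779a35bc",
}

_EXPECTED_ROWS = {"table1": 9, "table2": 19, "table3": 11, "agal_scores": 27}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MissenseMutation:
    """A single amino-acid substitution in protein coordinates.

    ``mut_residue`` may be ``None`` for incompletely reported mutations
    (the literature panel prints one such row, codon 166, without a target
    residue); such records are excluded from score lookups but retained in
    counts keyed on their printed score.
    """

    wt_residue: str
    position: int
    mut_residue: Optional[str]
    cdna: Optional[str] = None

    def __post_init__(self) -> None:
        if self.wt_residue not in RESIDUE_SET:
            raise ValidationError(f"unknown wild-type residue {self.wt_residue!r}")
        if self.mut_residue is not None and self.mut_residue not in RESIDUE_SET:
            raise ValidationError(f"unknown mutant residue {self.mut_residue!r}")
        if self.position < 1:
            raise ValidationError(f"protein position must be >= 1, got {self.position}")
        if self.mut_residue is not None and self.mut_residue == self.wt_residue:
            raise ValidationError(
                f"silent substitution {self.wt_residue}{self.position}{self.mut_residue}"
                " is not a missense mutation"
            )

    @property
    def complete(self) -> bool:
        return self.mut_residue is not None


@dataclass
class MutationRecord:
    """A mutation plus the annotations carried by the packaged panels.

    ``pssm_score`` is the integer conservation score of the mutant residue;
    ``mupro`` and ``sdm`` are sequence- and structure-based stability
    predictions (kcal/mol-like, negative = destabilising); ``psa_mc`` /
    ``psa_sc`` are main-chain / side-chain solvent accessibilities in percent;
    ``sec_stru`` is a secondary-structure code with element length, e.g.
    ``"P(5)"`` for a 5-residue polyproline-II helix; ``fold_increase`` is the
    DGJ-treated over untreated activity ratio; ``responsive`` records whether
    post-DGJ activity reached the 15%-of-wild-type threshold.
    """

    mutation: MissenseMutation
    pssm_score: int
    mupro: Optional[float] = None
    sdm: Optional[float] = None
    psa_mc: Optional[float] = None
    psa_sc: Optional[float] = None
    sec_stru: Optional[str] = None
    domain: Optional[str] = None
    active_site: bool = False
    phenotype: Optional[str] = None
    fold_increase: Optional[float] = None
    responsive: Optional[bool] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fold_increase is not None and self.fold_increase <= 0:
            raise ValidationError("fold_increase must be positive")
        if not isinstance(self.pssm_score, int):
            raise ValidationError("pssm_score must be an integer")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse oligonucleotide pair for site-directed mutagenesis."""

    name: str
    forward: str
    reverse: str


@dataclass
class Alignment:
    """A gapped protein multiple sequence alignment.

    ``sequences`` holds ``(identifier, residues)`` pairs over the 20 amino
    acids plus ``'-'`` (gap) and ``'X'`` (unknown). ``query_index`` selects
    the reference sequence whose ungapped coordinates define the PSSM
    coordinate system.
    """

    sequences: list[tuple[str, str]]
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError("alignment has no sequences")
        length = len(self.sequences[0][1])
        if length < 1:
            raise FormatError("alignment length must be >= 1")
        for i, (name, seq) in enumerate(self.sequences):
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: record {i + 1} ({name!r}) has length "
                    f"{len(seq)}, expected {length}"
                )
        if not 0 <= self.query_index < len(self.sequences):
            raise ValidationError(
                f"query_index {self.query_index} outside 0..{len(self.sequences) - 1}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def query(self) -> str:
        """The reference sequence with gaps removed (1-based protein coords)."""
        return self.sequences[self.query_index][1].replace("-", "")

    def query_columns(self) -> list[int]:
        """Alignment columns where the query holds a residue, in order."""
        row = self.sequences[self.query_index][1]
        return [i for i, c in enumerate(row) if c != "-"]


class SparseScoreTable:
    """Per-mutation integer scores, a sparse stand-in for a full matrix.

    Covers only the (position, mutant residue) pairs it was built from;
    exposes the same lookup surface the scorer needs from a full PSSM.
    """

    def __init__(self, entries: Iterable[tuple[int, str, str, int]]) -> None:
        self._scores: dict[tuple[int, str], int] = {}
        self._wildtype: dict[int, str] = {}
        for pos, wt, mut, score in entries:
            self._scores[(pos, mut)] = int(score)
            self._wildtype[pos] = wt

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._scores

    def score(self, position: int, residue: str) -> int:
        try:
            return self._scores[(position, residue)]
        except KeyError:
            raise KeyError(
                f"no score recorded for residue {residue} at position {position}"
            ) from None

    def query_residue(self, position: int) -> Optional[str]:
        return self._wildtype.get(position)


# ---------------------------------------------------------------------------
# mutation notation

_MUT_RE = re.compile(
    r"^\s*(?:p\.)?\s*([A-Za-z]{1,3})\s*(\d+)\s*([A-Za-z]{0,3})\s*$"
)


def _residue_code(token: str, what: str) -> str:
    token = token.strip()
    if len(token) == 1:
        code = token.upper()
        if code not in RESIDUE_SET:
            raise ParseError(f"unknown {what} residue code {token!r}")
        return code
    if len(token) == 3:
        code = _THREE_TO_ONE.get(token.upper())
        if code is None or code not in RESIDUE_SET:
            raise ParseError(f"unknown {what} residue code {token!r}")
        return code
    raise ParseError(f"residue code {token!r} is neither 1- nor 3-letter")


def parse_mutation(
    text: str, cdna: Optional[str] = None, allow_incomplete: bool = False
) -> MissenseMutation:
    """Parse HGVS-style protein notation such as ``"p.A230T"``.

    One- and three-letter residue codes are accepted, the ``p.`` prefix and
    surrounding whitespace are optional. ``allow_incomplete`` admits strings
    lacking the mutant residue (e.g. ``"p.L166"``), producing a record with
    ``mut_residue=None``; by default those raise :class:`ParseError`.
    """
    m = _MUT_RE.match(text)
    if m is None:
        raise ParseError(f"cannot parse mutation notation {text!r}")
    wt_tok, pos_tok, mut_tok = m.groups()
    wt = _residue_code(wt_tok, "wild-type")
    position = int(pos_tok)
    if not mut_tok:
        if allow_incomplete:
            return MissenseMutation(wt, position, None, cdna)
        raise ParseError(f"mutation {text!r} lacks a mutant residue")
    mut = _residue_code(mut_tok, "mutant")
    return MissenseMutation(wt, position, mut, cdna)


def format_mutation(mut: MissenseMutation) -> str:
    """Canonical one-letter form, e.g. ``p.A230T`` (``p.L166`` if incomplete)."""
    target = mut.mut_residue or ""
    return f"p.{mut.wt_residue}{mut.position}{target}"


# ---------------------------------------------------------------------------
# alignment I/O


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_alignment(path, format: str = "fasta", query_index: int = 0) -> Alignment:
    """Read a protein multiple alignment from FASTA or Stockholm.

    ``'.'`` gaps are normalised to ``'-'`` and residues uppercased. Ragged
    FASTA input raises :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise FormatError(f"cannot read Stockholm alignment: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no sequences found in {path}")
    sequences = [(rec.id, _normalise(str(rec.seq))) for rec in records]
    return Alignment(sequences=sequences, query_index=query_index)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA."""
    with open(path, "w") as fh:
        for name, seq in aln.sequences:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# PSSM interchange (NCBI-style ASCII layout)


def write_pssm(pssm, path) -> None:
    """Write a PSSM as ASCII: header of 20 residue letters, then one row per
    query position (1-based index, query residue, 20 integer scores)."""
    with open(path, "w") as fh:
        fh.write("pos\tres\t" + "\t".join(RESIDUES) + "\n")
        for i, res in enumerate(pssm.query):
            row = pssm.scores[i]
            fh.write(
                f"{i + 1}\t{res}\t" + "\t".join(str(row[r]) for r in RESIDUES) + "\n"
            )


def read_pssm(path):
    """Read a PSSM written by :func:`write_pssm`.

    Only query and integer scores are stored on disk, so the returned matrix
    carries no probability layer; round-tripping preserves scores exactly.
    """
    from .pssm import PSSM  # deferred: pssm builds on seqio types

    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise EmptyInputError(f"empty PSSM file {path}")
    header = lines[0].split("\t")
    if len(header) != 22 or "".join(header[2:]) != RESIDUES:
        raise FormatError(
            f"PSSM header must list the 20 residues {RESIDUES}, got {lines[0]!r}"
        )
    query_chars: list[str] = []
    scores: list[dict[str, int]] = []
    for n, line in enumerate(lines[1:], start=1):
        parts = line.split("\t")
        if len(parts) != 22:
            raise FormatError(
                f"PSSM row {n} has {len(parts) - 2} score columns, expected 20"
            )
        query_chars.append(parts[1])
        try:
            scores.append({r: int(v) for r, v in zip(RESIDUES, parts[2:])})
        except ValueError as exc:
            raise FormatError(f"non-integer score in PSSM row {n}: {exc}") from exc
    return PSSM(query="".join(query_chars), scores=scores, probabilities=None)


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_text(filename: str) -> str:
    return (resources.files("agalchap.data") / filename).read_text()


def _verify_fixture(name: str, text: str, n_rows: int) -> None:
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if expected is not None and digest != expected:
        raise FixtureIntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {expected}"
        )
    if n_rows != _EXPECTED_ROWS[name]:
        raise FixtureIntegrityError(
            f"fixture {name} has {n_rows} rows, expected {_EXPECTED_ROWS[name]}"
        )


def _opt_float(cell: str) -> Optional[float]:
    return None if cell in ("", "NA") else float(cell)


def _opt_text(cell: str) -> Optional[str]:
    return None if cell in ("", "NA") else cell


def _rows(text: str) -> list[dict[str, str]]:
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


def _mutation_record(row: dict[str, str], source: str) -> MutationRecord:
    mut = parse_mutation(row["aa"], cdna=row["cdna"], allow_incomplete=True)
    return MutationRecord(
        mutation=mut,
        pssm_score=int(row["pssm"]),
        mupro=_opt_float(row["mupro"]),
        sdm=_opt_float(row["sdm"]),
        psa_mc=_opt_float(row["psa_mc"]),
        psa_sc=_opt_float(row["psa_sc"]),
        sec_stru=_opt_text(row["sec_stru"]),
        domain=_opt_text(row["domain"]),
        active_site=row["active_site"] == "Yes",
        phenotype=_opt_text(row.get("phenotype", "NA")),
        fold_increase=_opt_float(row.get("fold_increase", "NA")),
        responsive=(
            None if row.get("responsive", "NA") in ("", "NA")
            else row["responsive"] == "Yes"
        ),
        source=source,
    )


def load_fixture_table(name: str):
    """Load a packaged panel: ``table1``/``table2`` give
    :class:`MutationRecord` lists (9 and 19 records), ``table3`` gives 10
    :class:`PrimerPair` objects (the flanking ECORI/XHOI pair plus nine
    mutagenic pairs). Integrity (row count and checksum) is verified on
    every load."""
    if name not in ("table1", "table2", "table3"):
        raise ValueError(f"unknown fixture table {name!r}")
    text = _data_text(f"{name}.tsv")
    rows = _rows(text)
    _verify_fixture(name, text, len(rows))
    if name == "table3":
        flank_f = next(r for r in rows if r["name"] == "ECOR1_FORWARD")
        flank_r = next(r for r in rows if r["name"] == "XHO1_REVERSE")
        pairs = [PrimerPair("flanking", flank_f["forward"], flank_r["reverse"])]
        pairs += [
            PrimerPair(r["name"], r["forward"], r["reverse"])
            for r in rows
            if r["name"] not in ("ECOR1_FORWARD", "XHO1_REVERSE")
        ]
        return pairs
    return [_mutation_record(row, source=name) for row in rows]


def load_score_table() -> SparseScoreTable:
    """Load the packaged per-mutation AGAL score table (sparse realisation of
    the scoring matrix over the 27 fully specified panel mutations)."""
    text = _data_text("agal_scores.tsv")
    rows = _rows(text)
    _verify_fixture("agal_scores", text, len(rows))
    return SparseScoreTable(
        (int(r["pos"]), r["wt"], r["mut"], int(r["score"])) for r in rows
    )


def read_score_table(path) -> SparseScoreTable:
    """Read a sparse score table (TSV: pos, wt, mut, score) from a path."""
    with open(path) as fh:
        rows = _rows(fh.read())
    return SparseScoreTable(
        (int(r["pos"]), r["wt"], r["mut"], int(r["score"])) for r in rows
    )
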