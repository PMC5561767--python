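"""Sequence and PSSM input/output.

Reads FASTA protein sequences and PSI-BLAST ASCII PSSM files (the
``-out_ascii_pssm`` dialect), writes the same dialect back, and computes a
single-sequence pseudo-PSSM from Dayhoff's mutation matrix (PAM250) as a
fallback when PSI-BLAST profiles are unavailable.

Conventions
-----------
* Positions are 1-based in PSSM files and 0-based in all in-memory arrays.
* PSSM scores are the first 20 integer columns of the ASCII file (the
  log-odds block); the percentage block is parsed and retained but is not
  the score matrix.
* Column order is whatever the file header declares (PSI-BLAST emits
  ``A R N D C Q E G H I L K M F P S T W Y V``); downstream code must index
  through :attr:`PSSM.column_order`, never by assumption.

Producing real profiles is delegated to PSI-BLAST; the command line used for
the curated datasets is::

    psiblast -query protein.fasta -db <protein_db> -num_iterations 3 \
        -evalue 0.001 -out_ascii_pssm protein.pssm

This module consumes only the ASCII output of that command.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue column order emitted by PSI-BLAST ASCII PSSM files.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard codes mapped to X on FASTA ingest.
_NONSTANDARD = set("BZJUO*")

_SCORE_FMT_DECIMALS = 4  # formatting precision of write_ascii_pssm


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file does not follow the expected layout."""


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20-letter alphabet (plus X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise FastaError(
                f"sequence {self.id!r} contains non-standard residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSM:
    """An L x 20 position-specific scoring matrix for one protein.

    ``scores[i, j]`` is the score of residue ``column_order[j]`` at 0-based
    position ``i``. ``residues`` is the implied query sequence when known
    (PSI-BLAST repeats it in the per-row residue column). ``percentages``
    holds the weighted-observed-percentage block of ASCII files for users who
    prefer it over log-odds; it is never used by the feature pipeline.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str = PSIBLAST_COLUMN_ORDER
    source: str = "psiblast_ascii"  # psiblast_ascii | pseudo_dayhoff | synthetic
    residues: str | None = None
    percentages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM scores must be L x 20, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one position")
        if sorted(self.column_order) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"column_order must be a permutation of the 20 residues, "
                f"got {self.column_order!r}"
            )

    @property
    def length(self) -> int:
        """Number of positions L (0-based rows 0..L-1)."""
        return self.scores.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PSSM):
            return NotImplemented
        return (
            self.protein_id == other.protein_id
            and self.column_order == other.column_order
            and self.scores.shape == other.scores.shape
            and np.allclose(self.scores, other.scores, atol=10 ** -_SCORE_FMT_DECIMALS)
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20 x 20 residue substitution matrix with a declared order."""

    name: str
    residue_order: str
    values: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (20, 20):
            raise ValueError(f"expected 20x20 matrix, got {vals.shape}")
        if not np.allclose(vals, vals.T):
            raise ValueError(f"substitution matrix {self.name!r} is not symmetric")
        if sorted(self.residue_order) != sorted(AMINO_ACIDS):
            raise ValueError("residue_order must cover the 20 standard residues")

    def score(self, a: str, b: str) -> float:
        return float(
            self.values[self.residue_order.index(a), self.residue_order.index(b)]
        )


def dayhoff_matrix() -> SubstitutionMatrix:
    """Dayhoff's mutation matrix (PAM250), restricted to the 20 standard residues.

    Loaded from Biopython's packaged NCBI-format copy.
    """
    pam = substitution_matrices.load("PAM250")
    order = PSIBLAST_COLUMN_ORDER
    vals = np.array([[pam[a, b] for b in order] for a in order], dtype=float)
    return SubstitutionMatrix(name="PAM250", residue_order=order, values=vals)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Ids are the first whitespace-delimited header token; residues are
    upper-cased and non-standard codes (B, Z, J, U, O, *) are mapped to X
    with a warning. Record order is preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    sequences: list[ProteinSequence] = []
    for rec in records:
        raw = str(rec.seq).upper()
        if not raw:
            raise FastaError(f"record {rec.id!r} has an empty sequence")
        if set(raw) & _NONSTANDARD:
            warnings.warn(
                f"record {rec.id!r}: non-standard residues mapped to X",
                stacklevel=2,
            )
            raw = "".join("X" if c in _NONSTANDARD else c for c in raw)
        unknown = set(raw) - set(AMINO_ACIDS) - {"X"}
        if unknown:
            raise FastaError(
                f"record {rec.id!r} contains unrecognized characters: {sorted(unknown)}"
            )
        sequences.append(ProteinSequence(id=rec.id, residues=raw))
    return sequences


def write_fasta(sequences: list[ProteinSequence], path) -> None:
    """Write sequences to FASTA (60-column wrap)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def parse_ascii_pssm(path, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The score matrix is the first 20 integer columns (log-odds block); the
    following 20 columns (weighted observed percentages) are retained in
    :attr:`PSSM.percentages`. Column order is read from the header line.
    Position indices must be contiguous starting at 1.
    """
    with open(path) as fh:
        lines = fh.readlines()

    header_idx = None
    column_order = None
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) in (20, 40) and all(
            len(t) == 1 and t in AMINO_ACIDS for t in tokens
        ):
            header_idx = i
            column_order = "".join(tokens[:20])
            break
    if header_idx is None:
        raise PSSMParseError(f"{path}: no residue-order header line found")

    scores: list[list[float]] = []
    percentages: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            break  # blank line terminates the matrix block
        if not tokens[0].lstrip("-").isdigit():
            break  # trailing K/Lambda statistics
        try:
            pos = int(tokens[0])
        except ValueError as exc:
            raise PSSMParseError(f"{path}:{lineno}: bad position index") from exc
        if pos != expected_pos:
            raise PSSMParseError(
                f"{path}:{lineno}: non-contiguous position index "
                f"(expected {expected_pos}, got {pos})"
            )
        residue = tokens[1]
        numeric = tokens[2:]
        if len(numeric) < 40:
            raise PSSMParseError(
                f"{path}:{lineno}: expected 40 numeric columns, got {len(numeric)}"
            )
        try:
            row = [float(t) for t in numeric[:40]]
        except ValueError as exc:
            raise PSSMParseError(
                f"{path}:{lineno}: non-numeric value in matrix row"
            ) from exc
        scores.append(row[:20])
        percentages.append(row[20:40])
        residues.append(residue)
        expected_pos += 1

    if not scores:
        raise PSSMParseError(f"{path}: no matrix rows found after header")

    if protein_id is None:
        from pathlib import Path

        protein_id = Path(path).stem
    return PSSM(
        protein_id=protein_id,
        scores=np.array(scores, dtype=float),
        column_order=column_order,
        source="psiblast_ascii",
        residues="".join(residues),
        percentages=np.array(percentages, dtype=float),
    )


def write_ascii_pssm(pssm: PSSM, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout.

    The percentage block is emitted from :attr:`PSSM.percentages` when
    present, otherwise as zeros; the two trailing per-row statistics are
    emitted as zeros. Integer scores are written as integers; fractional
    scores with 4 decimal places, which bounds the round-trip error.
    """

    def fmt(v: float) -> str:
        if float(v).is_integer():
            return f"{int(v):4d}"
        return f"{v:.{_SCORE_FMT_DECIMALS}f}"

    residues = pssm.residues or "X" * pssm.length
    pct = (
        pssm.percentages
        if pssm.percentages is not None
        else np.zeros_like(pssm.scores)
    )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weight ratio and "
            "information per position\n"
        )
        letters = "  ".join(pssm.column_order)
        fh.write(f"            {letters}   {letters}\n")
        for i in range(pssm.length):
            score_part = " ".join(fmt(v) for v in pssm.scores[i])
            pct_part = " ".join(fmt(v) for v in pct[i])
            fh.write(
                f"{i + 1:5d} {residues[i]}  {score_part}  {pct_part}  0.00 0.00\n"
            )
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.0000     0.0000\n")


# ---------------------------------------------------------------------------
# Pseudo-PSSM from a single sequence
# ---------------------------------------------------------------------------

def compute_pseudo_pssm(
    seq: ProteinSequence, sub: SubstitutionMatrix | None = None
) -> PSSM:
    """Single-sequence profile: score of residue j at position i is the
    substitution-matrix entry between j and the residue observed at i.

    This is the profile score P_ij = sum_k m(i,k) * n(j,k) with the
    degenerate single-sequence frequency m(i,k) = 1 for the observed residue
    and 0 otherwise, so row i is exactly the matrix row of residue i. It is
    a no-BLAST fallback, far less informative than a real PSI-BLAST profile.
    """
    if sub is None:
        sub = dayhoff_matrix()
    out_order = sub.residue_order
    rows = np.empty((len(seq), 20), dtype=float)
    for i, r in enumerate(seq.residues):
        if r not in AMINO_ACIDS:
            raise ValueError(
                f"sequence {seq.id!r}: residue {r!r} at position {i + 1} "
                "(1-based) is outside the 20-letter alphabet"
            )
        rows[i] = sub.values[out_order.index(r)]
    return PSSM(
        protein_id=seq.id,
        scores=rows,
        column_order=out_order,
        source="pseudo_dayhoff",
        residues=seq.residues,
    )
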