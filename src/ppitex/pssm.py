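"""Protein sequence and PSSM input/output.

A PSSM (position-specific scoring matrix) is stored as a 20xM real matrix:
one row per amino acid in the fixed order ``ARNDCQEGHILKMFPSTWYV`` (the row
convention of PSI-BLAST ASCII output) and one column per sequence position.
Profiles either come from PSI-BLAST ``-out_ascii_pssm`` files or from the
deterministic pseudo-PSSM generator, which lets the downstream pipeline run
without any database search.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

#: Fixed amino-acid row order for every PSSM in this package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Ambiguity/non-standard codes mapped to the placeholder residue 'X'.
_NONCANONICAL = set("BZJUO*")


class PssmFormatError(ValueError):
    """Raised when a PSSM file cannot be parsed."""


def normalize_residues(residues: str) -> str:
    """Uppercase and map non-canonical residue codes to the placeholder 'X'.

    Raises ``ValueError`` for an empty sequence or characters that are not
    amino-acid codes at all.
    """
    if not residues:
        raise ValueError("empty residue string")
    out = []
    for ch in residues.upper():
        if ch in AA_INDEX:
            out.append(ch)
        elif ch == "X" or ch in _NONCANONICAL:
            out.append("X")
        else:
            raise ValueError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the 20-letter alphabet (plus 'X')."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSM:
    """20xM evolutionary profile for one protein.

    ``scores[i, j]`` is the substitution score of amino acid ``AA_ORDER[i]``
    at sequence position ``j``.
    """

    protein_id: str
    scores: np.ndarray
    source: str = "pseudo"  # "psiblast" | "pseudo"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != 20:
            raise ValueError(
                f"PSSM must be 20xM, got shape {self.scores.shape}"
            )
        if self.scores.shape[1] < 1:
            raise ValueError("PSSM must have at least one column")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PSSM contains non-finite entries")

    @property
    def length(self) -> int:
        return self.scores.shape[1]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Record order is preserved; residues are uppercased and non-canonical
    codes mapped to 'X'. A record with an empty sequence is a format error.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinSequence(id=rec.id, residues=seq))
    return records


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def min_length_filter(
    sequences: Sequence[ProteinSequence], min_len: int = 50
) -> list[ProteinSequence]:
    """Drop sequences shorter than ``min_len`` residues, preserving order."""
    return [s for s in sequences if len(s) >= min_len]


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM parsing / writing
# ---------------------------------------------------------------------------

def parse_psiblast_pssm(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a 20xM :class:`PSSM`.

    Only the first 20 numeric columns (the log-odds block) are used; the
    weighted-percentage block and trailing information-content columns are
    ignored. The file stores positions as rows, so the result is the
    transpose of the printed layout.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    columns: list[list[float]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not header_seen:
                # Header line: 20 (or 40) single-letter residue labels.
                if len(tokens) >= 20 and all(t in AA_INDEX for t in tokens[:20]):
                    header_seen = True
                continue
            if not tokens:
                break  # blank line terminates the score block
            if len(tokens) < 22:
                # Footer (K/Lambda lines) or truncation.
                if columns:
                    break
                raise PssmFormatError(
                    f"{path}:{lineno}: unexpected line inside score block"
                )
            try:
                int(tokens[0])
            except ValueError:
                break
            try:
                scores = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise PssmFormatError(
                    f"{path}:{lineno}: non-numeric score cell ({exc})"
                ) from None
            columns.append(scores)
    if not columns:
        raise PssmFormatError(f"{path}: no position rows found")
    matrix = np.asarray(columns, dtype=float).T  # -> 20 x M
    return PSSM(
        protein_id=protein_id or path.stem,
        scores=matrix,
        source="psiblast",
    )


def write_psiblast_pssm(path: str | Path, pssm: PSSM, residues: str | None = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (log-odds block only).

    Used to materialize pseudo-PSSMs on disk in the same format the parser
    reads; integer scores round-trip exactly.
    """
    scores = pssm.scores
    res = residues or "X" * pssm.length
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AA_ORDER) + "   " + "  ".join(AA_ORDER) + "\n")
        for j in range(pssm.length):
            cells = " ".join(_fmt_score(v) for v in scores[:, j])
            # duplicate block stands in for the weighted-percentage columns
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{j + 1:5d} {res[j]} {cells}  {pct}  0.00 0.00\n")
        fh.write("\n")


def _fmt_score(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Pseudo-PSSM generation
# ---------------------------------------------------------------------------

def default_base_profile() -> np.ndarray:
    """BLOSUM62 restricted to the canonical 20 residues, in ``AA_ORDER``."""
    blosum = substitution_matrices.load("BLOSUM62")
    prof = np.empty((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            prof[i, j] = blosum[a, b]
    return prof


def read_base_profile(path: str | Path) -> np.ndarray:
    """Read a plain-text 20x20 substitution matrix (BLOSUM-style layout).

    First non-comment line: 20 column labels; following 20 lines: row label
    plus >=20 numbers. Rows/columns are reordered to ``AA_ORDER``.
    """
    rows: dict[str, dict[str, float]] = {}
    col_labels: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            tokens = line.split()
            if col_labels is None:
                col_labels = tokens
                continue
            label, values = tokens[0], tokens[1:]
            rows[label] = {
                c: float(v) for c, v in zip(col_labels, values)
            }
    if col_labels is None or any(aa not in rows for aa in AA_ORDER):
        raise ValueError(f"{path}: not a 20x20 substitution matrix")
    prof = np.array([[rows[a][b] for b in AA_ORDER] for a in AA_ORDER])
    return prof


def pseudo_pssm(
    seq: ProteinSequence,
    base_profile: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PSSM:
    """Deterministic stand-in for a PSI-BLAST profile.

    Column ``j`` is the ``base_profile`` row of residue ``j`` plus i.i.d.
    Gaussian noise with standard deviation ``noise_sd``. The placeholder
    residue 'X' receives the column-average of the base profile.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if base_profile is None:
        base_profile = default_base_profile()
    base_profile = np.asarray(base_profile, dtype=float)
    if base_profile.shape != (20, 20):
        raise ValueError("base_profile must be 20x20")
    placeholder = base_profile.mean(axis=0)
    cols = np.empty((len(seq), 20))
    for j, aa in enumerate(seq.residues):
        cols[j] = placeholder if aa == "X" else base_profile[AA_INDEX[aa]]
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        cols = cols + rng.normal(0.0, noise_sd, size=cols.shape)
    return PSSM(protein_id=seq.id, scores=cols.T, source="pseudo")


# ---------------------------------------------------------------------------
# Optional PSI-BLAST wrapper (untested; requires a local BLAST install + db)
# ---------------------------------------------------------------------------

@dataclass
class PsiBlastConfig:
    """Settings for the optional PSI-BLAST subprocess wrapper."""

    db: str = "swissprot"
    num_iterations: int = 3
    evalue: float = 0.001
    extra_args: list[str] = field(default_factory=list)


def run_psiblast(
    query_fasta: str | Path, out_pssm: str | Path, config: PsiBlastConfig | None = None
) -> PSSM:  # pragma: no cover - external tool, excluded from the test suite
    """Run ``psiblast`` to produce and parse an ASCII PSSM for one query."""
    config = config or PsiBlastConfig()
    if shutil.which("psiblast") is None:
        raise RuntimeError("psiblast executable not found on PATH")
    cmd = [
        "psiblast",
        "-query", str(query_fasta),
        "-db", config.db,
        "-num_iterations", str(config.num_iterations),
        "-evalue", str(config.evalue),
        "-out_ascii_pssm", str(out_pssm),
        *config.extra_args,
    ]
    subprocess.run(cmd, check=True)
    return parse_psiblast_pssm(out_pssm)
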