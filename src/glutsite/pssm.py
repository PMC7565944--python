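"""PSI-BLAST ASCII PSSM parsing, serialization, and window slicing.

Profiles are the ``-out_ascii_pssm`` product of a PSI-BLAST search
(typically 3 iterations at E-value 0.001 against a non-redundant protein
database; see :data:`PSIBLAST_COMMAND_TEMPLATE`).  Only the first numeric
block — the 20 log-odds substitution-score columns — enters the feature
pipeline; the weighted-percentage block and trailing statistics are ignored.

Two acquisition modes are supported downstream: one profile computed per
21-mer peptide (the default), or one profile per whole protein that is
sliced to each window with :func:`slice_profile`.  Rows outside the protein
(terminal X padding) score zero in all 20 columns, the neutral log-odds
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from glutsite.windows import AMINO_ACIDS, PAD

#: Documented external-command template; never executed by the package.
PSIBLAST_COMMAND_TEMPLATE = (
    "psiblast -query {query.fasta} -db {protein_db} -num_iterations 3 "
    "-evalue 0.001 -out_ascii_pssm {output.pssm}"
)


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM stream is malformed; carries a line number."""


@dataclass(frozen=True)
class Profile:
    """An L x 20 matrix of per-position amino-acid substitution scores.

    ``scores[i, j]`` is the log-odds score of observing amino acid
    ``column_order[j]`` at position ``i`` of the source sequence.
    """

    source_id: str
    scores: np.ndarray
    row_positions: str = ""  # residue per row, for cross-checking
    column_order: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(self.column_order):
            raise ValueError(
                f"profile {self.source_id!r}: expected Lx{len(self.column_order)} "
                f"matrix, got shape {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError(f"profile {self.source_id!r}: empty matrix")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        if self.row_positions and len(self.row_positions) != scores.shape[0]:
            raise ValueError(
                f"profile {self.source_id!r}: {len(self.row_positions)} row "
                f"residues for {scores.shape[0]} rows"
            )

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def parse_psiblast_pssm(text: str, source_id: str = "") -> Profile:
    """Parse PSI-BLAST ``-out_ascii_pssm`` output into a :class:`Profile`.

    Keeps the first 20 numeric columns of every position row (the log-odds
    block); the percentage block and the trailing information-content /
    Lambda statistics are discarded.
    """
    lines = text.splitlines()
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_index = 1
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if header_cols is None:
            # the column-header line lists single amino-acid letters
            if all(t in AMINO_ACIDS for t in tokens) and len(tokens) >= 20:
                header_cols = tokens[:20]
                if "".join(header_cols) != AMINO_ACIDS:
                    raise PSSMParseError(
                        f"line {lineno}: unexpected column order "
                        f"{''.join(header_cols)!r}"
                    )
            continue
        if not tokens[0].isdigit():
            break  # trailer (K/Lambda statistics) terminates the body
        if len(tokens) < 22:
            raise PSSMParseError(
                f"line {lineno}: position row has {len(tokens)} fields, "
                "expected index, residue and >= 20 scores"
            )
        if int(tokens[0]) != expected_index:
            raise PSSMParseError(
                f"line {lineno}: position index {tokens[0]} out of order "
                f"(expected {expected_index})"
            )
        expected_index += 1
        residues.append(tokens[1])
        try:
            rows.append([float(t) for t in tokens[2:22]])
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-numeric score field") from exc
    if header_cols is None:
        raise PSSMParseError("no 20-column amino-acid header line found")
    if not rows:
        raise PSSMParseError("no position rows found")
    return Profile(
        source_id=source_id,
        scores=np.array(rows, dtype=float),
        row_positions="".join(residues),
    )


def write_psiblast_pssm(profile: Profile) -> str:
    """Serialize a profile in the PSI-BLAST ASCII dialect (round-trippable).

    The percentage block is written as zeros; it carries no information for
    this pipeline.
    """
    out = ["", "Last position-specific scoring matrix computed"]
    letters = "  ".join(AMINO_ACIDS)
    out.append(" " * 10 + letters + "   " + letters)
    residues = profile.row_positions or PAD * profile.length
    for i in range(profile.length):
        scores = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:8.3f}"
                          for v in profile.scores[i])
        pct = " ".join("0" for _ in range(20))
        out.append(f"{i + 1:5d} {residues[i]}  {scores}   {pct}  0.00 0.00")
    out.append("")
    out.append("                      K         Lambda")
    out.append("Standard Ungapped    0.1347     0.3176")
    return "\n".join(out) + "\n"


def slice_profile(profile: Profile, center: int, xi: int = 10) -> Profile:
    """Cut a whole-protein profile down to a ``(2*xi+1) x 20`` window profile.

    Rows beyond either terminus are zero-filled, mirroring the X padding of
    sequence windows.
    """
    if not 1 <= center <= profile.length:
        raise ValueError(
            f"center {center} out of range 1..{profile.length} "
            f"for profile {profile.source_id!r}"
        )
    width = 2 * xi + 1
    out = np.zeros((width, 20), dtype=float)
    residues = list(PAD * width)
    src_res = profile.row_positions
    for k in range(width):
        i = center - xi + k  # 1-based source row
        if 1 <= i <= profile.length:
            out[k] = profile.scores[i - 1]
            if src_res:
                residues[k] = src_res[i - 1]
    return Profile(
        source_id=f"{profile.source_id}|{center}",
        scores=out,
        row_positions="".join(residues) if src_res else "",
    )


# ---------------------------------------------------------------------------
# Plain CSV serialization (fixture-friendly)
# ---------------------------------------------------------------------------


def write_profile_csv(profile: Profile, path: str | Path) -> None:
    """Write a profile as CSV: ``residue`` column then one column per amino acid."""
    df = pd.DataFrame(profile.scores, columns=list(profile.column_order))
    df.insert(0, "residue", list(profile.row_positions or PAD * profile.length))
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path, source_id: str = "") -> Profile:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "residue"]
    if "".join(cols) != AMINO_ACIDS:
        raise PSSMParseError(
            f"{path}: expected columns {AMINO_ACIDS!r}, got {''.join(cols)!r}"
        )
    residues = "".join(df["residue"].astype(str)) if "residue" in df else ""
    return Profile(
        source_id=source_id or str(path),
        scores=df[cols].to_numpy(dtype=float),
        row_positions=residues,
    )
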