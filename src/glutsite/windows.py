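"""Peptide window extraction around candidate lysine sites.

A candidate site is any lysine (K) in a protein.  Each site is represented
by a window of ``2*xi + 1`` residues centered on the lysine; positions that
fall outside the protein are padded with the dummy residue ``X`` so every
window has uniform length.  A window is *positive* when its center position
appears in the protein's annotated glutarylation sites and *negative*
otherwise — no separate negative list is consumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The canonical 20-letter amino-acid alphabet (PSSM column order).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Dummy residue used for terminal padding and unknown residues.
PAD = "X"

_VALID = set(AMINO_ACIDS) | {PAD}

#: Ambiguity / non-standard codes mapped to the dummy residue.
_NONSTANDARD = set("BZJUO*-.")


class AnnotationMismatchError(ValueError):
    """An annotated positive position does not hold a lysine."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based glutarylation site annotations."""

    id: str
    sequence: str
    positive_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seq = _sanitize_sequence(self.sequence, self.id)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "positive_positions", frozenset(self.positive_positions))
        for pos in self.positive_positions:
            if not 1 <= pos <= len(seq):
                raise AnnotationMismatchError(
                    f"protein {self.id!r}: annotated position {pos} outside "
                    f"sequence of length {len(seq)}"
                )
            if seq[pos - 1] != "K":
                raise AnnotationMismatchError(
                    f"protein {self.id!r}: annotated position {pos} is "
                    f"{seq[pos - 1]!r}, expected K"
                )


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length lysine-centered peptide with label and provenance.

    ``center_position`` is the 1-based position of the central lysine in the
    source protein; ``sequence`` has odd length with K in the middle and X
    padding where the protein terminates inside the window.
    """

    protein_id: str
    center_position: int
    sequence: str
    label: int  # 1 = glutarylated, 0 = not

    @property
    def xi(self) -> int:
        return len(self.sequence) // 2

    @property
    def sample_id(self) -> str:
        return f"{self.protein_id}|{self.center_position}"


def _sanitize_sequence(sequence: str, protein_id: str) -> str:
    seq = sequence.upper()
    bad = {c for c in seq if c not in _VALID}
    if bad:
        unknown = bad - _NONSTANDARD
        if unknown:
            raise ValueError(
                f"protein {protein_id!r}: invalid residue(s) {sorted(unknown)}"
            )
        logger.warning(
            "protein %r: mapping non-standard residue(s) %s to X",
            protein_id,
            sorted(bad),
        )
        seq = "".join(PAD if c in bad else c for c in seq)
    return seq


def extract_windows(protein: ProteinRecord, xi: int = 10) -> list[PeptideWindow]:
    """Extract one ``2*xi + 1``-residue window per lysine in *protein*.

    Windows centered on annotated positions are labeled positive (1), all
    other lysines negative (0).  Termini are padded with X.
    """
    if xi < 1:
        raise ValueError(f"xi must be >= 1, got {xi}")
    if not protein.sequence:
        raise ValueError(f"protein {protein.id!r} has empty sequence")
    padded = PAD * xi + protein.sequence + PAD * xi
    windows = []
    for i, residue in enumerate(protein.sequence, start=1):
        if residue != "K":
            continue
        fragment = padded[i - 1 : i - 1 + 2 * xi + 1]
        windows.append(
            PeptideWindow(
                protein_id=protein.id,
                center_position=i,
                sequence=fragment,
                label=int(i in protein.positive_positions),
            )
        )
    return windows


def extract_window_at(protein: ProteinRecord, center: int, xi: int = 10) -> PeptideWindow:
    """Re-extract the window at a known center (provenance replay)."""
    if not 1 <= center <= len(protein.sequence):
        raise ValueError(f"center {center} outside protein {protein.id!r}")
    if protein.sequence[center - 1] != "K":
        raise AnnotationMismatchError(
            f"protein {protein.id!r}: position {center} is not K"
        )
    padded = PAD * xi + protein.sequence + PAD * xi
    return PeptideWindow(
        protein_id=protein.id,
        center_position=center,
        sequence=padded[center - 1 : center - 1 + 2 * xi + 1],
        label=int(center in protein.positive_positions),
    )


# ---------------------------------------------------------------------------
# I/O: FASTA sequences, TSV annotations, FASTA windows
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> dict[str, set[int]]:
    """Read a ``protein_id<TAB>position`` annotation table.

    Lines starting with ``#`` and blank lines are ignored; positions are
    1-based.
    """
    sites: dict[str, set[int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>position', got {raw!r}")
        pid, pos_str = parts
        try:
            pos = int(pos_str)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer position {pos_str!r}") from exc
        sites.setdefault(pid, set()).add(pos)
    return sites


def read_proteins(
    fasta_path: str | Path, annotations: dict[str, set[int]] | str | Path | None = None
) -> list[ProteinRecord]:
    """Load proteins from FASTA and attach site annotations by id."""
    if annotations is None:
        sites: dict[str, set[int]] = {}
    elif isinstance(annotations, (str, Path)):
        sites = read_annotations(annotations)
    else:
        sites = annotations
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                positive_positions=frozenset(sites.get(rec.id, set())),
            )
        )
    return records


def write_windows_fasta(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as FASTA with ``>{protein_id}|{center}|{label}`` headers."""
    records = [
        SeqRecord(
            Seq(w.sequence),
            id=f"{w.protein_id}|{w.center_position}|{'positive' if w.label else 'negative'}",
            description="",
        )
        for w in windows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_windows_fasta(path: str | Path) -> list[PeptideWindow]:
    """Read windows written by :func:`write_windows_fasta`."""
    windows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            pid, center, label = rec.id.rsplit("|", 2)
        except ValueError as exc:
            raise ValueError(f"malformed window header {rec.id!r}") from exc
        windows.append(
            PeptideWindow(
                protein_id=pid,
                center_position=int(center),
                sequence=str(rec.seq).upper(),
                label=int(label == "positive"),
            )
        )
    return windows


def write_proteins_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins]
    SeqIO.write(records, str(path), "fasta")


def write_annotations(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    lines = ["# protein_id\tposition"]
    for p in proteins:
        for pos in sorted(p.positive_positions):
            lines.append(f"{p.id}\t{pos}")
    Path(path).write_text("\n".join(lines) + "\n")
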