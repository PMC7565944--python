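"""Synthetic annotated proteins and class-conditional PSSM profiles.

Real inputs to this pipeline are curated modification databases plus
PSI-BLAST profiles computed against a live protein database; neither is
needed for testing.  This module emulates both ends: random protein
sequences with lysine sites annotated at a configurable rate, and window
profiles drawn around a residue-dependent integer baseline on the log-odds
scale (identity-favoring scores in roughly [-5, 9], so fixtures resemble
real PSSM magnitudes).  For positive windows the means of designated
*signal columns* are shifted by ``effect_size`` in the five rows centered
on the site — the premise being that residues flanking a modification site
carry the discriminative evolutionary signal, which also makes
feature-importance recovery experiments meaningful.

With ``effect_size = 0`` the positive and negative profile distributions
are identical by construction.  Everything is deterministic under the spec
seed: per-window profile seeds are derived from the window's provenance, so
generation order never matters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from glutsite.dataset import LabeledDataset
from glutsite.features import extract_features
from glutsite.pssm import Profile
from glutsite.windows import AMINO_ACIDS, PAD, PeptideWindow, ProteinRecord, extract_windows

#: Lysine frequency used when drawing sequences (boosted above uniform 5%).
K_FREQUENCY = 0.08

#: Match / mismatch baseline scores on the log-odds scale.
_MATCH_SCORE = 6.0
_MISMATCH_SCORE = -1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark generator."""

    n_proteins: int = 50
    protein_length: int = 200
    site_rate: float = 0.15
    effect_size: float = 3.0
    signal_columns: tuple[int, ...] = (0, 1, 2, 3)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        if not 0 <= self.site_rate <= 1:
            raise ValueError("site_rate must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(not 0 <= c < 20 for c in self.signal_columns):
            raise ValueError("signal_columns must be indices in 0..19")
        object.__setattr__(self, "signal_columns", tuple(self.signal_columns))


def generate_proteins(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Draw random annotated proteins.

    Residues are drawn i.i.d. with lysine at :data:`K_FREQUENCY` and the
    other 19 amino acids sharing the remainder uniformly; each lysine is
    annotated positive with probability ``spec.site_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.full(20, (1.0 - K_FREQUENCY) / 19.0)
    probs[AMINO_ACIDS.index("K")] = K_FREQUENCY
    proteins = []
    for p in range(spec.n_proteins):
        idx = rng.choice(20, size=spec.protein_length, p=probs)
        seq = "".join(AMINO_ACIDS[i] for i in idx)
        k_positions = [i + 1 for i, c in enumerate(seq) if c == "K"]
        marks = rng.random(len(k_positions)) < spec.site_rate
        positives = frozenset(pos for pos, m in zip(k_positions, marks) if m)
        proteins.append(
            ProteinRecord(id=f"SYN{p + 1:04d}", sequence=seq, positive_positions=positives)
        )
    return proteins


def _window_seed(window: PeptideWindow, spec: SyntheticSpec) -> int:
    # stable per-window stream independent of generation order
    crc = zlib.crc32(window.sample_id.encode())
    return int((spec.seed * 0x9E3779B1 + crc) % (2**31))


def generate_profile(window: PeptideWindow, spec: SyntheticSpec) -> Profile:
    """Draw a class-conditional window profile.

    Scores are Gaussian (SD ``noise_sd``) around an identity-favoring
    residue baseline; for positive windows the signal-column means are
    raised by ``effect_size`` in the five rows centered on the lysine.
    X padding rows are identically zero.
    """
    rng = np.random.default_rng(_window_seed(window, spec))
    L = len(window.sequence)
    scores = np.zeros((L, 20))
    center = L // 2
    for i, residue in enumerate(window.sequence):
        if residue == PAD:
            continue  # padding rows carry the neutral zero score
        row = np.full(20, _MISMATCH_SCORE)
        row[AMINO_ACIDS.index(residue)] = _MATCH_SCORE
        if window.label == 1 and abs(i - center) <= 2:
            row[list(spec.signal_columns)] += spec.effect_size
        scores[i] = np.round(row + rng.normal(0.0, spec.noise_sd, size=20), 3)
    return Profile(
        source_id=window.sample_id, scores=scores, row_positions=window.sequence
    )


def generate_windows(spec: SyntheticSpec, xi: int = 10) -> list[PeptideWindow]:
    """All lysine windows over a fresh set of synthetic proteins."""
    windows: list[PeptideWindow] = []
    for protein in generate_proteins(spec):
        windows.extend(extract_windows(protein, xi=xi))
    return windows


def generate_dataset(
    spec: SyntheticSpec,
    xi: int = 10,
    n_per_class: int | None = None,
) -> LabeledDataset:
    """End-to-end synthetic feature dataset.

    Generates proteins, extracts windows, draws a profile per window and
    featurizes it.  With ``n_per_class`` the first that many positive and
    negative windows are kept (raising if the spec cannot supply them).
    """
    windows = generate_windows(spec, xi=xi)
    if n_per_class is not None:
        pos = [w for w in windows if w.label == 1][:n_per_class]
        neg = [w for w in windows if w.label == 0][:n_per_class]
        if len(pos) < n_per_class or len(neg) < n_per_class:
            raise ValueError(
                f"spec yields only {len(pos)} positive / {len(neg)} negative "
                f"windows; requested {n_per_class} per class"
            )
        windows = pos + neg
    features = np.array([extract_features(generate_profile(w, spec)) for w in windows])
    return LabeledDataset(
        features=features,
        labels=np.array([w.label for w in windows]),
        provenance=tuple(w.sample_id for w in windows),
    )
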