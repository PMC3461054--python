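"""Heptad-register annotation and atypicality statistics for coiled-coil stalks.

Coiled-coil sequences repeat with a seven-residue period a-b-c-d-e-f-g in
which positions a and d form the hydrophobic dimer seam. Kinesin-II stalks
are unusual in carrying charged residues at many a/d positions ("atypical
heptads"), which weakens the coil. This module assigns registers from
user-supplied coil blocks, scans for the most hydrophobically consistent
register with a simple Kyte-Doolittle window score (a deliberately
lightweight stand-in for dedicated coiled-coil predictors), counts charged
a/d occupancies, and slices named stalk segments in full-protein numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "HeptadAnnotation",
    "AtypicalityStats",
    "SegmentScheme",
    "assign_register",
    "score_register",
    "atypicality_stats",
    "slice_segment",
    "KLP64D_SEGMENTS",
    "KLP68D_SEGMENTS",
    "KYTE_DOOLITTLE",
    "DEFAULT_CHARGED",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
REGISTER_LETTERS = "abcdefg"
#: Physiological-pH charged set; His is excluded by default.
DEFAULT_CHARGED = frozenset("DEKR")

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter sequence with a full-protein numbering offset (1-based)."""

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self):
        bad = set(self.residues.upper()) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"non-amino-acid letters in sequence: {sorted(bad)}")
        if self.numbering_offset < 1:
            raise ValueError("numbering offset must be >= 1")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self):
        return len(self.residues)

    @property
    def first_residue(self) -> int:
        return self.numbering_offset

    @property
    def last_residue(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def index_of(self, residue_number: int) -> int:
        """0-based string index of a full-protein residue number."""
        i = residue_number - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(f"residue {residue_number} outside "
                             f"[{self.first_residue}, {self.last_residue}]")
        return i

    @classmethod
    def from_fasta(cls, path, numbering_offset: int = 1) -> list["ProteinSequence"]:
        return [cls(rec.id, str(rec.seq), numbering_offset)
                for rec in SeqIO.parse(str(path), "fasta")]


@dataclass(frozen=True)
class HeptadAnnotation:
    """Register string over {a..g, '-'} aligned to a sequence."""

    register: str
    coil_blocks: tuple = ()
    score: float = float("nan")
    low_confidence: bool = False

    def __post_init__(self):
        bad = set(self.register) - set(REGISTER_LETTERS) - {"-"}
        if bad:
            raise ValueError(f"invalid register letters: {sorted(bad)}")


@dataclass(frozen=True)
class AtypicalityStats:
    n_a_d_positions: int
    n_charged_a_d: int
    fraction_charged_a_d: float
    positions: tuple  # of (residue_number, letter, register)


class SegmentScheme:
    """Named inclusive intervals in full-protein numbering."""

    def __init__(self, intervals: dict[str, tuple[int, int]]):
        for name, (start, end) in intervals.items():
            if end < start:
                raise ValueError(f"segment {name!r}: end {end} < start {start}")
        self.intervals = dict(intervals)

    def __contains__(self, name):
        return name in self.intervals

    def __getitem__(self, name) -> tuple[int, int]:
        return self.intervals[name]

    def names(self):
        return list(self.intervals)


# Printed stalk segment boundaries (full-protein numbering, inclusive).
# SN2 and SC2-T ends are not printed anywhere; supply them via user config.
KLP64D_SEGMENTS = SegmentScheme({
    "S": (425, 589), "SN1": (425, 506), "SC1": (517, 589), "SC2": (529, 589),
})
KLP68D_SEGMENTS = SegmentScheme({
    "S": (423, 584), "SN1": (423, 501), "SC1": (511, 584), "middle": (502, 520),
})


def assign_register(seq: ProteinSequence,
                    blocks: list[tuple[int, int, str]]) -> HeptadAnnotation:
    """Cyclic a..g labelling of coil blocks given each block's starting phase.

    ``blocks`` are (start, end, phase) in full-protein numbering, inclusive
    on both ends; residues outside every block get '-'. Partial heptads are
    allowed and truncate mid-cycle.
    """
    register = ["-"] * len(seq)
    occupied = np.zeros(len(seq), dtype=bool)
    clean = []
    for start, end, phase in blocks:
        if phase not in REGISTER_LETTERS:
            raise ValueError(f"phase must be one of a..g, got {phase!r}")
        if end < start:
            raise ValueError(f"block ({start}, {end}) has end < start")
        i0, i1 = seq.index_of(start), seq.index_of(end)
        if occupied[i0:i1 + 1].any():
            raise ValueError(f"block ({start}, {end}) overlaps an earlier block")
        occupied[i0:i1 + 1] = True
        p0 = REGISTER_LETTERS.index(phase)
        for k, i in enumerate(range(i0, i1 + 1)):
            register[i] = REGISTER_LETTERS[(p0 + k) % 7]
        clean.append((start, end))
    return HeptadAnnotation("".join(register), tuple(clean))


def _window_phase_scores(residues: str) -> np.ndarray:
    """Mean a/d hydrophobicity minus mean elsewhere, for each of 7 offsets.

    Offset p places register 'a' at string index p (mod 7).
    """
    h = np.array([KYTE_DOOLITTLE[c] for c in residues])
    idx = np.arange(len(residues))
    scores = np.empty(7)
    for p in range(7):
        pos = (idx - p) % 7
        ad = (pos == 0) | (pos == 3)
        scores[p] = h[ad].mean() - h[~ad].mean()
    return scores


def score_register(seq: ProteinSequence, window: int = 21,
                   min_score: float = 0.5) -> HeptadAnnotation:
    """Best-phase heptad register by sliding hydrophobicity window.

    For every window the seven possible phase offsets are scored as mean
    Kyte-Doolittle hydropathy at a/d minus the mean at b,c,e,f,g; each
    residue takes the phase voted by the windows covering it. Ties break to
    the lowest offset and flag the annotation low-confidence, as does a best
    score below ``min_score``. This is a lightweight register scanner, not a
    probabilistic coiled-coil predictor.
    """
    n = len(seq)
    if window < 14:
        raise ValueError("window must be >= 14 (two heptads)")
    if n < window:
        raise ValueError(f"sequence length {n} is shorter than the window {window}")
    votes = np.zeros((n, 7))
    window_scores = []
    any_tie = False
    for start in range(0, n - window + 1):
        sub = seq.residues[start:start + window]
        scores = _window_phase_scores(sub)
        top = scores.max()
        # tolerance guards against float noise making equal offsets "win"
        winners = np.flatnonzero(scores >= top - 1e-9)
        if winners.size > 1:
            any_tie = True
        best = int(winners[0])  # deterministic tie-break: lowest offset
        window_scores.append(top)
        if top > 1e-9:
            # offset local to the window -> phase of the whole sequence:
            # phase p puts register 'a' at string indices i with i % 7 == p
            global_phase = (best + start) % 7
            votes[start:start + window, global_phase] += top
    phases = votes.argmax(axis=1)
    register = "".join(
        REGISTER_LETTERS[(i - phases[i]) % 7] for i in range(n))
    # merge runs of consistent phase into blocks (full-protein numbering)
    blocks = []
    run_start = 0
    for i in range(1, n + 1):
        if i == n or phases[i] != phases[run_start]:
            blocks.append((run_start + seq.numbering_offset,
                           i - 1 + seq.numbering_offset))
            run_start = i
    score = float(np.mean(window_scores))
    return HeptadAnnotation(register, tuple(blocks), score=score,
                            low_confidence=any_tie or score < min_score)


def atypicality_stats(annotation: HeptadAnnotation, seq: ProteinSequence,
                      charged_set=DEFAULT_CHARGED) -> AtypicalityStats:
    """Count charged residues occupying a/d register positions."""
    if len(annotation.register) != len(seq):
        raise ValueError("annotation and sequence lengths differ")
    positions = []
    n_ad = 0
    for i, (aa, reg) in enumerate(zip(seq.residues, annotation.register)):
        if reg in ("a", "d"):
            n_ad += 1
            if aa in charged_set:
                positions.append((i + seq.numbering_offset, aa, reg))
    n_charged = len(positions)
    frac = n_charged / n_ad if n_ad else 0.0
    return AtypicalityStats(n_ad, n_charged, frac, tuple(positions))


def slice_segment(seq: ProteinSequence, scheme: SegmentScheme,
                  name: str) -> ProteinSequence:
    """Extract a named segment, preserving full-protein numbering."""
    if name not in scheme:
        raise KeyError(f"unknown segment {name!r}; known: {scheme.names()}")
    start, end = scheme[name]
    i0, i1 = seq.index_of(start), seq.index_of(end)
    return ProteinSequence(f"{seq.id}_{name}", seq.residues[i0:i1 + 1], start)


def annotation_table(seq: ProteinSequence, annotation: HeptadAnnotation,
                     charged_set=DEFAULT_CHARGED):
    """Per-residue table (residue number, letter, register, charged_at_ad)."""
    import pandas as pd

    rows = [(i + seq.numbering_offset, aa, reg,
             reg in ("a", "d") and aa in charged_set)
            for i, (aa, reg) in enumerate(zip(seq.residues, annotation.register))]
    return pd.DataFrame(rows, columns=["residue", "letter", "register",
                                       "charged_at_ad"])
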