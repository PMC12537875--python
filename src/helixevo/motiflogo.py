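"""CRAC/CARC linear-motif scanning and Shannon-entropy sequence logos.

The CRAC motif is the loose pattern (L/V)-X(1-5)-(Y)-X(1-5)-(K/R) read
N-to-C; CARC is its inverse-order pattern (K/R)-X(1-5)-(Y/F)-X(1-5)-(L/V),
also read N-to-C. Spacer X positions may hold any residue. Every anchor
triple satisfying the class and spacer constraints is reported, so overlaps
and shared anchors are allowed.

Sequence logos summarize per-position conservation of an aligned sequence
set: information content R_i = log2(20) - H_i bits, with H_i the Shannon
entropy of the residue frequencies at position i, and letter heights
p_i(a) * R_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from helixevo.seqcore import ALPHABET, ALPHABET_SET


@dataclass(frozen=True)
class MotifPattern:
    """Three ordered anchor classes with bounded spacers between them."""

    name: str
    anchors: tuple  # three frozensets of one-letter codes
    spacer_min: int = 1
    spacer_max: int = 5

    def __post_init__(self):
        if len(self.anchors) != 3:
            raise ValueError("motif patterns have exactly three anchors")
        if not 1 <= self.spacer_min <= self.spacer_max <= 5:
            raise ValueError("spacer bounds must satisfy 1 <= min <= max <= 5")


CRAC = MotifPattern("CRAC", (frozenset("LV"), frozenset("Y"), frozenset("KR")))
CARC = MotifPattern("CARC", (frozenset("KR"), frozenset("YF"), frozenset("LV")))
PATTERNS = {"CRAC": CRAC, "CARC": CARC}


@dataclass(frozen=True)
class MotifMatch:
    """One anchor triple; positions are 1-based, p1 < p2 < p3."""

    pattern: str
    p1: int
    p2: int
    p3: int

    @property
    def span(self) -> tuple:
        return (self.p1, self.p3)

    @property
    def spacers(self) -> tuple:
        return (self.p2 - self.p1 - 1, self.p3 - self.p2 - 1)


def scan(sequence: str, pattern: MotifPattern) -> list:
    """Enumerate ALL matches of the pattern in the sequence (N-to-C).

    Returns every (p1, p2, p3) with residues in the anchor classes and both
    spacers within the pattern's bounds. Empty list when nothing matches.
    """
    for aa in sequence:
        if aa not in ALPHABET_SET:
            raise ValueError(f"non-alphabet symbol {aa!r}")
    a1, a2, a3 = pattern.anchors
    lo, hi = pattern.spacer_min, pattern.spacer_max
    n = len(sequence)
    matches = []
    for i in range(n):
        if sequence[i] not in a1:
            continue
        for j in range(i + lo + 1, min(i + hi + 2, n)):
            if sequence[j] not in a2:
                continue
            for k in range(j + lo + 1, min(j + hi + 2, n)):
                if sequence[k] in a3:
                    matches.append(MotifMatch(pattern.name, i + 1, j + 1, k + 1))
    return matches


def motif_presence(sequences, pattern: MotifPattern) -> float:
    """Fraction of sequences carrying at least one match."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need a non-empty sequence set")
    hits = sum(1 for s in sequences if scan(s, pattern))
    return hits / len(sequences)


def mutate_anchors_to_ala(sequence: str, matches) -> str:
    """Set every anchor position of the supplied matches to alanine."""
    out = list(sequence)
    for m in matches:
        for pos in (m.p1, m.p2, m.p3):
            if not 1 <= pos <= len(sequence):
                raise ValueError(f"anchor position {pos} outside sequence")
            out[pos - 1] = "A"
    return "".join(out)


def scan_to_tsv(records, pattern: MotifPattern, path) -> None:
    """Scan (id, sequence) records and write hits as a TSV."""
    rows = []
    for rid, seq in records:
        for m in scan(seq, pattern):
            rows.append((rid, m.pattern, m.p1, m.p2, m.p3))
    pd.DataFrame(rows, columns=["id", "pattern", "p1", "p2", "p3"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence logos

LOG2_20 = float(np.log2(20))


@dataclass
class LogoMatrix:
    """Per-position residue frequencies, information content, letter heights."""

    frequencies: np.ndarray   # (L, 20), rows sum to 1
    n_sequences: int
    small_sample_corrected: bool = False
    _info: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        p = self.frequencies
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        entropy = -plogp.sum(axis=1)
        info = LOG2_20 - entropy
        if self.small_sample_corrected:
            # standard small-sample correction e_n = (s-1)/(2 ln2 n)
            info = info - (20 - 1) / (2 * np.log(2) * self.n_sequences)
        self._info = np.clip(info, 0.0, LOG2_20)

    @property
    def information(self) -> np.ndarray:
        """R_i in bits, within [0, log2 20]."""
        return self._info

    @property
    def heights(self) -> np.ndarray:
        """Letter heights p_i(a) * R_i, shape (L, 20)."""
        return self.frequencies * self._info[:, None]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.heights, columns=list(ALPHABET))
        df.insert(0, "position", np.arange(1, len(df) + 1))
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def logo(sequences, small_sample_correction: bool = False) -> LogoMatrix:
    """Compute the logo matrix of an equal-length sequence set."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("all sequences must have equal length")
    idx = {aa: i for i, aa in enumerate(ALPHABET)}
    counts = np.zeros((L, 20))
    for s in sequences:
        for i, aa in enumerate(s):
            try:
                counts[i, idx[aa]] += 1
            except KeyError:
                raise ValueError(f"non-alphabet symbol {aa!r}")
    return LogoMatrix(frequencies=counts / len(sequences),
                      n_sequences=len(sequences),
                      small_sample_corrected=small_sample_correction)


def mirror_check(matrix: LogoMatrix) -> np.ndarray:
    """Per position-pair total-variation distance between p_i and p_{L+1-i}.

    Zero everywhere for sets of palindromic sequences. Returns one value per
    pair (i, L+1-i), i = 1..L/2.
    """
    p = matrix.frequencies
    L = p.shape[0]
    if L % 2 != 0:
        raise ValueError("mirror check requires an even sequence length")
    half = L // 2
    return 0.5 * np.abs(p[:half] - p[::-1][:half]).sum(axis=1)
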