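"""Normalization of annotated transmembrane spans into 20-residue windows.

Predicted TM segments vary in length, but downstream fitness predictors
operate on fixed 20-residue sequences. Spans longer than 20 residues are
removed; spans shorter than 20 are extended as evenly as possible on both
sides with the adjacent non-TM residues of the parent protein (the extra
residue of an odd deficit goes to the N-terminal side by default). If a
flank reaches a protein terminus, the remaining deficit shifts to the other
side; a window is rejected only when the whole protein cannot supply 20
residues. Proteins are split into single-pass (1 span) and multi-pass
(>= 2 spans) sets for separate analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_LENGTH = 20


@dataclass
class ProteinRecord:
    """A protein with 1-based inclusive TM span annotations."""

    id: str
    sequence: str
    tm_spans: list          # [(start, end), ...] 1-based inclusive
    quality_flags: int = 10

    def __post_init__(self):
        prev_end = 0
        for start, end in self.tm_spans:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"{self.id}: span ({start}, {end}) outside sequence of "
                    f"length {len(self.sequence)}"
                )
            if start <= prev_end:
                raise ValueError(f"{self.id}: spans must be ascending, non-overlapping")
            prev_end = end

    @property
    def n_passes(self) -> int:
        return len(self.tm_spans)


@dataclass
class TMDWindow:
    protein_id: str
    pass_index: int          # 1-based index of the span within the protein
    sequence: str
    origin_span: tuple
    n_extended_left: int
    n_extended_right: int

    def __post_init__(self):
        if len(self.sequence) != WINDOW_LENGTH:
            raise ValueError(
                f"window must be exactly {WINDOW_LENGTH} residues, "
                f"got {len(self.sequence)}"
            )


@dataclass
class Rejection:
    protein_id: str
    pass_index: int
    origin_span: tuple
    reason: str              # "too_long" | "terminus"


def normalize_span(record: ProteinRecord, span, pass_index: int = 1,
                   odd_deficit_to_n: bool = True):
    """Normalize one TM span to a 20-residue window, or reject it.

    Returns a TMDWindow or a Rejection. Spans > 20 residues are rejected
    ("too_long"); spans of exactly 20 pass unchanged; shorter spans are
    extended with flanking protein residues, the deficit split as evenly as
    possible (parity controlled by ``odd_deficit_to_n``).
    """
    start, end = span
    if not (1 <= start <= end <= len(record.sequence)):
        raise ValueError(f"span ({start}, {end}) outside protein sequence")
    span_len = end - start + 1
    if span_len > WINDOW_LENGTH:
        return Rejection(record.id, pass_index, (start, end), "too_long")

    deficit = WINDOW_LENGTH - span_len
    left_want = (deficit + 1) // 2 if odd_deficit_to_n else deficit // 2
    right_want = deficit - left_want

    left_avail = start - 1
    right_avail = len(record.sequence) - end
    left = min(left_want, left_avail)
    right = min(right_want + (left_want - left), right_avail)
    # shift any unmet right-side demand back to the left
    left = min(left + (right_want + (left_want - left) - right), left_avail)
    if left + right != deficit:
        return Rejection(record.id, pass_index, (start, end), "terminus")

    seq = record.sequence[start - 1 - left: end + right]
    return TMDWindow(
        protein_id=record.id, pass_index=pass_index, sequence=seq,
        origin_span=(start, end), n_extended_left=left, n_extended_right=right,
    )


def normalize_record(record: ProteinRecord, odd_deficit_to_n: bool = True):
    """Normalize every span of a protein; returns (windows, rejections)."""
    windows, rejections = [], []
    for i, span in enumerate(record.tm_spans, start=1):
        result = normalize_span(record, span, pass_index=i,
                                odd_deficit_to_n=odd_deficit_to_n)
        (windows if isinstance(result, TMDWindow) else rejections).append(result)
    return windows, rejections


def split_by_passes(records, min_quality_flags: int = 10,
                    odd_deficit_to_n: bool = True) -> dict:
    """Partition proteins into single-pass and multi-pass sets and normalize.

    Proteins failing the quality-flag threshold or carrying zero spans are
    excluded (the latter with a warning). Returns a dict with per-set
    protein lists, windows, and rejections.
    """
    single, multi = [], []
    for record in records:
        if record.quality_flags < min_quality_flags:
            continue
        if record.n_passes == 0:
            warnings.warn(f"{record.id}: no TM spans, excluded")
            continue
        (single if record.n_passes == 1 else multi).append(record)

    out = {}
    for name, group in (("single_pass", single), ("multi_pass", multi)):
        windows, rejections = [], []
        for record in group:
            w, r = normalize_record(record, odd_deficit_to_n=odd_deficit_to_n)
            windows.extend(w)
            rejections.extend(r)
        out[name] = {"proteins": group, "windows": windows,
                     "rejections": rejections}
    return out


def predict_batch(windows, predictor) -> pd.DataFrame:
    """Apply a sequence->float predictor to every window.

    Returns a DataFrame with columns id, pass_index, sequence, fitness;
    quartile summaries are available via ``.fitness.quantile``.
    """
    rows = [
        (w.protein_id, w.pass_index, w.sequence, float(predictor(w.sequence)))
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["id", "pass_index", "sequence", "fitness"])


def fitness_quartiles(table: pd.DataFrame) -> dict:
    q = table["fitness"].quantile([0.25, 0.5, 0.75])
    return {"q1": float(q[0.25]), "median": float(q[0.5]), "q3": float(q[0.75]),
            "iqr": float(q[0.75] - q[0.25]), "n": int(len(table))}


# ---------------------------------------------------------------------------
# I/O: `id<TAB>sequence<TAB>spans` with spans as `start-end;start-end`

def read_proteome_tsv(path) -> list:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:3] != ["id", "sequence", "spans"]:
            raise ValueError("expected header 'id\\tsequence\\tspans'")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            rid, seq, spans_s, *rest = line.split("\t")
            spans = []
            if spans_s:
                for part in spans_s.split(";"):
                    a, _, b = part.partition("-")
                    spans.append((int(a), int(b)))
            flags = int(rest[0]) if rest else 10
            records.append(ProteinRecord(rid, seq.upper(), spans, flags))
    return records


def write_proteome_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\tspans\tquality_flags\n")
        for r in records:
            spans = ";".join(f"{a}-{b}" for a, b in r.tm_spans)
            fh.write(f"{r.id}\t{r.sequence}\t{spans}\t{r.quality_flags}\n")


def write_windows_tsv(windows, path) -> None:
    df = pd.DataFrame(
        [(w.protein_id, w.pass_index, w.sequence, w.origin_span[0],
          w.origin_span[1], w.n_extended_left, w.n_extended_right)
         for w in windows],
        columns=["id", "pass_index", "sequence", "span_start", "span_end",
                 "ext_left", "ext_right"],
    )
    df.to_csv(path, sep="\t", index=False)
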