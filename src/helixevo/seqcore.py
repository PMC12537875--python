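"""Amino-acid alphabet, palindromic genotypes, template builders, sequence I/O.

The search space of 20-residue transmembrane peptides is reduced by encoding
each candidate as a mirror-symmetric (palindromic) sequence: only the first
L/2 residues are free, the rest are their mirror image. This is appropriate
for a symmetric bilayer, where the two membrane leaflets are equivalent, and
shrinks the space from 20^20 to 20^10 distinct genotypes at L = 20.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes, alphabetical order.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


def encode_residue(aa: str) -> int:
    """Map a one-letter code to its alphabet index (a bijection)."""
    try:
        return ALPHABET_INDEX[aa]
    except KeyError:
        raise ValueError(f"unknown residue {aa!r}; expected one of {ALPHABET}")


def decode_residue(idx: int) -> str:
    if not 0 <= idx < len(ALPHABET):
        raise ValueError(f"residue index {idx} out of range 0..19")
    return ALPHABET[idx]


@dataclass(frozen=True)
class PalindromicGenotype:
    """The L/2 free residues encoding a mirror-symmetric peptide of length L."""

    free: str
    length: int = 20

    def __post_init__(self):
        if self.length % 2 != 0:
            raise ValueError(f"total length must be even, got {self.length}")
        if len(self.free) != self.length // 2:
            raise ValueError(
                f"free half-genome must have length {self.length // 2}, "
                f"got {len(self.free)}"
            )
        for i, aa in enumerate(self.free):
            if aa not in ALPHABET_SET:
                raise ValueError(f"non-alphabet symbol {aa!r} at position {i + 1}")

    def expand(self) -> str:
        return self.free + self.free[::-1]


def expand_palindrome(genotype: PalindromicGenotype) -> str:
    """Expand a half-genome into the full mirror-symmetric peptide.

    The result s satisfies s[i] == free[i] for i < L/2 and
    s[L-1-i] == free[i], i.e. it reads identically in both directions.
    """
    return genotype.expand()


# ---------------------------------------------------------------------------
# Template grammar: blocks of `<residue-or-group><count>`, e.g. "D3K3L11K3D3"
# or "GK2[LA]7LK2A" (bracketed groups repeat as a unit; a missing count is 1).

_BLOCK_RE = re.compile(r"([A-Z])(\d*)|\[([A-Z]+)\](\d*)")


def parse_template(spec: str) -> list[tuple[str, int]]:
    """Parse a template grammar string into (unit, count) blocks."""
    blocks: list[tuple[str, int]] = []
    pos = 0
    while pos < len(spec):
        m = _BLOCK_RE.match(spec, pos)
        if m is None:
            raise ValueError(f"malformed template {spec!r} at position {pos + 1}")
        if m.group(1) is not None:
            unit, count_s = m.group(1), m.group(2)
        else:
            unit, count_s = m.group(3), m.group(4)
        for i, aa in enumerate(unit):
            if aa not in ALPHABET_SET:
                raise ValueError(
                    f"non-alphabet symbol {aa!r} in template at position "
                    f"{m.start() + (0 if m.group(1) else 1) + i + 1}"
                )
        count = int(count_s) if count_s else 1
        if count < 1:
            raise ValueError(f"block count must be >= 1 at position {pos + 1}")
        blocks.append((unit, count))
        pos = m.end()
    if not blocks:
        raise ValueError("empty template")
    return blocks


def build_from_template(spec: str) -> str:
    """Expand a template grammar string into a peptide sequence.

    Examples: "A1" -> "A"; "GK2[LA]7LK2A" -> the 21-residue KALP21 peptide
    with a contiguous hydrophobic L/A core of 15 residues.
    """
    return "".join(unit * count for unit, count in parse_template(spec))


def block_scan_member(x: int) -> str:
    """A member of the hydrophobic block-length scan family, total length 20.

    Returns D2 K_k L_x K_k D2 with k = 8 - x/2 so that every family member is
    exactly 20 residues long, with equal lysine flanks around a poly-leucine
    core of length x (x even, 0 <= x <= 16).
    """
    if x % 2 != 0:
        raise ValueError(f"hydrophobic block length x must be even, got {x}")
    if not 0 <= x <= 16:
        raise ValueError(f"x must be in 0..16 to keep 20 residues, got {x}")
    k = 8 - x // 2
    return "DD" + "K" * k + "L" * x + "K" * k + "DD"


# Reference peptides used throughout the package.
KALP21 = "GK2[LA]7LK2A"
L10 = "D3K3L10K3D3"
L11 = "D3K3L11K3D3"


def hydrophobic_core_length(sequence: str, core_residues: str = "LAVIGMFWC") -> int:
    """Length of the longest contiguous run of core (hydrophobic) residues."""
    best = run = 0
    core = set(core_residues)
    for aa in sequence:
        run = run + 1 if aa in core else 0
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# FASTA / TSV I/O

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs; rejects duplicates/empties."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    seen: dict[str, int] = {}
    dups = []
    for rid, _ in records:
        seen[rid] = seen.get(rid, 0) + 1
        if seen[rid] == 2:
            dups.append(rid)
    if dups:
        raise ValueError(f"duplicate FASTA ids: {', '.join(dups)}")
    empty = [rid for rid, seq in records if not seq]
    if empty:
        raise ValueError(f"empty sequence for ids: {', '.join(empty)}")
    return records


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA, 60-column wrapped."""
    seqrecords = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_sequence_tsv(path) -> list[tuple[str, str]]:
    """Read a TSV sequence list with header ``id<TAB>sequence``."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        if header[:2] != ["id", "sequence"]:
            raise ValueError(f"expected header 'id\\tsequence', got {header}")
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed TSV line: {line!r}")
            records.append((fields[0], fields[1].upper()))
    return records


def write_sequence_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\n")
        for rid, seq in records:
            fh.write(f"{rid}\t{seq}\n")
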