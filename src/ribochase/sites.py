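"""RNase E cleavage-signature scanning and RNA 3'-end clustering.

RNase E prefers single-stranded AU-rich RNA.  Two positional rules
summarise its cleavage signature around a scissile phosphodiester bond:
a uridine two nucleotides downstream of the bond (+2U) and an adenine
three or four nucleotides upstream (-3/4A).

Coordinate convention (stated here once, used everywhere): positions are
1-based with the transcription start site at +1.  A bond index b names
the phosphodiester bond between residues b and b+1.  "+2" is the second
nucleotide downstream of the bond, i.e. residue b+2; "-3"/"-4" are the
third/fourth nucleotides upstream, i.e. residues b-2 and b-3.  BED
output converts to 0-based half-open intervals; internal coordinates
stay 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGU")


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with TSS = position 1; T is accepted and read as U."""

    id: str
    residues: str

    @classmethod
    def from_string(cls, residues: str, id: str = "rna") -> "RnaSequence":
        seq = residues.upper().replace("T", "U")
        if not seq:
            raise ValueError("empty sequence")
        for i, ch in enumerate(seq, start=1):
            if ch not in _VALID:
                raise ValueError(f"invalid residue {ch!r} at position {i} of {id!r}")
        return cls(id=id, residues=seq)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> str:
        """1-based residue access."""
        return self.residues[pos - 1]


@dataclass(frozen=True)
class CleavageSiteCall:
    """A candidate scissile bond and which rules it satisfies."""

    bond: int
    plus2_u: bool
    minus34_a: bool

    @property
    def both(self) -> bool:
        return self.plus2_u and self.minus34_a

    @property
    def n_rules(self) -> int:
        return int(self.plus2_u) + int(self.minus34_a)


@dataclass(frozen=True)
class EndCluster:
    """A run of clustered RNA 3'-end positions (1-based, inclusive)."""

    start: int
    end: int
    count: int


def scan_cleavage_sites(seq: RnaSequence | str) -> list[CleavageSiteCall]:
    """Scan every eligible bond for the +2U and -3/4A rules.

    Bonds b with b-2 >= 1 and b+2 <= length are scanned (so both the +2
    and at least the -3 context exist; the -4 position is checked only
    where it exists).  Bonds matching neither rule are omitted.  Output
    order: both-rule hits first, each group by position.
    """
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    n = len(seq)
    if n < 5:
        raise ValueError("sequence too short to scan (need >= 5 residues)")
    calls = []
    for b in range(3, n - 1):
        plus2 = seq.residue(b + 2) == "U"
        minus34 = seq.residue(b - 2) == "A" or (b - 3 >= 1 and seq.residue(b - 3) == "A")
        if plus2 or minus34:
            calls.append(CleavageSiteCall(bond=b, plus2_u=plus2, minus34_a=minus34))
    calls.sort(key=lambda c: (not c.both, c.bond))
    return calls


def find_u_tracts(seq: RnaSequence | str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal runs of >= ``min_len`` consecutive U, 1-based inclusive.

    The default of six matches the minimal uridine stretch acting as an
    RNase E entry site in the 5' UTR studied here.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(seq, str):
        seq = RnaSequence.from_string(seq)
    return [
        (m.start() + 1, m.end())
        for m in re.finditer(f"U{{{min_len},}}", seq.residues)
    ]


def cluster_end_positions(
    positions: Iterable[int], max_gap: int = 10
) -> list[EndCluster]:
    """Greedy single-linkage clustering of mapped 3'-end positions.

    Positions are sorted; a cluster extends while the next position lies
    within ``max_gap`` nt of the cluster's current maximum.  The default
    gap of 10 nt resolves end maps like the two regions 78-90 and
    214-229 nt downstream of a TSS into exactly two clusters.
    """
    pos = sorted(int(p) for p in positions)
    if not pos:
        raise ValueError("no positions given")
    if pos[0] <= 0:
        raise ValueError(f"positions must be positive, got {pos[0]}")
    clusters = []
    start = end = pos[0]
    count = 1
    for p in pos[1:]:
        if p - end <= max_gap:
            end = p
            count += 1
        else:
            clusters.append(EndCluster(start, end, count))
            start = end = p
            count = 1
    clusters.append(EndCluster(start, end, count))
    return clusters


# ---------------------------------------------------------------------------
# file formats


def read_fasta(path) -> list[RnaSequence]:
    """Read a (possibly multi-record) FASTA; T/U tolerant."""
    records = [
        RnaSequence.from_string(str(rec.seq), id=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: Sequence[RnaSequence], path) -> None:
    """Write FASTA wrapped at 70 columns."""
    recs = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


def write_bed(calls: Sequence[CleavageSiteCall], seq_id: str, path) -> None:
    """Write site calls as BED6 (0-based half-open, per BED convention).

    Each bond is represented by the 2-nt interval covering its two
    flanking residues: bond b -> [b-1, b+1).  name is the matched rule
    set, score the number of matched rules.
    """
    with open(path, "w") as fh:
        for c in calls:
            name = "both" if c.both else ("plus2U" if c.plus2_u else "minus34A")
            fh.write(f"{seq_id}\t{c.bond - 1}\t{c.bond + 1}\t{name}\t{c.n_rules}\t+\n")


def read_positions(path) -> list[int]:
    """Read a plain-text list of integer positions, one per line."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            out.append(int(line))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: not an integer: {line!r}") from exc
    return out
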