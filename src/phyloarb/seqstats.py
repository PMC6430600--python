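"""Alignment concatenation, column filtering, and G/C content.

Supermatrix plumbing for marker-based phylogenetics: per-gene alignments
are concatenated over a shared taxon universe (taxa missing a fragment
are gap-padded across it), noisy columns are removed by explicit
gap-fraction / consensus thresholds, and per-taxon G/C content is pooled
over amplified coding fragments. Column coordinates are 0-based
half-open throughout. '-' is a gap; 'X' and 'N' are unknown residues;
both are excluded from consensus and base counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "concatenate", "filter_columns", "gc_content"]

GAP = "-"
UNKNOWN = {"X", "N"}


@dataclass
class Alignment:
    """Equal-length gap-padded sequences keyed by taxon, with the column
    interval of every source fragment recorded for concatenated data."""

    records: dict[str, str]
    fragments: list[tuple[str, int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.records = {t: s.upper() for t, s in self.records.items()}
        if not self.fragments and self.records:
            self.fragments = [(self.name or "all", 0, self.length)]

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values()))) if self.records else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.records)

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.records.values())

    @classmethod
    def from_fasta(cls, path, name: str = "") -> "Alignment":
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate taxon {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq)
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(records, name=name or str(path))

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(seq), id=taxon, description="")
                for taxon, seq in self.records.items()]
        SeqIO.write(recs, str(path), "fasta")


def concatenate(alignments: Sequence[Alignment],
                taxa: Sequence[str] | None = None) -> Alignment:
    """Concatenate fragment alignments into a supermatrix.

    ``taxa`` fixes the row universe (default: union in first-seen order);
    a taxon absent from a fragment gets gaps across that fragment's span.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if taxa is None:
        seen: dict[str, None] = {}
        for aln in alignments:
            for t in aln.taxa:
                seen.setdefault(t)
        taxa = list(seen)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    fragments: list[tuple[str, int, int]] = []
    offset = 0
    for k, aln in enumerate(alignments):
        span = aln.length
        fragments.append((aln.name or f"fragment{k}", offset, offset + span))
        for t in taxa:
            parts[t].append(aln.records.get(t, GAP * span))
        offset += span
    return Alignment({t: "".join(p) for t, p in parts.items()}, fragments,
                     name="+".join(a.name or f"fragment{k}" for k, a in enumerate(alignments)))


def filter_columns(alignment: Alignment, max_gap_fraction: float = 0.2,
                   min_consensus_fraction: float = 0.0) -> Alignment:
    """Drop columns with too many gaps or too weak a consensus.

    A column survives when its gap fraction is <= ``max_gap_fraction``
    and the modal residue (among non-gap, non-unknown characters) makes
    up >= ``min_consensus_fraction`` of those characters. Column order is
    preserved and fragment boundaries are remapped. Idempotent at fixed
    thresholds.
    """
    for thr in (max_gap_fraction, min_consensus_fraction):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    n = len(alignment.records)
    keep: list[int] = []
    for i in range(alignment.length):
        col = alignment.column(i)
        gaps = col.count(GAP)
        if gaps / n > max_gap_fraction:
            continue
        residues = [c for c in col if c != GAP and c not in UNKNOWN]
        if residues:
            modal = Counter(residues).most_common(1)[0][1]
            if modal / len(residues) < min_consensus_fraction:
                continue
        elif min_consensus_fraction > 0:
            continue
        keep.append(i)
    new_records = {t: "".join(seq[i] for i in keep) for t, seq in alignment.records.items()}
    # remap fragment boundaries onto the retained-column coordinate system
    new_fragments: list[tuple[str, int, int]] = []
    kept_before = 0
    keep_set = set(keep)
    for name, start, end in alignment.fragments:
        width = sum(1 for i in range(start, end) if i in keep_set)
        new_fragments.append((name, kept_before, kept_before + width))
        kept_before += width
    return Alignment(new_records, new_fragments, name=alignment.name)


def gc_content(sequences: str | Iterable[str]) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T) pooled over one taxon's
    fragments; gaps, N, and any non-ACGT characters are excluded."""
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = Counter()
    for seq in sequences:
        counts.update(seq.upper())
    gc = counts["G"] + counts["C"]
    total = gc + counts["A"] + counts["T"]
    if total == 0:
        raise ValueError("no A/C/G/T bases to count")
    return gc / total
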