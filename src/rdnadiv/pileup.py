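"""Strand-split allele pileups over the rDNA unit.

A :class:`PileupMatrix` is the in-memory stand-in for an aligned read stack:
per-position counts of each observed allele, split by strand. Single-base
alleles live in a dense (L, 4, 2) array over (position, base A/C/G/T, strand
forward/reverse); indel alleles, which are sparse, live in a mapping keyed by
the left-anchored (position, ref, alt) allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, FormatError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupMatrix:
    isolate_id: str
    reference: str  # prototype sequence the reads were stacked against
    base_counts: np.ndarray  # int64 (L, 4, 2): position x base x (fwd, rev)
    indel_counts: dict[tuple[int, str, str], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.reference)
        if self.base_counts.shape != (L, 4, 2):
            raise DataError(
                f"base_counts shape {self.base_counts.shape} != ({L}, 4, 2)"
            )
        if (self.base_counts < 0).any() or any(
            f < 0 or r < 0 for f, r in self.indel_counts.values()
        ):
            raise DataError("negative allele counts")

    @property
    def length(self) -> int:
        return len(self.reference)

    def depths(self) -> np.ndarray:
        """Total read depth per position (base-call reads plus indel reads)."""
        depth = self.base_counts.sum(axis=(1, 2))
        for (pos, _ref, _alt), (f, r) in self.indel_counts.items():
            depth[pos - 1] += f + r
        return depth

    def base_count(self, position: int, base: str) -> tuple[int, int]:
        """(forward, reverse) counts of a base at a 1-based position."""
        f, r = self.base_counts[position - 1, BASE_INDEX[base]]
        return int(f), int(r)

    # -- TSV serialization (position, allele, strand, count) ------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tref\talt\tstrand\tcount\n")
            nz = np.argwhere(self.base_counts > 0)
            for pos0, b, s in nz:
                fh.write(
                    f"{pos0 + 1}\t{self.reference[pos0]}\t{BASES[b]}\t"
                    f"{'+' if s == 0 else '-'}\t{self.base_counts[pos0, b, s]}\n"
                )
            for (pos, ref, alt), (f, r) in sorted(self.indel_counts.items()):
                if f:
                    fh.write(f"{pos}\t{ref}\t{alt}\t+\t{f}\n")
                if r:
                    fh.write(f"{pos}\t{ref}\t{alt}\t-\t{r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str, isolate_id: str) -> "PileupMatrix":
        base_counts = np.zeros((len(reference), 4, 2), dtype=np.int64)
        indel_counts: dict[tuple[int, str, str], list[int]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["position", "ref", "alt", "strand", "count"]:
                raise FormatError(f"unexpected pileup TSV header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                pos, ref, alt, strand, count = line.rstrip("\n").split("\t")
                s = 0 if strand == "+" else 1
                if len(ref) == 1 and len(alt) == 1:
                    base_counts[int(pos) - 1, BASE_INDEX[alt], s] += int(count)
                else:
                    key = (int(pos), ref, alt)
                    indel_counts.setdefault(key, [0, 0])[s] += int(count)
        return cls(
            isolate_id=isolate_id,
            reference=reference,
            base_counts=base_counts,
            indel_counts={k: (f, r) for k, (f, r) in indel_counts.items()},
        )
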