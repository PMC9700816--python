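"""The rDNA unit prototype: sequence, element annotation, coordinate conventions.

The *S. cerevisiae* rDNA locus is a tandem array of ~9.1 kb units, each unit
carrying the four rRNA genes (5S, 5.8S, 18S, 25S), the external and internal
transcribed spacers (ETS1/2, ITS1/2) and two non-transcribed spacers (NTS1/2).
Every module in this package works in 1-based inclusive coordinates on a single
rearranged prototype unit in which the NTS region precedes the 35S transcription
unit. BED input follows the BED standard (0-based, half-open) and is converted
on load. Variant positions inside the rRNA genes can additionally be expressed
in gene-local coordinates (e.g. "25S position 1248"), the convention used by
rRNA nomenclature and by structural annotations.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, CoordinateError, FormatError

ELEMENT_LABELS = frozenset(
    {"NTS1", "NTS2", "ETS1", "ETS2", "ITS1", "ITS2", "5S", "5.8S", "18S", "25S"}
)
RRNA_GENES = ("5S", "5.8S", "18S", "25S")
#: sentinel returned by :meth:`RDNAPrototype.element_of` for positions outside
#: every annotated interval
UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class ElementInterval:
    """One annotated element, 1-based inclusive."""

    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class RDNAPrototype:
    """A validated rDNA unit: sequence plus non-overlapping element intervals."""

    sequence: str
    elements: list[ElementInterval]
    name: str = "rDNA"
    _starts: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise FormatError(f"prototype sequence contains non-ACGT symbols: {bad}")
        labels = [e.label for e in self.elements]
        unknown = set(labels) - ELEMENT_LABELS
        if unknown:
            raise AnnotationError(f"unknown element labels: {sorted(unknown)}")
        if len(labels) != len(set(labels)):
            raise AnnotationError("duplicate element labels in annotation")
        self.elements = sorted(self.elements, key=lambda e: e.start)
        prev_end = 0
        for e in self.elements:
            if e.start < 1 or e.end > self.unit_length or e.start > e.end:
                raise AnnotationError(
                    f"element {e.label} [{e.start},{e.end}] outside unit "
                    f"[1,{self.unit_length}]"
                )
            if e.start <= prev_end:
                raise AnnotationError(f"element {e.label} overlaps the previous interval")
            prev_end = e.end
        self._starts = [e.start for e in self.elements]

    @property
    def unit_length(self) -> int:
        return len(self.sequence)

    # -- element / gene coordinates -------------------------------------------------

    def _interval_at(self, position: int) -> ElementInterval | None:
        if not 1 <= position <= self.unit_length:
            raise CoordinateError(
                f"position {position} outside unit [1,{self.unit_length}]"
            )
        i = bisect.bisect_right(self._starts, position) - 1
        if i >= 0 and position in self.elements[i]:
            return self.elements[i]
        return None

    def element_of(self, position: int) -> str:
        """Label of the element containing ``position``, or ``"unannotated"``."""
        iv = self._interval_at(position)
        return iv.label if iv is not None else UNANNOTATED

    def element_interval(self, label: str) -> ElementInterval:
        for e in self.elements:
            if e.label == label:
                return e
        raise AnnotationError(f"element {label!r} not annotated")

    def gene_length(self, gene: str) -> int:
        if gene not in RRNA_GENES:
            raise CoordinateError(f"{gene!r} is not an rRNA gene")
        return self.element_interval(gene).length

    def to_gene_coordinate(self, position: int) -> tuple[str, int]:
        """Convert a unit position inside an rRNA gene to (gene, local 1-based)."""
        iv = self._interval_at(position)
        if iv is None or iv.label not in RRNA_GENES:
            raise CoordinateError(
                f"position {position} is not inside an rRNA gene "
                f"(element: {iv.label if iv else UNANNOTATED})"
            )
        return iv.label, position - iv.start + 1

    def from_gene_coordinate(self, gene: str, local_position: int) -> int:
        """Inverse of :meth:`to_gene_coordinate`."""
        iv = self.element_interval(gene)
        if gene not in RRNA_GENES:
            raise CoordinateError(f"{gene!r} is not an rRNA gene")
        if not 1 <= local_position <= iv.length:
            raise CoordinateError(
                f"{gene} local position {local_position} outside [1,{iv.length}]"
            )
        return iv.start + local_position - 1

    # -- sequence context -----------------------------------------------------------

    def homopolymer_run(self, position: int) -> int:
        """Length of the maximal single-base run containing ``position``."""
        return homopolymer_run(self.sequence, position)

    def poly_stretch_positions(self, min_len: int = 10) -> frozenset[int]:
        """Positions inside any single-base stretch of at least ``min_len`` nt."""
        return _poly_stretch_positions(self.sequence, min_len)


# -- plain-string sequence helpers (also used on pileup reference strings) ----------


def homopolymer_run(sequence: str, position: int) -> int:
    """Maximal run of identical bases containing 1-based ``position``."""
    if not 1 <= position <= len(sequence):
        raise CoordinateError(f"position {position} outside sequence")
    i = position - 1
    base = sequence[i]
    lo = i
    while lo > 0 and sequence[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < len(sequence) and sequence[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def indel_homopolymer_run(sequence: str, anchor_position: int) -> int:
    """Run length immediately 3' of a left-anchored indel's anchor base.

    Mirrors the HRUN convention of low-frequency callers: the run of identical
    bases starting at the base after the anchor.
    """
    if anchor_position >= len(sequence):
        return 0
    return homopolymer_run(sequence, anchor_position + 1)


@lru_cache(maxsize=8)
def _poly_stretch_positions(sequence: str, min_len: int) -> frozenset[int]:
    out: set[int] = set()
    i = 0
    n = len(sequence)
    while i < n:
        j = i
        while j + 1 < n and sequence[j + 1] == sequence[i]:
            j += 1
        if j - i + 1 >= min_len:
            out.update(range(i + 1, j + 2))  # 1-based inclusive
        i = j + 1
    return frozenset(out)


# -- FASTA/BED I/O ------------------------------------------------------------------


def load_prototype(fasta_path: str | Path, bed_path: str | Path) -> RDNAPrototype:
    """Load the prototype from a single-record FASTA and a BED element annotation.

    BED intervals (0-based, half-open) are converted to the package's 1-based
    inclusive convention; validation of overlap, range and label uniqueness
    happens in :class:`RDNAPrototype`.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(
            f"prototype FASTA must contain exactly one record, found {len(records)}"
        )
    rec = records[0]
    elements = []
    with open(bed_path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 4:
                raise FormatError(f"{bed_path}:{line_no}: BED line needs 4 columns")
            _, start, end, label = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{bed_path}:{line_no}: non-integer interval") from exc
            if end_i <= start_i:
                raise FormatError(f"{bed_path}:{line_no}: empty interval")
            elements.append(ElementInterval(label, start_i + 1, end_i))
    return RDNAPrototype(sequence=str(rec.seq), elements=elements, name=rec.id)


def write_prototype(
    prototype: RDNAPrototype, fasta_path: str | Path, bed_path: str | Path
) -> None:
    """Write the prototype back out as FASTA + BED (inverse of ``load_prototype``)."""
    rec = SeqRecord(Seq(prototype.sequence), id=prototype.name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(bed_path, "w") as fh:
        for e in prototype.elements:
            fh.write(f"{prototype.name}\t{e.start - 1}\t{e.end}\t{e.label}\n")
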