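"""Variant records and VCF 4.2 interchange.

A :class:`VariantCall` is one alternative sequence at one rDNA unit position in
one isolate, carrying its intragenomic variant frequency (iVF = fraction of the
isolate's rDNA reads supporting the alternative), read depth, per-strand
support and a phred-scaled strand-bias score. One (isolate, position, alt, iVF)
record is one iVFP. VCFs are read and written through pysam with the INFO keys
emitted by low-frequency callers: AF (float), DP (int), SB (phred int), HRUN
(int, indels) and DP4 (ref-fwd, ref-rev, alt-fwd, alt-rev).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import DataError, FormatError
from .prototype import RDNAPrototype

log = logging.getLogger(__name__)

CALL_TABLE_COLUMNS = [
    "isolate_id", "position", "ref", "alt", "ivf", "depth",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "sb_phred", "hrun", "element",
]


@dataclass(frozen=True)
class VariantCall:
    """One alternative sequence at one rDNA position in one isolate."""

    isolate_id: str
    position: int  # 1-based rDNA-unit coordinate
    ref_seq: str
    alt_seq: str
    ivf: float
    depth: int
    strand_counts: tuple[int, int, int, int] | None = None  # ref+, ref-, alt+, alt-
    sb_phred: float = 0.0
    hrun: int | None = None
    element: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ivf <= 1.0:
            raise DataError(f"iVF must be in (0,1], got {self.ivf}")
        if self.ref_seq == self.alt_seq:
            raise DataError("ref and alt sequences are identical")
        if self.sb_phred < 0:
            raise DataError("strand-bias score must be non-negative")
        if self.strand_counts is not None:
            _, _, alt_f, alt_r = self.strand_counts
            if alt_f + alt_r > self.depth:
                raise DataError("alt strand counts exceed depth")

    @property
    def is_indel(self) -> bool:
        return len(self.ref_seq) != 1 or len(self.alt_seq) != 1

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_seq) - len(self.alt_seq))

    def with_element(self, prototype: RDNAPrototype) -> "VariantCall":
        return replace(self, element=prototype.element_of(self.position))


# -- tabular view -------------------------------------------------------------------


def calls_to_table(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Flatten calls into the tabular form used by the analysis modules."""
    rows = []
    for c in calls:
        sc = c.strand_counts or (None, None, None, None)
        rows.append(
            (c.isolate_id, c.position, c.ref_seq, c.alt_seq, c.ivf, c.depth,
             sc[0], sc[1], sc[2], sc[3], c.sb_phred, c.hrun, c.element)
        )
    return pd.DataFrame(rows, columns=CALL_TABLE_COLUMNS)


def table_to_calls(table: pd.DataFrame) -> list[VariantCall]:
    calls = []
    for row in table.itertuples(index=False):
        sc = (row.ref_fwd, row.ref_rev, row.alt_fwd, row.alt_rev)
        strand_counts = None if any(pd.isna(v) for v in sc) else tuple(int(v) for v in sc)
        calls.append(
            VariantCall(
                isolate_id=row.isolate_id, position=int(row.position),
                ref_seq=row.ref, alt_seq=row.alt, ivf=float(row.ivf),
                depth=int(row.depth), strand_counts=strand_counts,
                sb_phred=float(row.sb_phred),
                hrun=None if pd.isna(row.hrun) else int(row.hrun),
                element=None if pd.isna(row.element) else row.element,
            )
        )
    return calls


# -- VCF I/O ------------------------------------------------------------------------


class _quiet_htslib:
    """Silence htslib header-sanity chatter: AF/SB numbering follows the
    LoFreq convention (Number=1), which newer htslib warns about."""

    def __enter__(self):
        self._old = pysam.set_verbosity(0)

    def __exit__(self, *exc):
        pysam.set_verbosity(self._old)


def _vcf_header(contig: str, contig_length: int, extra_meta: dict | None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(contig, length=contig_length)
    header.info.add("AF", 1, "Float", "Intragenomic variant frequency (alt reads / depth)")
    header.info.add("DP", 1, "Integer", "Read depth at the position")
    header.info.add("SB", 1, "Integer", "Phred-scaled strand-bias score (Fisher exact)")
    header.info.add("HRUN", 1, "Integer", "Reference homopolymer run length at the site")
    header.info.add("DP4", 4, "Integer", "ref-forward, ref-reverse, alt-forward, alt-reverse")
    for key, value in (extra_meta or {}).items():
        header.add_meta(key, value=str(value))
    return header


def write_variant_calls(
    calls: Sequence[VariantCall],
    vcf_path: str | Path,
    prototype: RDNAPrototype | None = None,
    contig: str | None = None,
    contig_length: int | None = None,
    meta: dict | None = None,
) -> None:
    """Write calls as a position-sorted plain-text VCF 4.2.

    Unsorted input is sorted, never an error. ``meta`` entries become
    ``##key=value`` header lines (used for filter/seed provenance).
    """
    if prototype is not None:
        contig, contig_length = prototype.name, prototype.unit_length
    if contig is None or contig_length is None:
        raise DataError("either a prototype or contig name+length is required")
    header = _vcf_header(contig, contig_length, meta)
    ordered = sorted(calls, key=lambda c: (c.position, c.ref_seq, c.alt_seq))
    with _quiet_htslib(), pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for c in ordered:
            rec = out.new_record(
                contig=contig, start=c.position - 1, stop=c.position - 1 + len(c.ref_seq),
                alleles=(c.ref_seq, c.alt_seq), filter="PASS",
            )
            rec.info["AF"] = float(c.ivf)
            rec.info["DP"] = int(c.depth)
            rec.info["SB"] = int(round(c.sb_phred))
            if c.hrun is not None:
                rec.info["HRUN"] = int(c.hrun)
            if c.strand_counts is not None:
                rec.info["DP4"] = tuple(int(v) for v in c.strand_counts)
            out.write(rec)


def read_variant_calls(
    vcf_path: str | Path,
    isolate_id: str,
    prototype: RDNAPrototype | None = None,
) -> list[VariantCall]:
    """Read one isolate's calls from a LoFreq-style VCF.

    One :class:`VariantCall` per ALT allele per record; multi-allelic records
    are split. Records missing AF or DP are skipped with a logged warning.
    """
    calls: list[VariantCall] = []
    try:
        with _quiet_htslib():
            vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vf:
        declared = set(vf.header.info.keys())  # .get raises on undeclared keys
        for rec in vf:
            if "AF" not in rec.info or "DP" not in rec.info:
                log.warning("%s:%s record lacks AF/DP, skipped", vcf_path, rec.pos)
                continue
            af = rec.info["AF"]
            afs = list(af) if isinstance(af, tuple) else [af] * len(rec.alts or ())
            depth = int(rec.info["DP"])
            sb = float(rec.info.get("SB", 0) or 0) if "SB" in declared else 0.0
            hrun = rec.info.get("HRUN") if "HRUN" in declared else None
            dp4 = rec.info.get("DP4") if "DP4" in declared else None
            strand_counts = tuple(int(v) for v in dp4) if dp4 is not None else None
            for alt, ivf in zip(rec.alts or (), afs):
                call = VariantCall(
                    isolate_id=isolate_id, position=rec.pos, ref_seq=rec.ref,
                    alt_seq=alt, ivf=float(ivf), depth=depth,
                    strand_counts=strand_counts, sb_phred=sb,
                    hrun=None if hrun is None else int(hrun),
                )
                calls.append(call.with_element(prototype) if prototype else call)
    return calls
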