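"""Parsing and 40-bit encoding of genomic variant records.

A queryable variant is reduced to five fields — chromosome, position, the
last character of REF, the last character of ALT, and whether the variant
is annotated as a SNP — and packed into a single 40-bit integer:

    chrom (5 bits) || pos (30 bits) || ref (2 bits) || alt (2 bits) || snp (1 bit)

with the chromosome in the most significant bits.  Nucleotide symbols are
coded ``{A: 0, C: 1, G: 2, T: 3, empty: 0}``; the ``{A, empty} -> 0``
collapse is the only information the encoding loses.  Substitution
(SVTYPE=SUB) and insertion (SVTYPE=INS) rows are dropped at parse time —
only SNPs are queryable and deletions are retained as non-SNP rows — which
is why a single trailing character of REF/ALT suffices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

__all__ = [
    "VariantRecord",
    "EncodedRecord",
    "VcfParseError",
    "parse_vcf",
    "parse_query_lines",
    "encode_record",
    "decode_record",
    "digits_base_b",
]

CHROM_CODES = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24}
_CODE_CHROM = {v: k for k, v in CHROM_CODES.items()}
SYMBOL_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "": 0}
_CODE_SYMBOL = {0: "A", 1: "C", 2: "G", 3: "T"}  # decoding collapses empty -> A

POS_BITS = 30
RECORD_BITS = 40


class VcfParseError(ValueError):
    """A VCF data line violates the expected schema."""


@dataclass(frozen=True)
class VariantRecord:
    """One retained variant row, reduced to the queryable fields."""

    chrom: str  # "1".."22", "X", "Y"
    pos: int  # as printed in the VCF (1-based), < 2^30
    ref_sym: str  # one of "A","C","G","T","" (empty)
    alt_sym: str
    is_snp: bool

    def __post_init__(self):
        if self.chrom not in CHROM_CODES:
            raise VcfParseError(f"CHROM {self.chrom!r} outside 1..22, X, Y")
        if not 0 <= self.pos < 2**POS_BITS:
            raise VcfParseError(f"POS {self.pos} does not fit in {POS_BITS} bits")
        for sym in (self.ref_sym, self.alt_sym):
            if sym not in SYMBOL_CODES:
                raise VcfParseError(f"symbol {sym!r} outside {{A,C,G,T,empty}}")


@dataclass(frozen=True)
class EncodedRecord:
    """The 40-bit packed form of a :class:`VariantRecord`."""

    value: int

    def __post_init__(self):
        if not 0 <= self.value < 2**RECORD_BITS:
            raise ValueError(f"encoded value {self.value} does not fit in 40 bits")


def _last_symbol(fld: str) -> str:
    """Last character of a REF/ALT field; empty for missing fields."""
    fld = fld.strip()
    if fld in ("", ".", "-"):
        return ""
    sym = fld[-1].upper()
    if sym not in ("A", "C", "G", "T"):
        raise VcfParseError(f"REF/ALT field {fld!r} ends in non-nucleotide {sym!r}")
    return sym


def _svtype(info: str) -> str | None:
    for kv in info.split(";"):
        if kv.startswith("SVTYPE="):
            return kv[len("SVTYPE="):]
    return None


def parse_vcf(stream: Iterable[str] | TextIO) -> list[VariantRecord]:
    """Parse VCF 4.2 text into retained variant records.

    Header lines (starting ``#``) are skipped.  Data lines must carry at
    least the eight mandatory tab-separated columns; SVTYPE is read from
    the INFO key-value list.  Rows annotated SVTYPE=SUB or SVTYPE=INS are
    dropped; all others (SNP, DEL, or unannotated) are retained, with
    ``is_snp`` true exactly for SVTYPE=SNP.
    """
    records: list[VariantRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise VcfParseError(
                f"line {lineno}: expected >= 8 tab-separated columns, got {len(cols)}"
            )
        chrom, pos_s, _id, ref, alt, _qual, _filter, info = cols[:8]
        svtype = _svtype(info)
        if svtype in ("SUB", "INS"):
            continue
        if chrom not in CHROM_CODES:
            raise VcfParseError(f"line {lineno}: CHROM {chrom!r} outside 1..22, X, Y")
        try:
            pos = int(pos_s)
        except ValueError:
            raise VcfParseError(f"line {lineno}: POS {pos_s!r} is not an integer") from None
        if not 0 <= pos < 2**POS_BITS:
            raise VcfParseError(f"line {lineno}: POS {pos} does not fit in 30 bits")
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref_sym=_last_symbol(ref),
                alt_sym=_last_symbol(alt),
                is_snp=(svtype == "SNP"),
            )
        )
    return records


def parse_query_lines(stream: Iterable[str] | TextIO) -> list[VariantRecord]:
    """Parse a plain-text query list: ``CHROM POS REF ALT`` per line.

    Queries are SNP lookups, so ``is_snp`` is set on every record.
    Blank lines and ``#`` comments are skipped.
    """
    out: list[VariantRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise VcfParseError(
                f"query line {lineno}: expected 'CHROM POS REF ALT', got {line!r}"
            )
        chrom, pos_s, ref, alt = parts
        out.append(
            VariantRecord(
                chrom=chrom,
                pos=int(pos_s),
                ref_sym=_last_symbol(ref),
                alt_sym=_last_symbol(alt),
                is_snp=True,
            )
        )
    return out


def encode_record(rec: VariantRecord) -> EncodedRecord:
    """Pack a variant record into its 40-bit integer."""
    value = (
        CHROM_CODES[rec.chrom] * 2**35
        + rec.pos * 2**5
        + SYMBOL_CODES[rec.ref_sym] * 2**3
        + SYMBOL_CODES[rec.alt_sym] * 2
        + int(rec.is_snp)
    )
    return EncodedRecord(value)


def decode_record(enc: EncodedRecord) -> VariantRecord:
    """Unpack a 40-bit value; the empty symbol decodes as 'A' (code collision)."""
    v = enc.value
    chrom_code = v >> 35
    if chrom_code not in _CODE_CHROM:
        raise ValueError(f"chromosome code {chrom_code} has no label")
    return VariantRecord(
        chrom=_CODE_CHROM[chrom_code],
        pos=(v >> 5) & (2**POS_BITS - 1),
        ref_sym=_CODE_SYMBOL[(v >> 3) & 3],
        alt_sym=_CODE_SYMBOL[(v >> 1) & 3],
        is_snp=bool(v & 1),
    )


def digits_base_b(x: int, b: int, count: int) -> list[int]:
    """Little-endian base-b digits of x, padded to exactly ``count`` digits."""
    if b < 2 or b & (b - 1):
        raise ValueError(f"base b={b} must be a power of two >= 2")
    if x < 0 or x >= b**count:
        raise ValueError(f"{x} does not fit in {count} base-{b} digits")
    digits = []
    for _ in range(count):
        digits.append(x % b)
        x //= b
    return digits
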