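"""Synthetic VCF fixtures with known ground truth, plus adversarial cases.

The generator emulates the input the protocol is built for: VCF 4.2 files
whose rows carry #CHROM in {1..22, X, Y}, POS below 2^30 (positions of at
most nine decimal digits fit here), single-nucleotide REF/ALT, and an
INFO SVTYPE tag drawn from {SNP, DEL, SUB, INS}.  A fixture also carries
a query list with planted hits (verbatim copies of dataset SNP rows) and
planted misses (SNP queries whose 40-bit encoding appears nowhere in the
dataset), together with the expected verdict for each — the ground truth
every end-to-end test is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vcf_codec import (
    CHROM_CODES,
    VariantRecord,
    encode_record,
)

__all__ = ["FixtureSpec", "Fixture", "gen_vcf", "gen_adversarial"]

_NUC = ["A", "C", "G", "T"]
_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of variant">\n'
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)

#: Default SVTYPE mix: mostly SNPs (the queryable rows), with deletions
#: retained by the parser and substitutions/insertions dropped by it.
DEFAULT_MIX = {"SNP": 0.70, "DEL": 0.10, "SUB": 0.10, "INS": 0.10}


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: row count, planted queries, SVTYPE mix, seed."""

    num_rows: int
    num_hits: int = 0
    num_misses: int = 0
    svtype_mix: dict = field(default_factory=lambda: dict(DEFAULT_MIX))
    seed: int = 0


@dataclass
class Fixture:
    """Generated artifacts: VCF text, query text, and the truth table."""

    vcf_text: str
    query_text: str
    truth: list[tuple[VariantRecord, str]]  # (query record, "MATCH"/"NO-MATCH")
    records: list[VariantRecord]  # retained rows, in file order (ground truth)


def _random_snp(rng: np.random.Generator, chroms: list[str]) -> VariantRecord:
    ref, alt = rng.choice(4, size=2, replace=False)
    return VariantRecord(
        chrom=chroms[rng.integers(len(chroms))],
        pos=int(rng.integers(1, 2**30)),
        ref_sym=_NUC[ref],
        alt_sym=_NUC[alt],
        is_snp=True,
    )


def _vcf_line(rec: VariantRecord, svtype: str) -> str:
    ref = rec.ref_sym or "."
    alt = rec.alt_sym or "."
    return f"{rec.chrom}\t{rec.pos}\t.\t{ref}\t{alt}\t100\tPASS\tSVTYPE={svtype}\n"


def gen_vcf(spec: FixtureSpec) -> Fixture:
    """Generate a VCF file, query list and ground-truth verdicts.

    Retained rows (SNP and DEL) are distinct after 40-bit encoding.
    Planted hits are verbatim SNP rows of the dataset; planted misses are
    SNP queries whose encoding collides with no retained row.  SUB and
    INS rows are present in the file but, being dropped by the parser,
    can never be matchable.
    """
    if spec.num_hits > spec.num_rows:
        raise ValueError("cannot plant more hits than rows")
    rng = np.random.default_rng(spec.seed)
    chroms = list(CHROM_CODES)
    types = list(spec.svtype_mix)
    probs = np.array([spec.svtype_mix[k] for k in types], dtype=float)
    probs = probs / probs.sum()

    lines: list[str] = []
    retained: list[VariantRecord] = []
    snp_rows: list[VariantRecord] = []
    seen: set[int] = set()
    # force enough SNP rows to host the planted hits
    forced_snps = spec.num_hits
    for row_idx in range(spec.num_rows):
        svtype = "SNP" if row_idx < forced_snps else types[
            rng.choice(len(types), p=probs)
        ]
        while True:
            base = _random_snp(rng, chroms)
            if svtype == "SNP":
                rec = base
            elif svtype == "DEL":
                rec = VariantRecord(base.chrom, base.pos, base.ref_sym, "", False)
            else:  # SUB / INS: dropped by the parser, fields arbitrary
                rec = VariantRecord(base.chrom, base.pos, base.ref_sym,
                                    base.alt_sym, False)
            if svtype in ("SUB", "INS"):
                break
            enc = encode_record(rec).value
            if enc not in seen:
                seen.add(enc)
                break
        lines.append(_vcf_line(rec, svtype))
        if svtype not in ("SUB", "INS"):
            retained.append(rec)
            if svtype == "SNP":
                snp_rows.append(rec)

    # planted queries
    truth: list[tuple[VariantRecord, str]] = []
    hit_rows = [snp_rows[i] for i in rng.choice(len(snp_rows), size=spec.num_hits,
                                                replace=False)] if spec.num_hits else []
    for rec in hit_rows:
        truth.append((rec, "MATCH"))
    for _ in range(spec.num_misses):
        while True:
            rec = _random_snp(rng, chroms)
            if encode_record(rec).value not in seen:
                break
        truth.append((rec, "NO-MATCH"))

    query_lines = [
        f"{q.chrom} {q.pos} {q.ref_sym or '.'} {q.alt_sym or '.'}\n"
        for q, _v in truth
    ]
    return Fixture(
        vcf_text=_VCF_HEADER + "".join(lines),
        query_text="".join(query_lines),
        truth=truth,
        records=retained,
    )


def gen_adversarial(kind: str, params) -> dict:
    """Construct a targeted toy instance for bound and uniqueness testing.

    ``wraparound``: a binary direct-mode instance where choosing t equal
    to the string length makes a maximally distant row sum to exactly t,
    wrapping to zero — a fabricated match that the modulus bound exists
    to prevent.  ``duplicate-stub``: two distinct records sharing the
    high bits (equal stubs, different bin offsets).  ``near-miss``: a
    dataset row plus a query at Hamming distance 1 from it.
    """
    if kind == "wraparound":
        ell = params.ell
        # query all-zeros, one row all-ones: sum of squared diffs == ell
        return {
            "t_unsafe": ell,
            "ell": ell,
            "row_bits": [1] * ell,
            "query_bits": [0] * ell,
        }
    if kind == "duplicate-stub":
        x = 0b1010 << params.ell_R  # shared stub, offsets 0 and 1
        return {"x": x, "y": x | 1}
    if kind == "near-miss":
        rng = np.random.default_rng(7)
        x = int(rng.integers(0, 2**params.ell))
        flip = int(rng.integers(0, params.ell))
        return {"row": x, "query": x ^ (1 << flip)}
    raise ValueError(f"unknown adversarial kind {kind!r}")
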