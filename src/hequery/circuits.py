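"""The three SIMD string-matching circuits: CAM, CMA, and CA.

A dataset of N strings of L digits is batched column-wise: batch i,
digit position j becomes one slot vector holding the j-th digit of rows
n(i-1)+1 .. ni.  A query is either replicated across all slots (direct
mode) or laid out as a hashed table whose bins align with the dataset's
bins (hashed mode).  The circuits are:

``CAM``  (compare-add-multiply):  prod_i  sum_j (D_ij - X_j)^2
    A zero in slot k means row n(i-1)+k matched in some batch i.  Depth
    1 + ceil(log2 B); requires t above the sum's maximum to prevent
    wrap-around false positives; primality of t makes the batch product
    safe without any further bound.

``CMA``  (compare-multiply-add):  sum_i  prod_j [1 - (D_ij - X_j)^2]
    Slot k counts the batches in which bin k matched; the slot sum is the
    total match count.  Depth 1 + ceil(log2 L); only needs t > B.  In
    hashed mode, multiplicative 0/1 masks invalidate empty bins.

``CA``   (compare-add, single batch):  sum_j (D_j - X_j)^2
    Slot k holds the Hamming distance (binary digits) between the query
    and row k.  Depth 1; needs t > L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import params as _params
from .cuckoo import CuckooTable, PackedMultiquery, fill_sentinels
from .simd_backend import (
    OpLedger,
    ProtocolParams,
    SlotVector,
    balanced_product,
    sv_mul,
    sv_plain_rsub,
    sv_square,
    sv_sub,
    sv_add,
)

__all__ = [
    "BatchedDataset",
    "BatchedQuery",
    "MatchResult",
    "BoundViolation",
    "cam_eval",
    "cam_decode",
    "cma_eval",
    "ca_eval",
    "layout_direct",
    "layout_query_direct",
    "layout_hashed_dataset",
    "layout_hashed_query",
]

PAD_SENTINEL_ROLE = "dataset"  # padding rows reuse the dataset-side sentinel


class BoundViolation(ValueError):
    """The plaintext modulus does not exceed the circuit's wrap-around bound."""


@dataclass
class BatchedDataset:
    """B x L matrix of slot vectors, plus mode and optional CMA masks."""

    data: list[list[SlotVector]]  # [batch][digit position]
    mode: str  # "direct" | "hashed"
    params: ProtocolParams
    masks: list[SlotVector] | None = None  # one 0/1 vector per batch (CMA)

    @property
    def B(self) -> int:
        return len(self.data)

    @property
    def L(self) -> int:
        return len(self.data[0])


@dataclass
class BatchedQuery:
    """B_X x L matrix of slot vectors with optional mask and placement."""

    data: list[list[SlotVector]]
    mode: str
    params: ProtocolParams
    masks: list[SlotVector] | None = None  # one per table (CMA)
    placement: dict[tuple[int, int], tuple[int, int]] | None = None
    k: int = 1

    @property
    def B_X(self) -> int:
        return len(self.data)


@dataclass
class MatchResult:
    """Decoded outcome of a query evaluation."""

    verdicts: list[str]  # per query: "MATCH" | "NO-MATCH"
    match_count: int | None = None  # zero count (hashed CAM) / slot sum (CMA)
    distances: np.ndarray | None = None  # per-slot Hamming distances (CA)


def _require_t(params: ProtocolParams, circuit: str, L: int, B: int) -> None:
    ell_bits = params.ell_L if circuit == "cam-hashed" else params.ell
    bound = _params.t_bound(circuit, ell_bits=ell_bits, b=params.b, B=B)
    if params.t <= bound:
        raise BoundViolation(
            f"t={params.t} must exceed the {circuit} bound {bound}; "
            "refusing to evaluate (wrap-around can fabricate matches)"
        )


def cam_eval(
    ds: BatchedDataset,
    q: Sequence[SlotVector],
    ledger: OpLedger | None = None,
) -> SlotVector:
    """Evaluate CAM of one query row against all B batches.

    Consumes exactly (2L-1)B additions, LB squarings and B-1
    multiplications, at depth 1 + ceil(log2 B) over fresh inputs.
    """
    circuit = "cam-hashed" if ds.mode == "hashed" else "cam-direct"
    _require_t(ds.params, circuit, ds.L, ds.B)
    if len(q) != ds.L:
        raise ValueError(f"query has {len(q)} positions, dataset rows have {ds.L}")
    batch_sums = []
    for row in ds.data:
        acc = None
        for j in range(ds.L):
            sq = sv_square(sv_sub(row[j], q[j], ledger), ledger)
            acc = sq if acc is None else sv_add(acc, sq, ledger)
        batch_sums.append(acc)
    return balanced_product(batch_sums, ledger)


def cam_decode(
    results: SlotVector | list[SlotVector],
    placement: dict[tuple[int, int], tuple[int, int]] | None,
    mode: str,
    k: int = 1,
) -> MatchResult:
    """Decode CAM output slots into per-query verdicts.

    Hashed mode: query q matched iff one of its placed bins holds a zero;
    the zero count over placed bins is the exact match count (dataset
    rows are distinct, so a query can produce at most one zero).  A zero
    at a bin outside the placement map cannot arise with correct
    sentinels and is reported as an integrity error.  Direct mode: MATCH
    iff any slot is zero.
    """
    if isinstance(results, SlotVector):
        results = [results]
    if mode == "direct":
        any_zero = any(bool(np.any(r.slots == 0)) for r in results)
        return MatchResult(verdicts=["MATCH" if any_zero else "NO-MATCH"])
    if placement is None:
        raise ValueError("hashed-mode decoding requires a placement map")
    placed_bins = {v for v in placement.values()}
    zeros = set()
    for tbl_idx, r in enumerate(results):
        for s in np.flatnonzero(r.slots == 0):
            if (tbl_idx, int(s)) not in placed_bins:
                raise RuntimeError(
                    f"integrity error: zero slot at unplaced bin "
                    f"(table {tbl_idx}, bin {int(s)})"
                )
            zeros.add((tbl_idx, int(s)))
    hits = {q_idx for (q_idx, _i), bin_ref in placement.items() if bin_ref in zeros}
    verdicts = ["MATCH" if q_idx in hits else "NO-MATCH" for q_idx in range(k)]
    return MatchResult(verdicts=verdicts, match_count=len(zeros))


def cma_eval(
    ds: BatchedDataset,
    q: Sequence[SlotVector],
    q_mask: SlotVector | None = None,
    ledger: OpLedger | None = None,
) -> SlotVector:
    """Evaluate CMA (masked in hashed mode) of one query row.

    Unmasked cost: (L+1)B - 1 additions, LB squarings, (L-1)B
    multiplications, depth 1 + ceil(log2 L).  The plain ``1 - x`` steps
    are free.  In hashed mode each batch product is multiplied by the
    dataset's 0/1 mask and the final sum by the query's mask (B + 1 extra
    multiplications, two extra levels of depth); the masks zero every bin
    that is empty on either side, which is how empty bins are invalidated
    here instead of by arithmetic sentinels.
    """
    if ds.params.b != 2:
        raise ValueError("CMA compares binary digit strings only (b=2); "
                         "the larger-base optimization does not apply")
    _require_t(ds.params, "cma", ds.L, ds.B)
    if ds.mode == "hashed" and (ds.masks is None or q_mask is None):
        raise ValueError("hashed-mode CMA requires dataset and query masks")
    if len(q) != ds.L:
        raise ValueError(f"query has {len(q)} positions, dataset rows have {ds.L}")
    acc = None
    for b_idx, row in enumerate(ds.data):
        terms = [
            sv_plain_rsub(1, sv_square(sv_sub(row[j], q[j], ledger), ledger))
            for j in range(ds.L)
        ]
        prod = balanced_product(terms, ledger)
        if ds.masks is not None:
            prod = sv_mul(prod, ds.masks[b_idx], ledger)
        acc = prod if acc is None else sv_add(acc, prod, ledger)
    if q_mask is not None:
        acc = sv_mul(acc, q_mask, ledger)
    return acc


def ca_eval(
    ds: BatchedDataset,
    q: Sequence[SlotVector],
    ledger: OpLedger | None = None,
) -> SlotVector:
    """Evaluate CA: per-slot Hamming distance, single batch, binary digits."""
    if ds.B != 1:
        raise ValueError(f"CA requires batch count B=1, got B={ds.B}")
    if ds.params.b != 2:
        raise ValueError("CA distances are Hamming distances over bits (b=2)")
    _require_t(ds.params, "ca", ds.L, 1)
    row = ds.data[0]
    acc = None
    for j in range(ds.L):
        sq = sv_square(sv_sub(row[j], q[j], ledger), ledger)
        acc = sq if acc is None else sv_add(acc, sq, ledger)
    return acc


# ---------------------------------------------------------------------------
# layouts


def layout_direct(rows: np.ndarray, params: ProtocolParams) -> BatchedDataset:
    """Column-major batching of an N x L digit matrix (direct mode).

    Rows are padded up to a multiple of n with the digit value ``b`` — an
    impossible digit on the dataset side — so a padding row can never
    equal any valid query.
    """
    rows = np.asarray(rows, dtype=np.int64)
    N, L = rows.shape
    n = params.n
    B = max(1, math.ceil(N / n))
    padded = np.full((B * n, L), params.b, dtype=np.int64)
    padded[:N] = rows
    data = [
        [SlotVector.encrypt(padded[i * n : (i + 1) * n, j], params.t) for j in range(L)]
        for i in range(B)
    ]
    return BatchedDataset(data=data, mode="direct", params=params)


def layout_query_direct(digits: Sequence[int], params: ProtocolParams) -> list[SlotVector]:
    """Replicate query digits across all slots (constant polynomials)."""
    return [
        SlotVector.encrypt(np.full(params.n, dig, dtype=np.int64), params.t)
        for dig in digits
    ]


def layout_hashed_dataset(
    tables: list[CuckooTable],
    params: ProtocolParams,
    with_masks: bool = False,
    optimized: bool = False,
) -> BatchedDataset:
    """Digitize hashed dataset tables into B x ell_Lb slot vectors."""
    data = []
    masks: list[SlotVector] | None = [] if with_masks else None
    for tbl in tables:
        digits = fill_sentinels(tbl, "dataset", params, optimized=optimized)
        data.append(
            [SlotVector.encrypt(digits[:, j], params.t) for j in range(params.ell_Lb)]
        )
        if masks is not None:
            masks.append(SlotVector.encrypt(tbl.occupied().astype(np.int64), params.t))
    return BatchedDataset(data=data, mode="hashed", params=params, masks=masks)


def layout_hashed_query(
    packed: PackedMultiquery,
    params: ProtocolParams,
    with_masks: bool = False,
    optimized: bool = False,
) -> BatchedQuery:
    """Digitize B_X packed query tables into slot vectors."""
    data = []
    masks: list[SlotVector] | None = [] if with_masks else None
    for tbl in packed.tables:
        digits = fill_sentinels(tbl, "query", params, optimized=optimized)
        data.append(
            [SlotVector.encrypt(digits[:, j], params.t) for j in range(params.ell_Lb)]
        )
        if masks is not None:
            masks.append(SlotVector.encrypt(tbl.occupied().astype(np.int64), params.t))
    return BatchedQuery(
        data=data,
        mode="hashed",
        params=params,
        masks=masks,
        placement=packed.placement,
        k=packed.k,
    )
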