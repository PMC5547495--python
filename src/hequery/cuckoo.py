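"""Permutation-based d-cuckoo hashing of records and queries.

A 40-bit record ``X`` is split as ``X = X_L || X_R`` with ``X_R`` the low
``ell_R`` bits.  Hash function i maps it to bin

    Loc_i(X) = i * 2**ell_R + (H_i(X_L) XOR X_R),

so the low bits of the record and the hash-function index are both
absorbed into the *bin index*, and only the ``ell_L``-bit stub ``X_L`` is
stored.  Two distinct records can never produce the same stub in the same
bin: equal bins force ``H_i(X_L) XOR X_R = H_i(Y_L) XOR Y_R`` with the
same i, so equal stubs force ``X_R = Y_R`` and hence ``X = Y``.  This is
what lets the matching circuits compare only ``ell_L`` bits per bin.

Datasets are inserted with the random-walk method (evict-and-relocate
under a freshly chosen alternative hash function); a query populates all
d of its candidate bins, since the client cannot know which one the
dataset insertion settled on.  Multiqueries share tables: the packing
assigns each (query, hash index) location to the first table whose bin is
free, and always emits the pre-announced number of tables ``B_X`` so the
message size reveals nothing about collisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .simd_backend import ProtocolParams

__all__ = [
    "EMPTY",
    "HashSeeds",
    "CuckooTable",
    "PackedMultiquery",
    "HashingFailure",
    "PackingFailure",
    "loc",
    "insert_batch",
    "hash_dataset",
    "hash_query",
    "pack_multiquery",
    "fill_sentinels",
]

EMPTY = -1  # bin marker; stored stubs are >= 0

#: Random-walk step budget per inserted batch, as a multiple of the batch
#: size.  Far above anything reachable at validated expansion factors, so
#: hitting it signals a genuine hashing failure rather than slow mixing.
WALK_CAP_FACTOR = 100


class HashingFailure(RuntimeError):
    """Random-walk insertion exceeded its step budget.

    At parameters chosen from the capacity model this happens with
    probability at most 2^-lam; observing it is a security-relevant event
    (the table's mere existence would leak that unusually many collisions
    occurred), so it is raised rather than silently retried.
    """


class PackingFailure(RuntimeError):
    """A multiquery needed more tables than the pre-announced B_X."""


def _mix64(z: np.ndarray | int):
    """SplitMix64 finalizer: a fast, well-mixed 64-bit permutation.

    Multiplication deliberately wraps mod 2^64.
    """
    z = np.uint64(z) if isinstance(z, int) else z.astype(np.uint64)
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@dataclass(frozen=True)
class HashSeeds:
    """Seeds for the d hash functions H_0..H_{d-1}.

    Each H_i is a seeded pseudorandom function of the stub, truncated to
    ell_R bits.  Seeds are client secrets: they are never written into
    any server-visible payload.
    """

    seeds: tuple[int, ...]

    @property
    def d(self) -> int:
        return len(self.seeds)

    @classmethod
    def generate(cls, d: int, rng: np.random.Generator) -> "HashSeeds":
        return cls(tuple(int(s) for s in rng.integers(0, 2**63, size=d)))

    def hash_stub(self, i: int, x_L: int, ell_R: int) -> int:
        """H_i(X_L) truncated to ell_R bits."""
        h = _mix64(np.uint64((int(x_L) ^ self.seeds[i]) & 0xFFFFFFFFFFFFFFFF))
        return int(h) & ((1 << ell_R) - 1)

    def hash_stubs(self, x_L: np.ndarray, ell_R: int) -> np.ndarray:
        """Vectorized H_i(X_L) for all i: returns an (len(x_L), d) array."""
        x = x_L.astype(np.uint64)[:, None]
        s = np.array(self.seeds, dtype=np.uint64)[None, :]
        return (_mix64(x ^ s) & np.uint64((1 << ell_R) - 1)).astype(np.int64)


@dataclass
class CuckooTable:
    """A hash table of n bins, each empty or holding an ell_L-bit stub.

    Bin s belongs to region ``s >> ell_R``; region i is written only by
    hash function i, so occupied bins appear only in regions 0..d-1.
    """

    bins: np.ndarray  # int64, EMPTY or a stub value
    ell_R: int

    @property
    def n(self) -> int:
        return int(self.bins.shape[0])

    def occupied(self) -> np.ndarray:
        return self.bins != EMPTY

    @classmethod
    def empty(cls, n: int, ell_R: int) -> "CuckooTable":
        return cls(bins=np.full(n, EMPTY, dtype=np.int64), ell_R=ell_R)


@dataclass
class PackedMultiquery:
    """B_X query tables plus the placement map needed to decode results."""

    tables: list[CuckooTable]
    #: (query index, hash index) -> (table index, bin index)
    placement: dict[tuple[int, int], tuple[int, int]]
    k: int

    @property
    def B_X(self) -> int:
        return len(self.tables)


def _split(x: int, ell_R: int) -> tuple[int, int]:
    return x >> ell_R, x & ((1 << ell_R) - 1)


def loc(i: int, x: int, seeds: HashSeeds, params: ProtocolParams) -> int:
    """Bin index of record x under hash function i."""
    if not 0 <= i < params.d:
        raise ValueError(f"hash index {i} outside [0, d={params.d})")
    x_L, x_R = _split(x, params.ell_R)
    return i * 2**params.ell_R + (seeds.hash_stub(i, x_L, params.ell_R) ^ x_R)


def insert_batch(
    items: list[int],
    params: ProtocolParams,
    seeds: HashSeeds,
    rng: np.random.Generator,
) -> CuckooTable:
    """Insert one batch of distinct records via the random walk.

    Each item starts at a uniformly chosen Loc_i; an evicted occupant is
    re-placed under a uniformly chosen hash index different from the one
    it occupied.  Raises :class:`HashingFailure` once the walk exceeds
    ``WALK_CAP_FACTOR * len(items)`` placements.
    """
    n, d, ell_R = params.n, params.d, params.ell_R
    if len(items) > params.N_prime:
        raise ValueError(f"batch of {len(items)} exceeds N_prime={params.N_prime}")
    vals = np.asarray(items, dtype=np.int64)
    x_L = vals >> ell_R
    x_R = vals & ((1 << ell_R) - 1)
    # all candidate bins, precomputed: locs[j, i] = Loc_i(items[j])
    h = seeds.hash_stubs(x_L, ell_R)
    locs = (np.arange(d, dtype=np.int64)[None, :] << ell_R) | (h ^ x_R[:, None])

    bin_item = np.full(n, EMPTY, dtype=np.int64)  # which item occupies each bin
    cap = WALK_CAP_FACTOR * max(len(items), 1)
    steps = 0
    # pre-drawn randomness, refilled on demand
    draws = rng.integers(0, d, size=4 * max(len(items), 1)).tolist() if d > 1 else []
    draw_pos = 0

    def next_draw() -> int:
        nonlocal draw_pos, draws
        if draw_pos >= len(draws):
            draws = rng.integers(0, d, size=4096).tolist()
            draw_pos = 0
        v = draws[draw_pos]
        draw_pos += 1
        return v

    for start in range(len(items)):
        cur = start
        i = next_draw()
        while True:
            steps += 1
            if steps > cap:
                raise HashingFailure(
                    f"random walk exceeded {cap} steps inserting {len(items)} "
                    f"items into n={n} bins with d={d}"
                )
            s = int(locs[cur, i])
            occ = int(bin_item[s])
            bin_item[s] = cur
            if occ == EMPTY:
                break
            # evicted occupant sat in region i; re-place under a different index
            cur = occ
            j = next_draw()
            while j == i:
                j = next_draw()
            i = j

    table = CuckooTable.empty(n, ell_R)
    used = bin_item != EMPTY
    table.bins[used] = x_L[bin_item[used]]
    return table


def hash_dataset(
    records: list[int],
    params: ProtocolParams,
    seeds: HashSeeds,
    rng: np.random.Generator,
) -> list[CuckooTable]:
    """Hash a dataset into ``B = ceil(N / N_prime)`` tables with shared seeds.

    Records are partitioned into batches in input order.  All batches use
    the same hash functions — a query's d candidate bins must be the same
    in every table for the comparison to be meaningful.  Duplicate records
    are rejected: the exact-match-count guarantee of the hashed circuits
    presumes distinct rows.
    """
    if len(set(records)) != len(records):
        raise ValueError("dataset records must be distinct")
    if not records:
        return [insert_batch([], params, seeds, rng)]
    B = math.ceil(len(records) / params.N_prime)
    return [
        insert_batch(records[j * params.N_prime : (j + 1) * params.N_prime],
                     params, seeds, rng)
        for j in range(B)
    ]


def hash_query(x: int, params: ProtocolParams, seeds: HashSeeds) -> CuckooTable:
    """Hash one query: its stub is written at *all* d candidate bins.

    The client cannot know which of the d locations the dataset insertion
    chose for a matching record, so every candidate must be populated.
    The d regions are disjoint, so the d writes never collide.
    """
    table = CuckooTable.empty(params.n, params.ell_R)
    x_L = x >> params.ell_R
    for i in range(params.d):
        table.bins[loc(i, x, seeds, params)] = x_L
    return table


def pack_multiquery(
    queries: list[int],
    B_X: int,
    params: ProtocolParams,
    seeds: HashSeeds,
) -> PackedMultiquery:
    """Pack k queries into exactly B_X shared tables.

    Locations are assigned deterministically — queries in input order,
    hash indices in order, first table with a free bin — so the placement
    map is reproducible.  Exactly B_X tables are emitted even when fewer
    would suffice (all-empty padding tables), because the announced query
    size must not depend on realized hash collisions.
    """
    if B_X < 1:
        raise ValueError("B_X must be >= 1")
    if len(set(queries)) != len(queries):
        raise ValueError("queries must be distinct")
    tables = [CuckooTable.empty(params.n, params.ell_R) for _ in range(B_X)]
    placement: dict[tuple[int, int], tuple[int, int]] = {}
    for q_idx, x in enumerate(queries):
        x_L = x >> params.ell_R
        for i in range(params.d):
            s = loc(i, x, seeds, params)
            for tbl_idx in range(B_X):
                if tables[tbl_idx].bins[s] == EMPTY:
                    tables[tbl_idx].bins[s] = x_L
                    placement[(q_idx, i)] = (tbl_idx, s)
                    break
            else:
                raise PackingFailure(
                    f"bin {s} needed by more than B_X={B_X} queries"
                )
    return PackedMultiquery(tables=tables, placement=placement, k=len(queries))


def fill_sentinels(
    table: CuckooTable,
    role: str,
    params: ProtocolParams,
    optimized: bool = False,
) -> np.ndarray:
    """Digitize a table into an (n, ell_Lb) matrix with empty-bin sentinels.

    Occupied bins contribute the little-endian base-b digits of their
    stub.  Empty bins receive an *impossible* digit value — ``b`` for the
    dataset role, ``b + 1`` for the query role — so that an empty bin can
    never produce a spurious zero difference; the two roles use different
    sentinels so that dataset-empty and query-empty bins also never agree.
    In basic mode the sentinel fills every digit position (worst-case
    per-bin sum ``ell_Lb * (b+1)^2``); in optimized mode it fills only
    digit position 0, zeros elsewhere, tightening the modulus bound to
    ``(ell_Lb - 1)(b-1)^2 + (b+1)^2``.
    """
    if role not in ("dataset", "query"):
        raise ValueError(f"role must be 'dataset' or 'query', got {role!r}")
    sentinel = params.b if role == "dataset" else params.b + 1
    b, ell_Lb = params.b, params.ell_Lb
    log_b = b.bit_length() - 1
    shifts = (np.arange(ell_Lb, dtype=np.int64) * log_b)[None, :]
    digits = (table.bins[:, None] >> shifts) & (b - 1)  # little-endian
    empty = table.bins == EMPTY
    if optimized:
        digits[empty, :] = 0
        digits[empty, 0] = sentinel
    else:
        digits[empty, :] = sentinel
    return digits
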