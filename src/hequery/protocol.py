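"""The two-party query protocol, as file-based client and server roles.

The *client* owns the data and the secret key: it parses and encodes a
VCF file, cuckoo-hashes it, encrypts the digitized tables, and uploads
the resulting payload to the *server*.  Later the client submits an
encrypted multiquery; the server evaluates the matching circuit on
ciphertexts alone and returns one result ciphertext per query table; the
client decrypts and, using its private placement map, reads off a
MATCH / NO-MATCH verdict per query.

The server never sees hash seeds or any plaintext-derived value: payload
headers carry only public parameters, and blob counts are functions of
those parameters alone, so message sizes leak nothing about the data.
Client and server are implemented as roles within one process exchanging
files; transport is out of scope.

Payload container format (version 1): magic ``HEQP``, a 4-byte
little-endian header length, a JSON header, then for each blob a 4-byte
little-endian slot count followed by that many little-endian 32-bit
residues.  The reference backend's "ciphertexts" are slot vectors; a
real-HE adapter would store opaque ciphertext bytes in the same frames.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable

import numpy as np

from . import params as _params
from .circuits import (
    BatchedDataset,
    MatchResult,
    cam_decode,
    cam_eval,
    cma_eval,
    layout_hashed_dataset,
    layout_hashed_query,
)
from .cuckoo import HashSeeds, hash_dataset, pack_multiquery
from .simd_backend import ProtocolParams, SlotVector, derive_params, sv_plain_mul
from .vcf_codec import VariantRecord, encode_record, parse_vcf

__all__ = [
    "ClientState",
    "EncryptedPayload",
    "CapacityExceeded",
    "client_setup",
    "client_query",
    "server_evaluate",
    "client_decode",
    "write_payload",
    "read_payload",
]

MAGIC = b"HEQP"
FORMAT_VERSION = 1


class CapacityExceeded(ValueError):
    """The realized per-table load exceeds the capacity line at the chosen lam."""


@dataclass
class EncryptedPayload:
    """A self-describing header plus ordered ciphertext blobs."""

    header: dict
    blobs: list[np.ndarray]  # each a length-n int64 residue vector


@dataclass
class ClientState:
    """Client-private material: seeds, params, and per-query placement maps.

    Never serialized into any server-visible artifact; sufficient to
    decode every response for queries it produced.
    """

    params: ProtocolParams
    seeds: HashSeeds
    circuit: str = "cam"
    B: int = 1
    N: int = 0
    queries: dict[int, dict] = field(default_factory=dict)  # qid -> placement info
    next_query_id: int = 0

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "params": {
                    "n": p.n, "t": p.t, "d": p.d, "b": p.b, "ell": p.ell,
                    "N_prime": p.N_prime, "lam": p.lam,
                },
                "seeds": list(self.seeds.seeds),
                "circuit": self.circuit,
                "B": self.B,
                "N": self.N,
                "queries": {
                    str(qid): {
                        "k": q["k"],
                        "B_X": q["B_X"],
                        "placement": [
                            [qi, i, tbl, s]
                            for (qi, i), (tbl, s) in q["placement"].items()
                        ],
                    }
                    for qid, q in self.queries.items()
                },
                "next_query_id": self.next_query_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClientState":
        obj = json.loads(text)
        p = obj["params"]
        state = cls(
            params=derive_params(**p),
            seeds=HashSeeds(tuple(obj["seeds"])),
            circuit=obj["circuit"],
            B=obj["B"],
            N=obj["N"],
            next_query_id=obj["next_query_id"],
        )
        for qid, q in obj["queries"].items():
            state.queries[int(qid)] = {
                "k": q["k"],
                "B_X": q["B_X"],
                "placement": {
                    (qi, i): (tbl, s) for qi, i, tbl, s in q["placement"]
                },
            }
        return state


def _public_header(params: ProtocolParams, circuit: str, role: str, num_tables: int,
                   masks: bool) -> dict:
    # public parameters only: no seeds, nothing data-dependent
    return {
        "version": FORMAT_VERSION,
        "n": params.n,
        "t": params.t,
        "d": params.d,
        "b": params.b,
        "ell": params.ell,
        "ell_Lb": params.ell_Lb,
        "circuit": circuit,
        "role": role,
        "num_tables": num_tables,
        "masks": masks,
    }


def write_payload(fh: BinaryIO, payload: EncryptedPayload) -> None:
    if payload.header.get("t", 0) > 2**32:
        raise ValueError("container stores 32-bit residues; t must be < 2^32")
    header = json.dumps(payload.header, sort_keys=True).encode()
    fh.write(MAGIC)
    fh.write(struct.pack("<I", len(header)))
    fh.write(header)
    for blob in payload.blobs:
        arr = np.asarray(blob, dtype=np.uint32)
        fh.write(struct.pack("<I", arr.size))
        fh.write(arr.astype("<u4").tobytes())


def read_payload(fh: BinaryIO) -> EncryptedPayload:
    if fh.read(4) != MAGIC:
        raise ValueError("not a payload container (bad magic)")
    (hlen,) = struct.unpack("<I", fh.read(4))
    header = json.loads(fh.read(hlen).decode())
    if header.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported container version {header.get('version')}")
    blobs = []
    while True:
        raw = fh.read(4)
        if not raw:
            break
        (count,) = struct.unpack("<I", raw)
        blobs.append(
            np.frombuffer(fh.read(4 * count), dtype="<u4").astype(np.int64)
        )
    return EncryptedPayload(header=header, blobs=blobs)


def _blobs_of_dataset(ds: BatchedDataset) -> list[np.ndarray]:
    blobs = [sv.slots for row in ds.data for sv in row]
    if ds.masks is not None:
        blobs += [m.slots for m in ds.masks]
    return blobs


def client_setup(
    vcf_stream: Iterable[str],
    params: ProtocolParams,
    rng: np.random.Generator,
    circuit: str = "cam",
    enforce_lam: int | None = None,
    allow_capacity_leak: bool = False,
) -> tuple[ClientState, EncryptedPayload]:
    """Parse, encode, hash, sentinel-fill, batch and encrypt a VCF dataset.

    Produces ``B * ell_Lb`` ciphertext blobs (plus B masks for CMA).  When
    ``enforce_lam`` is given and the (d, n) pair is covered by the
    capacity model, a per-table load above the capacity line's limit is
    rejected unless ``allow_capacity_leak`` acknowledges the resulting
    hashing failure probability above ``2**-lam``.
    """
    if circuit not in ("cam", "cma"):
        raise ValueError(f"protocol circuits are 'cam' and 'cma', got {circuit!r}")
    records = parse_vcf(vcf_stream)
    encoded = [encode_record(r).value for r in records]
    B = max(1, math.ceil(len(encoded) / params.N_prime))
    if enforce_lam is not None and not allow_capacity_leak:
        # the hashing-failure probability is governed by the realized
        # per-table load: full batches hold N_prime items, a lone batch
        # holds all N of them
        e_req, per_table_cap, _ = _params.capacity(
            params.n, params.d, enforce_lam, B
        )
        load = len(encoded) if B == 1 else params.N_prime
        if load > per_table_cap:
            raise CapacityExceeded(
                f"per-table load {load} exceeds the capacity-line limit "
                f"{per_table_cap:.0f} (e={e_req:.4f}) at lam={enforce_lam} "
                f"with B={B}; pass allow_capacity_leak=True to accept the leak"
            )
    seeds = HashSeeds.generate(params.d, rng)
    tables = hash_dataset(encoded, params, seeds, rng)
    ds = layout_hashed_dataset(tables, params, with_masks=(circuit == "cma"))
    state = ClientState(
        params=params, seeds=seeds, circuit=circuit, B=len(tables), N=len(encoded)
    )
    payload = EncryptedPayload(
        header=_public_header(params, circuit, "dataset", len(tables),
                              circuit == "cma"),
        blobs=_blobs_of_dataset(ds),
    )
    return state, payload


def client_query(
    mutations: list[VariantRecord],
    state: ClientState,
    B_X: int,
) -> tuple[int, EncryptedPayload]:
    """Pack and encrypt a k-multiquery into exactly B_X tables.

    Returns a query id (used to decode the response) and a payload of
    ``B_X * ell_Lb`` blobs — always, regardless of realized collisions.
    """
    encoded = [encode_record(m).value for m in mutations]
    packed = pack_multiquery(encoded, B_X, state.params, state.seeds)
    q = layout_hashed_query(packed, state.params, with_masks=(state.circuit == "cma"))
    qid = state.next_query_id
    state.next_query_id += 1
    state.queries[qid] = {"k": packed.k, "B_X": B_X, "placement": packed.placement}
    blobs = [sv.slots for row in q.data for sv in row]
    if q.masks is not None:
        blobs += [m.slots for m in q.masks]
    header = _public_header(state.params, state.circuit, "query", B_X,
                            state.circuit == "cma")
    header["query_id"] = qid
    header["k"] = packed.k
    return qid, EncryptedPayload(header=header, blobs=blobs)


def _unpack_tables(payload: EncryptedPayload) -> tuple[dict, list[list[SlotVector]],
                                                       list[SlotVector] | None]:
    h = payload.header
    t, ell_Lb, num = h["t"], h["ell_Lb"], h["num_tables"]
    data_blobs = payload.blobs[: num * ell_Lb]
    tables = [
        [SlotVector.encrypt(data_blobs[i * ell_Lb + j], t) for j in range(ell_Lb)]
        for i in range(num)
    ]
    masks = None
    if h["masks"]:
        masks = [SlotVector.encrypt(bl, t) for bl in payload.blobs[num * ell_Lb :]]
    return h, tables, masks


def server_evaluate(
    dataset: EncryptedPayload,
    query: EncryptedPayload,
    randomize: bool = False,
    rng: np.random.Generator | None = None,
) -> EncryptedPayload:
    """Evaluate the matching circuit; touches only ciphertexts and headers.

    Returns B_X result blobs, one CAM (or masked-CMA) output per packed
    query table.  With ``randomize`` (for a dataset owner distinct from
    the querying client) every non-zero CAM slot is multiplied by a
    fresh random non-zero scalar, hiding everything but zeroness.
    """
    dh, ds_tables, ds_masks = _unpack_tables(dataset)
    qh, q_tables, q_masks = _unpack_tables(query)
    for key in ("n", "t", "b", "ell_Lb", "circuit"):
        if dh[key] != qh[key]:
            raise ValueError(f"incompatible headers: {key} {dh[key]} != {qh[key]}")
    params = derive_params(n=dh["n"], t=dh["t"], d=dh["d"], b=dh["b"], ell=dh["ell"])
    if params.ell_Lb != dh["ell_Lb"]:
        raise ValueError("header ell_Lb inconsistent with (n, d, b, ell)")
    ds = BatchedDataset(data=ds_tables, mode="hashed", params=params, masks=ds_masks)
    results = []
    for tbl_idx, q_row in enumerate(q_tables):
        if dh["circuit"] == "cma":
            out = cma_eval(ds, q_row, q_mask=q_masks[tbl_idx])
        else:
            out = cam_eval(ds, q_row)
        if randomize:
            if rng is None:
                raise ValueError("randomize=True requires an rng")
            r = rng.integers(1, params.t, size=params.n)
            out = sv_plain_mul(out, r)
        results.append(out)
    header = {
        "version": FORMAT_VERSION,
        "n": dh["n"],
        "t": dh["t"],
        "circuit": dh["circuit"],
        "role": "response",
        "num_tables": qh["num_tables"],
        "masks": False,
        "query_id": qh.get("query_id"),
        "depth": max(r.depth for r in results),
    }
    return EncryptedPayload(header=header, blobs=[r.slots for r in results])


def client_decode(response: EncryptedPayload, state: ClientState,
                  query_id: int | None = None) -> MatchResult:
    """Decrypt the response and decode per-query verdicts.

    Requires the placement map stored when the query was created; a
    response for an unknown query id is rejected.
    """
    qid = response.header.get("query_id") if query_id is None else query_id
    if qid is None or qid not in state.queries:
        raise ValueError(f"no client state for query id {qid!r}")
    info = state.queries[qid]
    t = response.header["t"]
    results = [SlotVector.encrypt(bl, t) for bl in response.blobs]
    if state.circuit == "cma":
        # slot value = number of batches matching that bin; sum = match count
        total = sum(int(r.slots.sum()) for r in results)
        hits = set()
        for tbl_idx, r in enumerate(results):
            for s in np.flatnonzero(r.slots != 0):
                hits.add((tbl_idx, int(s)))
        matched = {
            qi for (qi, _i), bin_ref in info["placement"].items() if bin_ref in hits
        }
        verdicts = ["MATCH" if qi in matched else "NO-MATCH"
                    for qi in range(info["k"])]
        return MatchResult(verdicts=verdicts, match_count=total)
    return cam_decode(results, info["placement"], mode="hashed", k=info["k"])
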