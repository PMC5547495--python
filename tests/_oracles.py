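"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def negacyclic_mul(a: list[int], b: list[int], t: int) -> list[int]:
    """Schoolbook product in Z_t[x]/(x^n + 1): x^n wraps with a sign flip."""
    n = len(a)
    out = [0] * n
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            k = i + j
            if k < n:
                out[k] = (out[k] + ai * bj) % t
            else:
                out[k - n] = (out[k - n] - ai * bj) % t
    return out


def poly_eval(coeffs: list[int], x: int, t: int) -> int:
    acc = 0
    for c in reversed(coeffs):
        acc = (acc * x + c) % t
    return acc


def membership_verdicts(dataset: list[int], queries: list[int]) -> list[str]:
    """Exact set-membership verdicts, the ground truth for every circuit."""
    ds = set(dataset)
    return ["MATCH" if q in ds else "NO-MATCH" for q in queries]


def hamming_rows(rows: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Per-row Hamming distance between bit rows and a bit query."""
    return np.sum(rows != query[None, :], axis=1)
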