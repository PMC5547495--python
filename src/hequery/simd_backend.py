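"""Reference semantics for batched leveled homomorphic evaluation.

A leveled HE scheme with batching evaluates arithmetic circuits slot-wise
over ``Z_t^n``: a plaintext polynomial in ``R_t = Z_t[x]/(x^n + 1)`` (with
``n`` a power of two and ``t`` a prime satisfying ``2n | t - 1``) is
isomorphic, as a ring, to a direct product of ``n`` copies of ``Z_t``.
This module implements that semantics exactly in the clear: a
:class:`SlotVector` plays the role of a ciphertext, carrying its slot
values together with the multiplicative depth the evaluation has consumed.
Every value and every depth the protocol produces is therefore identical
to what decryption after a real homomorphic evaluation would give — the
backend omits only the noise and the ciphertext modulus, which affect
performance, not results.

The true ring isomorphism is also provided (:func:`compose` /
:func:`decompose`, via the negacyclic number-theoretic transform) so that
the slot-wise semantics can be cross-checked against genuine polynomial
arithmetic in ``R_t``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import sympy

from . import params as _params

__all__ = [
    "ProtocolParams",
    "SlotVector",
    "PlainPoly",
    "OpLedger",
    "ParameterError",
    "derive_params",
    "validate_params",
    "compose",
    "decompose",
    "sv_add",
    "sv_sub",
    "sv_square",
    "sv_mul",
    "sv_plain_mul",
    "sv_plain_rsub",
    "balanced_product",
]


class ParameterError(ValueError):
    """A protocol parameter set violates one of its validity invariants."""


@dataclass(frozen=True)
class ProtocolParams:
    """All public scheme and hashing parameters, with derived lengths.

    Attributes
    ----------
    n: slot count / polynomial ring degree (power of two).
    t: plaintext modulus (prime, ``t ≡ 1 (mod 2n)``).
    d: number of cuckoo hash functions (>= 3 in validated sets).
    b: digit base for string representation (power of two).
    ell: record bit-length (40 for encoded variant records).
    ell_R: bits absorbed into the bin index, ``log2 n - ceil(log2 d)``.
    ell_L: stored stub bits, ``ell - ell_R``.
    ell_Lb: stored digit count, ``ceil(ell_L / log2 b)``.
    N_prime: per-batch item capacity (≤ n).
    lam: statistical security parameter in bits.
    """

    n: int
    t: int
    d: int
    b: int
    ell: int
    ell_R: int
    ell_L: int
    ell_Lb: int
    N_prime: int
    lam: int = 30


def _is_pow2(x: int) -> bool:
    return x > 0 and x & (x - 1) == 0


def derive_params(
    n: int,
    t: int,
    d: int,
    b: int,
    ell: int = 40,
    N_prime: int | None = None,
    lam: int = 30,
) -> ProtocolParams:
    """Fill in the derived lengths without circuit-specific validation."""
    if not _is_pow2(n):
        raise ParameterError(f"n={n} is not a power of two")
    if not _is_pow2(b) or b < 2:
        raise ParameterError(f"b={b} must be a power of two >= 2")
    if d < 1 or ell < 1:
        raise ParameterError("d and ell must be positive")
    ell_R = int(math.log2(n)) - math.ceil(math.log2(d))
    if ell_R < 0 or ell_R >= ell:
        raise ParameterError(
            f"ell_R = log2(n) - ceil(log2(d)) = {ell_R} not in [0, ell)"
        )
    ell_L = ell - ell_R
    ell_Lb = math.ceil(ell_L / math.log2(b))
    if N_prime is None:
        N_prime = n
    if N_prime > n:
        raise ParameterError(f"N_prime={N_prime} exceeds table size n={n}")
    return ProtocolParams(
        n=n, t=t, d=d, b=b, ell=ell,
        ell_R=ell_R, ell_L=ell_L, ell_Lb=ell_Lb,
        N_prime=N_prime, lam=lam,
    )


def validate_params(
    n: int,
    t: int,
    d: int,
    b: int,
    ell: int,
    circuit: str,
    B: int = 1,
    N_prime: int | None = None,
    lam: int = 30,
    optimized: bool = False,
) -> ProtocolParams:
    """Derive and fully validate a parameter set for a given circuit.

    Checks, in order: n power of two; t prime; ``2n | t - 1`` (batching);
    d >= 3 (2-hash cuckoo scales exponentially in the security parameter
    and is excluded); and that t strictly exceeds the active circuit's
    wrap-around bound.  Raises :class:`ParameterError` naming the failed
    bound.
    """
    p = derive_params(n, t, d, b, ell, N_prime=N_prime, lam=lam)
    if not sympy.isprime(t):
        raise ParameterError(f"t={t} is not prime")
    if (t - 1) % (2 * n) != 0:
        raise ParameterError(f"t={t} does not satisfy t ≡ 1 (mod 2n={2*n})")
    if d < 3:
        raise ParameterError(f"d={d} < 3: only d >= 3 hash functions are supported")
    circuit = circuit.lower()
    ell_bits = p.ell_L if circuit == "cam-hashed" else ell
    bound = _params.t_bound(circuit, ell_bits=ell_bits, b=b, B=B, optimized=optimized)
    if t <= bound:
        raise ParameterError(
            f"t={t} must strictly exceed the {circuit} bound {bound}"
        )
    return p


# ---------------------------------------------------------------------------
# slot vectors


@dataclass
class OpLedger:
    """Counts of homomorphic operations consumed by an evaluation.

    Plain-constant operations (subtracting from an unencrypted 1,
    multiplying by an unencrypted mask) are free and not counted.
    """

    adds: int = 0
    squares: int = 0
    mults: int = 0

    def __iadd__(self, other: "OpLedger") -> "OpLedger":
        self.adds += other.adds
        self.squares += other.squares
        self.mults += other.mults
        return self


@dataclass(frozen=True)
class SlotVector:
    """A length-n vector of residues mod t standing in for a ciphertext.

    ``depth`` tracks consumed multiplicative depth: additions keep the
    maximum of the operand depths, squarings and multiplications add one.
    A fresh encryption has depth 0.
    """

    slots: np.ndarray  # int64, values in [0, t)
    t: int
    depth: int = 0
    fresh: bool = True

    @classmethod
    def encrypt(cls, values, t: int) -> "SlotVector":
        arr = np.asarray(values, dtype=np.int64) % t
        return cls(slots=arr, t=t, depth=0, fresh=True)

    @property
    def n(self) -> int:
        return int(self.slots.shape[0])

    def __post_init__(self):
        if self.slots.dtype != np.int64:
            object.__setattr__(self, "slots", self.slots.astype(np.int64))
        if np.any(self.slots < 0) or np.any(self.slots >= self.t):
            object.__setattr__(self, "slots", self.slots % self.t)


def _check_compat(a: SlotVector, b: SlotVector) -> None:
    if a.n != b.n or a.t != b.t:
        raise ValueError(
            f"operand mismatch: (n={a.n}, t={a.t}) vs (n={b.n}, t={b.t})"
        )


def sv_add(a: SlotVector, b: SlotVector, ledger: OpLedger | None = None) -> SlotVector:
    _check_compat(a, b)
    if ledger is not None:
        ledger.adds += 1
    return SlotVector((a.slots + b.slots) % a.t, a.t, max(a.depth, b.depth), False)


def sv_sub(a: SlotVector, b: SlotVector, ledger: OpLedger | None = None) -> SlotVector:
    _check_compat(a, b)
    if ledger is not None:
        ledger.adds += 1
    return SlotVector((a.slots - b.slots) % a.t, a.t, max(a.depth, b.depth), False)


def sv_square(a: SlotVector, ledger: OpLedger | None = None) -> SlotVector:
    if ledger is not None:
        ledger.squares += 1
    return SlotVector((a.slots * a.slots) % a.t, a.t, a.depth + 1, False)


def sv_mul(a: SlotVector, b: SlotVector, ledger: OpLedger | None = None) -> SlotVector:
    _check_compat(a, b)
    if ledger is not None:
        ledger.mults += 1
    return SlotVector((a.slots * b.slots) % a.t, a.t, max(a.depth, b.depth) + 1, False)


def sv_plain_mul(a: SlotVector, plain) -> SlotVector:
    """Multiply slot-wise by an unencrypted vector (free: no depth, no count)."""
    vec = np.asarray(plain, dtype=np.int64) % a.t
    return SlotVector((a.slots * vec) % a.t, a.t, a.depth, False)


def sv_plain_rsub(const: int, a: SlotVector) -> SlotVector:
    """Compute ``const - a`` with an unencrypted constant (free)."""
    return SlotVector((const - a.slots) % a.t, a.t, a.depth, False)


def balanced_product(
    terms: list[SlotVector], ledger: OpLedger | None = None
) -> SlotVector:
    """Product of all terms via a balanced binary tree.

    Uses ``len(terms) - 1`` multiplications and increases depth over the
    deepest input by exactly ``ceil(log2(len(terms)))`` — the tree shape
    is what realizes the logarithmic depth of the batch product.
    """
    if not terms:
        raise ValueError("balanced_product of an empty list")
    layer = list(terms)
    while len(layer) > 1:
        nxt = []
        for i in range(0, len(layer) - 1, 2):
            nxt.append(sv_mul(layer[i], layer[i + 1], ledger))
        if len(layer) % 2:
            nxt.append(layer[-1])
        layer = nxt
    return layer[0]


# ---------------------------------------------------------------------------
# the batching isomorphism  R_t  ≅  Z_t^n


@dataclass(frozen=True)
class PlainPoly:
    """An element of ``R_t = Z_t[x]/(x^n + 1)``; index 0 is the constant term."""

    coeffs: tuple[int, ...]
    t: int

    @property
    def n(self) -> int:
        return len(self.coeffs)


def _primitive_2n_root(n: int, t: int) -> int:
    """Smallest primitive 2n-th root of unity mod t.

    With 2n a power of two, any x with ``x^n ≡ -1 (mod t)`` has order
    exactly 2n, so a linear scan over small x suffices.
    """
    if (t - 1) % (2 * n) != 0:
        raise ValueError(f"no primitive 2n-th root of unity mod t={t} (2n ∤ t-1)")
    for x in range(2, t):
        if pow(x, n, t) == t - 1:
            return x
    raise ValueError(f"no primitive 2n-th root of unity mod t={t}")


def _ntt(a: list[int], omega: int, t: int) -> list[int]:
    """out[i] = sum_j a[j] * omega^(i*j) mod t (radix-2 Cooley-Tukey)."""
    n = len(a)
    if n == 1:
        return list(a)
    omega_sq = omega * omega % t
    even = _ntt(a[0::2], omega_sq, t)
    odd = _ntt(a[1::2], omega_sq, t)
    out = [0] * n
    w = 1
    half = n // 2
    for k in range(half):
        x = w * odd[k] % t
        out[k] = (even[k] + x) % t
        out[k + half] = (even[k] - x) % t
        w = w * omega % t
    return out


def decompose(poly: PlainPoly, params: ProtocolParams) -> np.ndarray:
    """Map a plaintext polynomial to its n slot values.

    Slot i holds the evaluation of the polynomial at ``psi^(2i+1)``, the
    i-th root of ``x^n + 1`` in root-power order, where psi is the
    smallest primitive 2n-th root of unity mod t.  This map is a ring
    isomorphism: it turns polynomial addition and negacyclic
    multiplication into slot-wise arithmetic.
    """
    n, t = params.n, params.t
    if poly.n != n:
        raise ValueError(f"polynomial has {poly.n} coefficients, expected {n}")
    psi = _primitive_2n_root(n, t)
    # p(psi^(2i+1)) = sum_j (a_j psi^j) (psi^2)^(i j): twist then plain NTT
    twisted = [poly.coeffs[j] * pow(psi, j, t) % t for j in range(n)]
    return np.array(_ntt(twisted, psi * psi % t, t), dtype=np.int64)


def compose(values, params: ProtocolParams) -> PlainPoly:
    """Inverse of :func:`decompose`: slot values to a plaintext polynomial.

    An all-equal slot vector composes to the constant polynomial, which is
    why a query symbol can be encoded by writing it directly as a constant.
    """
    n, t = params.n, params.t
    vals = [int(v) % t for v in values]
    if len(vals) != n:
        raise ValueError(f"expected {n} slot values, got {len(vals)}")
    psi = _primitive_2n_root(n, t)
    omega_inv = pow(psi * psi % t, t - 2, t)
    n_inv = pow(n, t - 2, t)
    untwisted = _ntt(vals, omega_inv, t)
    psi_inv = pow(psi, t - 2, t)
    coeffs = tuple(
        untwisted[j] * n_inv % t * pow(psi_inv, j, t) % t for j in range(n)
    )
    return PlainPoly(coeffs=coeffs, t=t)
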