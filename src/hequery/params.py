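"""Public-parameter mathematics for the encrypted-query protocol.

Everything here is plaintext arithmetic over *public* quantities: the
plaintext-modulus bounds that keep slot values from wrapping around ``t``,
the empirically calibrated cuckoo-capacity lines that limit how many
records fit in a hash table at a given statistical security level, the
balls-in-boxes tail bound governing multiquery packing, and a prime search
for batching-compatible plaintext moduli.

Statistical security is expressed in bits: an observable failure event
(a cuckoo-hashing failure while building the dataset tables, or a
multiquery needing more tables than announced) must occur with probability
at most ``2**-lam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import sympy

__all__ = [
    "CAPACITY_LINES",
    "CapacityModel",
    "MultiqueryPlan",
    "t_bound",
    "find_plain_modulus",
    "validate_plain_modulus",
    "capacity",
    "multiquery_failure_bound",
    "min_BX",
    "max_k",
    "empirical_cuckoo_failure",
]

#: Calibrated linear relations  lam = slope * e - intercept  between the
#: hash-table expansion factor e = n / N' and the statistical security
#: parameter, for d-cuckoo hashing with d hash functions into n bins.
#: These nine lines are empirical constants; no extrapolation to other
#: (d, n) pairs is performed.
CAPACITY_LINES: dict[tuple[int, int], tuple[float, float]] = {
    (3, 4096): (120.5, 138.1),
    (3, 8192): (122.5, 141.5),
    (3, 16384): (123.3, 143.5),
    (4, 4096): (126.2, 136.3),
    (4, 8192): (128.2, 139.6),
    (4, 16384): (127.5, 140.0),
    (5, 4096): (126.1, 134.0),
    (5, 8192): (121.3, 129.7),
    (5, 16384): (121.5, 130.8),
}


@dataclass(frozen=True)
class CapacityModel:
    """The table of calibrated capacity lines, exposed as an object."""

    lines: tuple[tuple[tuple[int, int], tuple[float, float]], ...] = tuple(
        sorted(CAPACITY_LINES.items())
    )

    def line(self, d: int, n: int) -> tuple[float, float]:
        try:
            return CAPACITY_LINES[(d, n)]
        except KeyError:
            raise KeyError(
                f"no calibrated capacity line for (d={d}, n={n}); "
                f"supported: d in {{3,4,5}}, n in {{4096,8192,16384}}"
            ) from None


@dataclass(frozen=True)
class MultiqueryPlan:
    """A (k, B_X) pairing together with the security level it achieves."""

    k: int
    B_X: int
    lam_achieved: float  # -log2 of the packing-failure bound


def _digits_for(bits: int, b: int) -> int:
    """Number of base-b digits needed for a ``bits``-bit string."""
    return math.ceil(bits / math.log2(b))


def t_bound(
    circuit: str,
    ell_bits: int | None = None,
    b: int = 2,
    B: int | None = None,
    optimized: bool = False,
) -> int:
    """Exclusive lower bound on the plaintext modulus t for a circuit.

    Any prime ``t`` strictly greater than the returned value (and with
    ``2n | t - 1`` for batching) guarantees that no intermediate slot value
    wraps around ``t``, which is what rules out false positives.

    Parameters
    ----------
    circuit:
        One of ``"cam-hashed"``, ``"cam-direct"``, ``"cma"``, ``"ca"``.
    ell_bits:
        Bit-length of the compared strings: the stored stub length ell_L
        for hashed CAM, the full record length ell for direct CAM and CA.
    b:
        Digit base used to represent the strings (power of 2; b=2 means
        plain bits). Ignored for CMA and CA.
    B:
        Batch count; required for CMA only.
    optimized:
        For hashed CAM: assume empty-bin sentinels are written into a
        single designated digit position instead of every position, which
        tightens the bound to ``(ell_Lb - 1)(b-1)^2 + (b+1)^2``.
    """
    circuit = circuit.lower()
    if circuit == "cam-hashed":
        if ell_bits is None:
            raise ValueError("cam-hashed bound needs ell_bits (= ell_L)")
        ell_Lb = _digits_for(ell_bits, b)
        if optimized:
            return (ell_Lb - 1) * (b - 1) ** 2 + (b + 1) ** 2
        # empty bins carry sentinel b (dataset) / b+1 (query) in every
        # digit, so one digit's squared difference can reach (b+1)^2
        return ell_Lb * (b + 1) ** 2
    if circuit == "cam-direct":
        if ell_bits is None:
            raise ValueError("cam-direct bound needs ell_bits")
        ell_b = _digits_for(ell_bits, b)
        return ell_b * (b - 1) ** 2
    if circuit == "cma":
        if B is None:
            raise ValueError("cma bound needs the batch count B")
        return B
    if circuit == "ca":
        if ell_bits is None:
            raise ValueError("ca bound needs ell_bits")
        return ell_bits
    raise ValueError(f"unknown circuit {circuit!r}")


def validate_plain_modulus(t: int, n: int, bound: int) -> bool:
    """True iff t is a valid plaintext modulus: prime, ≡ 1 (mod 2n), > bound."""
    return t > bound and (t - 1) % (2 * n) == 0 and sympy.isprime(t)


def find_plain_modulus(n: int, bound: int) -> int:
    """Smallest prime t with t > bound and 2n | t - 1 (batching-compatible)."""
    if bound < 1:
        raise ValueError("bound must be >= 1")
    step = 2 * n
    # first candidate == 1 (mod 2n) strictly above the bound
    t = (bound // step) * step + 1
    if t <= bound:
        t += step
    while not sympy.isprime(t):
        t += step
    return t


def capacity(n: int, d: int, lam: float, B: int = 1) -> tuple[float, float, int]:
    """Cuckoo capacity at security level lam with B batches.

    Solves the calibrated line ``lam + log2(B) = slope * e - intercept``
    for the expansion factor e, and returns ``(e, N_prime, N_max)`` where
    ``N_prime = n / e`` is the per-table item capacity and
    ``N_max = floor(B * n / e)`` the total dataset row cap.  The
    ``log2(B)`` correction accounts for B independent chances of a hashing
    failure across the batch tables.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if B < 1:
        raise ValueError("B must be >= 1")
    slope, intercept = CapacityModel().line(d, n)
    e = (lam + math.log2(B) + intercept) / slope
    N_prime = n / e
    N_max = math.floor(B * n / e)
    return e, N_prime, N_max


def multiquery_failure_bound(n: int, d: int, k: int, B_X: int) -> float:
    """Upper bound on the probability that packing k queries needs > B_X tables.

    Each of the d location functions maps into a disjoint region of n/d
    bins; placing the k queries in one region is a balls-in-boxes
    experiment, and a union bound over all n bins gives

        n * sum_{i=B_X+1}^{k} C(k, i) (d/n)^i (1 - d/n)^(k-i).

    The expression is evaluated exactly with rational arithmetic and
    clamped to [0, 1] (the union bound can exceed 1 for extreme inputs).
    """
    if B_X < 1 or k < 1:
        raise ValueError("B_X and k must be >= 1")
    if d >= n:
        raise ValueError("need d < n")
    if B_X >= k:
        return 0.0
    p = Fraction(d, n)
    total = Fraction(0)
    for i in range(B_X + 1, k + 1):
        total += math.comb(k, i) * p**i * (1 - p) ** (k - i)
    bound = n * total
    return float(min(bound, Fraction(1)))


def min_BX(n: int, d: int, k: int, lam: float) -> int:
    """Smallest table count B_X with packing-failure bound at most 2^-lam.

    ``B_X = k`` always suffices (a bin can hold at most k of the k
    queries), so the scan terminates.
    """
    for B_X in range(1, k + 1):
        if multiquery_failure_bound(n, d, k, B_X) <= 2.0**-lam:
            return B_X
    return k


def max_k(n: int, d: int, B_X: int, lam: float) -> int:
    """Largest multiquery size k supported by B_X tables at level ~lam.

    Because published operating points for this bound are quoted as
    approximate powers of two, the criterion is that -log2 of the exact
    bound rounds to at least lam at the nearest integer (i.e. the bound is
    at most 2^-(lam - 0.5)); a strict 2^-lam cutoff would reject quoted
    operating points whose bound is marginally above it.
    """
    threshold = 2.0 ** -(lam - 0.5)
    k = B_X  # bound is exactly 0 here
    while True:
        if multiquery_failure_bound(n, d, k + 1, B_X) > threshold:
            return k
        k += 1


def empirical_cuckoo_failure(
    n: int, d: int, N_prime: int, trials: int, seed: int, ell: int = 40
) -> float:
    """Observed d-cuckoo hashing failure rate over seeded random trials.

    Repeatedly draws ``N_prime`` distinct random ``ell``-bit records,
    builds one hash table with fresh hash-function seeds, and reports the
    fraction of trials in which the random-walk insertion failed.  This is
    a reduced-trial estimator of the failure probability that the
    capacity lines were calibrated against; it can resolve only rates
    down to about 1/trials.
    """
    import numpy as np

    from .cuckoo import HashingFailure, HashSeeds, insert_batch
    from .simd_backend import derive_params

    if trials < 1:
        raise ValueError("trials must be >= 1")
    params = derive_params(n=n, t=65537, d=d, b=2, ell=ell, N_prime=N_prime)
    rng = np.random.default_rng(seed)
    failures = 0
    for _ in range(trials):
        items = rng.choice(2**ell, size=N_prime, replace=False)
        seeds = HashSeeds.generate(d, rng)
        try:
            insert_batch([int(v) for v in items], params, seeds, rng)
        except HashingFailure:
            failures += 1
    return failures / trials
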