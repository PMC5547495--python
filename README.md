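# hequery

Privacy-preserving exact-match queries on genomic variant data using
homomorphic encryption (HE).

A medical center wants to store VCF files in a public cloud and later ask
"is this mutation present?" without the cloud learning anything about the
data or the queries. `hequery` implements a complete protocol for this
setting: each VCF row is reduced to a 40-bit record
`chrom(5) ∥ pos(30) ∥ ref(2) ∥ alt(2) ∥ snp(1)`, shortened by
permutation-based *d*-cuckoo hashing, packed into the *n* SIMD slots of a
batched HE plaintext, and matched under encryption by low-depth arithmetic
circuits. The package is aimed at researchers in applied cryptography and
genome privacy who need the *exact* plaintext semantics of the protocol —
every slot value, ciphertext count, multiplicative depth and operation
count — together with the full public-parameter calculus.

## The model

With ring degree *n* (a power of two) and plaintext modulus *t* (prime,
`2n | t − 1`), the plaintext ring `R_t = Z_t[x]/(x^n + 1)` splits into a
direct product of *n* slots, so one ciphertext carries *n* residues mod
*t* operated on in SIMD fashion. A dataset of *N* strings of *L* digits
is laid out column-wise into `B = ⌈N/n⌉` batches and matched against a
query `X` with one of three circuits:

- **CAM** `∏_{i≤B} Σ_{j≤L} (D_ij − X_j)²` — slot *k* is 0 iff row
  *n(i−1)+k* matches in some batch; depth `1 + ⌈log₂ B⌉`;
  cost `(2L−1)B` additions, `LB` squarings, `B−1` multiplications.
- **CMA** `Σ_{i≤B} ∏_{j≤L} [1 − (D_ij − X_j)²]` — slot values count
  matches; depth `1 + ⌈log₂ L⌉`; needs only `t > B`.
- **CA** `Σ_j (D_j − X_j)²` (single batch) — slot *k* holds the Hamming
  distance to row *k*; depth 1.

Cuckoo hashing with *d* hash functions stores only the high
`ℓ_L = ℓ − ℓ_R` bits of each record, with `ℓ_R = log₂ n − ⌈log₂ d⌉` bits
and the hash-function index absorbed into the *bin index*
(`Loc_i(X) = i·2^{ℓ_R} + [H_i(X_L) ⊕ X_R]`), so only `ℓ_L` bits per bin
need comparing. At the reference operating point (*n* = 8192, *d* = 4,
base *b* = 2¹⁰) a 40-bit record shrinks to `ℓ_{L,b} = 3` digits, and any
prime `t > ℓ_{L,b}(b+1)² = 3 151 875` with `2n | t − 1` rules out
wrap-around false positives. *k* queries pack into `B_X` shared tables,
where `B_X` is fixed in advance from an exact balls-in-boxes binomial
bound so that observed message sizes leak nothing.

The backend evaluates these circuits on plaintext slot vectors with exact
depth and operation accounting — the values are identical to what
decrypting a real leveled-HE evaluation would give — and the true ring
isomorphism (negacyclic NTT compose/decompose) is included for
cross-checking against genuine polynomial arithmetic.

## Worked example

```
$ hequery gen-fixture --rows 1000 --hits 3 --misses 2 --seed 7 --out-prefix fx
wrote fx.vcf (1000 rows), 5 queries
$ hequery encrypt-db fx.vcf --seed 1 --out db.pay --state client.state
encrypted 798 rows into 1 batch tables (3 ciphertext blobs)
$ hequery make-query fx.queries.txt --state client.state --bx 1 --out q.pay
query id 0: 5 mutations in 3 blobs
$ hequery evaluate db.pay q.pay --out r.pay
response: 1 blob(s), depth 1
$ hequery decode r.pay --state client.state
0	MATCH
1	MATCH
2	MATCH
3	NO-MATCH
4	NO-MATCH
```

Of the 1000 generated rows, 798 survive parsing (substitution and
insertion rows are dropped; only SNPs are queryable). At the default
parameters (*n* = 8192, *t* = 3 686 401, *d* = 4, *b* = 1024) they fill one
cuckoo table, encrypted as `B·ℓ_{L,b} = 3` ciphertext blobs. The
5-multiquery packs into a single table (3 blobs), the server returns one
result ciphertext per query table at depth `1 + ⌈log₂ 1⌉ = 1`, and the
client's placement map decodes the three planted hits and two planted
misses exactly.

The parameter planner prints the capacity and packing regime:

```
$ hequery params --n 8192 --d 4 --lam 30 --b-batches 13 --k 5
  expansion factor e       1.3518
  per-table capacity N'    6060.1
  dataset row cap N_max    78781
  multiquery tables B_X    4
  t bound (hashed CAM)     3151875
  suggested plain modulus  3194881
```

meaning: at statistical security 2⁻³⁰ with 13 batches, each hash table
may hold ≈6060 records (78 781 rows total), a 5-multiquery needs 4 tables
at that security level (a single table succeeds with probability ≈0.98),
and any batching-compatible prime above 3 151 875 is a safe plaintext
modulus.

## Layout

- `src/hequery/simd_backend.py` — slot vectors, depth/op accounting, NTT
  batching isomorphism, parameter validation
- `src/hequery/vcf_codec.py` — VCF parsing and the 40-bit record codec
- `src/hequery/cuckoo.py` — permutation-based d-cuckoo hashing, query
  hashing, multiquery packing, empty-bin sentinels
- `src/hequery/circuits.py` — CAM / CMA / CA with layouts and decoding
- `src/hequery/params.py` — modulus bounds, capacity lines, packing
  bounds, prime search, failure-rate estimator
- `src/hequery/protocol.py` — client/server roles, payload containers
- `src/hequery/synthdata.py` — synthetic VCF fixtures with ground truth
- `docs/methods.md` — modeling assumptions and design choices
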