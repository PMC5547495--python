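# Methods

This note records the model implemented by `hequery`, the parameter
conventions, the numerical and design choices that were genuinely open,
and what the synthetic-data tests do and do not establish.

## Reference backend instead of a real HE library

The protocol's testable surface is entirely arithmetic: which residues
end up in which slots, how much multiplicative depth a circuit consumes,
how many ciphertexts cross the wire. All of these are determined by the
plaintext semantics of a leveled HE scheme with batching and are
independent of keys, noise, or the ciphertext modulus *q*. The mandatory
backend therefore evaluates circuits directly on length-*n* slot vectors
mod *t*, with the depth rule "add/sub: max of operands; square/multiply:
max + 1" and an operation ledger that counts ciphertext additions,
squarings and general multiplications separately (squarings are cheaper
in practice). Plain-constant operations — the `1 − x` in CMA, mask
multiplication by the server's randomizer — are free and uncounted.
A fresh encryption has depth 0. A real-HE adapter would slot in behind
the same Setup/KeyGen/Encrypt/Decrypt/Evaluate surface; scheme internals
(relinearization, noise budgets, *q* selection, computational security
estimation) are out of scope by design.

The batching isomorphism `R_t ≅ Z_t^n` is implemented for real via the
negacyclic NTT so that the slot semantics can be cross-checked against
schoolbook polynomial arithmetic. Slot order is fixed as root-power
order: slot *i* is the evaluation at `ψ^(2i+1)`, where ψ is the
*smallest* primitive 2n-th root of unity mod *t*. Any consistent slot
order is valid (the protocol never relies on a particular one); fixing
the smallest root makes compose/decompose reproducible across runs and
platforms.

## Parameters and their defaults

| symbol | meaning | default | why |
|---|---|---|---|
| *n* | slot count / ring degree | 8192 | reference operating point; large enough for 7700-item tables, small enough for fast HE |
| *t* | plaintext modulus | 3 686 401 | prime, `2n∣t−1`, exceeds the hashed-CAM bound 3 151 875 |
| *d* | cuckoo hash functions | 4 | best capacity/cost trade-off; d=2 scales exponentially in λ and is excluded, so d ≥ 3 is enforced |
| *b* | digit base | 2¹⁰ | turns the 29 stored bits into ℓ_{L,b}=3 digits; CMA and CA use b=2 (their semantics need 0/1 differences) |
| ℓ | record bit length | 40 | 5 (chrom) + 30 (pos) + 2 + 2 + 1 |
| N′ | per-table item budget | 7700 | reference throughput point; at λ=30 the capacity line caps the realized load at ≈6060 instead |
| λ | statistical security | 30 | failure events observable by the server must have probability ≤ 2⁻λ; 30–40 is the customary range |

Derived: `ℓ_R = log₂ n − ⌈log₂ d⌉` (bits absorbed into the bin index),
`ℓ_L = ℓ − ℓ_R` (stored stub), `ℓ_{L,b} = ⌈ℓ_L / log₂ b⌉` (stored
digits).

### Modulus bounds

A circuit is refused (never silently evaluated) when *t* does not
strictly exceed its wrap-around bound: `ℓ_{L,b}(b+1)²` for hashed CAM
with basic sentinels, `(ℓ_{L,b}−1)(b−1)² + (b+1)²` in the optimized
sentinel mode, `ℓ_b(b−1)²` for direct CAM, *B* for CMA, ℓ for CA.
Primality of *t* makes the CAM batch product safe without any further
bound — a product is 0 mod a prime iff a factor is. The tests include a
constructed instance demonstrating that an undersized modulus does
fabricate a match, which is why refusal rather than warning is the right
behavior.

### Capacity lines

The relation between the hash-table expansion factor `e = n/N′` and the
statistical security λ is taken from nine empirically calibrated linear
fits `λ = slope·e − intercept`, one per (d, n) ∈ {3,4,5} × {4096, 8192,
16384}. These are treated as exact constants: re-deriving them would
require on the order of 2³⁰ table constructions per point, and the trend
across *n* is weak enough that extrapolation to other ring sizes is
deliberately refused. With *B* batch tables the left side becomes
`λ + log₂ B` (B independent chances to fail). A reduced-trial estimator
(`params.empirical_cuckoo_failure`) rebuilds tables with fresh seeds and
reports the observed failure fraction; at 10³ trials it can only resolve
rates down to ~10⁻³, so it serves as a sanity check of the regime (zero
failures well below capacity, rising failures as the load approaches
*n*), not as a re-derivation of the lines.

Capacity enforcement in `client_setup` checks the *realized per-table
load* — *N* when one batch suffices, N′ for full batches — against `n/e`
from the corrected line. This convention reproduces the published row
caps (B = 13, λ = 30 → per-table 6060, total `⌊13·8192/e⌋ = 78 781`;
λ = 40 → 74 483) and reflects that hashing failure is a per-table event.
`N_max = ⌊B·n/e⌋` with floor rounding is the convention that matches
both caps; ceiling or nearest-integer rounding does not.

### Multiquery planning

The probability that *k* queries need more than `B_X` shared tables is
bounded by `n · Σ_{i>B_X} C(k,i)(d/n)^i(1−d/n)^{k−i}`, evaluated exactly
in rational arithmetic (no normal approximation) and clamped to [0, 1]
since the union bound can exceed 1 for extreme inputs. `min_BX` scans
upward (B_X = k always suffices by pigeonhole). `max_k` uses
round-to-nearest on −log₂ of the bound: published operating points in
this regime are quoted as approximate powers of two, and the k = 16,
B_X = 4 point achieves 2⁻²⁹·⁹ — a strict 2⁻³⁰ cutoff would reject it, so
the rounding convention is part of the model and is documented here
prominently. A predetermined number *M* of multiqueries over the data's
lifetime would add log₂ M to the required level; the default assumes
M = 1.

## Hashing conventions

- **Split orientation.** `X_R` is the *low* `ℓ_R` bits, `X_L` the high
  `ℓ_L` bits. Either orientation is valid; this one is fixed and used
  consistently on both dataset and query side.
- **Hash functions.** `H_i` is a keyed 64-bit mixing permutation
  (SplitMix64 finalizer of `X_L ⊕ seed_i`, truncated to `ℓ_R` bits).
  The protocol needs independent pseudorandom functions, not collision
  resistance — the adversary never sees the seeds, which live only in
  client state and are excluded from every payload header by
  construction. A keyed integer mixer is vectorizable with numpy, which
  keeps the failure-rate estimator at N′ = 7700 × 10³ trials cheap.
- **Random walk.** Insertion places an item under a uniformly chosen
  hash index and relocates evicted occupants under a uniformly chosen
  *different* index. The occupant's previous index is recoverable from
  its bin's region (`s >> ℓ_R`), one of the conveniences of encoding the
  hash index in the bin index. The walk aborts after `100 ×` batch-size
  placements: at validated expansion factors reaching this cap is
  astronomically unlikely, so hitting it is treated as a genuine
  hashing failure (a security-relevant, λ-bounded event), not retried.
- **Batch assignment.** Records fill batches in input order; any
  deterministic partition is correct since every batch is compared
  against the query.
- **Duplicates.** Hashed-CAM's exact-match-count property presumes
  distinct dataset rows; duplicates are rejected at hashing time rather
  than given undefined semantics.
- **Sentinels.** Empty dataset bins hold the impossible digit *b*, empty
  query bins *b* + 1, in every digit position (basic mode). The bounds
  assume per-digit sentinels; the optimized mode writes the sentinel in
  digit position 0 only, zeros elsewhere, and tightens the modulus
  bound accordingly. When `ℓ_L` is not a multiple of log₂ b the top
  digit has a smaller range; sentinels still use b and b+1 everywhere,
  which remains sound (they exceed every valid digit).
- **Packing.** Multiquery locations are assigned deterministically
  (queries in input order, hash indices in order, first table with a
  free bin), making the placement map reproducible; exactly `B_X` tables
  are always emitted, padding with all-empty tables, so message size is
  a function of public parameters only.

## Protocol and serialization

Client and server are roles within one process exchanging files; network
transport, key management and malicious-model defenses are out of scope.
The payload container is a versioned header (JSON, public parameters
only) followed by length-prefixed blobs of little-endian 32-bit residues
(hence *t* < 2³²; the reference modulus is 22 bits). Response size is
`B_X` blobs regardless of content. For the variant where the dataset
owner is not the querying client, `server_evaluate(randomize=True)`
multiplies the CAM output slot-wise by a random non-zero vector, hiding
everything except which slots are zero; zero slots are preserved because
*t* is prime. CMA is selectable in the same container (masks ride along
as extra blobs); CA is available at the circuits layer for single-batch
Hamming profiling.

Direct-mode padding rows (when `n ∤ N`) are filled with the dataset-side
sentinel digit *b* rather than zeros — zero padding would falsely match
an all-zero query.

## Synthetic data: what it shows and what it does not

The fixture generator emulates the input schema end to end: CHROM
uniform over {1..22, X, Y}, POS uniform below 2³⁰ (positions of up to
nine decimal digits fit in 30 bits; uniform-below-2³⁰ generation is a
strict superset of nine-digit positions), REF ≠ ALT for SNP rows, an
SVTYPE mix over {SNP, DEL, SUB, INS}, planted hits that appear verbatim
as dataset rows and planted misses whose encodings appear nowhere.
Ground truth is recorded at generation time and independently checked
against a brute-force membership oracle.

What passing these tests establishes: the protocol's verdicts equal
exact set membership — zero false positives and negatives — under every
in-bounds parameter set tried, and every count (ciphertexts, operations,
depth) matches its closed form. What they do not establish: behavior on
real-world VCF complexity outside the schema (genotype columns,
structural variants beyond SVTYPE, multi-allelic normalization —
explicitly out of scope), allele-frequency realism (irrelevant to
exact matching), or the performance of an actual HE backend.

A note on the chromosome field: the schema accepts labels 1–22, X, Y
(codes 1–24 in 5 bits). Descriptions of the field as ranging from 0
upward exist; whether 0 is a real label or an off-by-one is unclear, so
the codec accepts 1–22 plus X/Y and this choice is noted rather than
silently widened.

## Test problem sizes

The randomized end-to-end suite runs 10³ instances at n ∈ {16, 32, 64},
t = 65537 (one prime valid for all test ring sizes), d = 3, 12-bit toy
records — small enough that brute force is instant and the whole sweep
takes seconds, large enough to exercise multi-batch hashing, packing and
both sentinel roles. The operation/depth grid covers (ℓ, B) ∈ [1, 16]².
The hashing estimator runs 10³ trials at the reference operating point
(n = 8192, d = 4, N′ = 7700) and observes zero failures, consistent with
a failure rate well below 10⁻³ at that load. Ciphertext-count checks use
real pipeline runs at N = 10⁴ and 10⁵ records.

## Known limitations

- The reference backend proves nothing about noise growth; a parameter
  set that is arithmetic-safe here may still need a larger *q* in a real
  scheme.
- Capacity lines cover only the nine calibrated (d, n) pairs; other
  pairs raise instead of extrapolating.
- The `{A, empty} → 0` symbol collapse is inherited from the record
  encoding: a deletion-with-empty-ALT and the same position with ALT=A
  are indistinguishable after encoding.
- Queries are SNP lookups; SUB/INS rows are dropped at parse time and
  can never match.
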