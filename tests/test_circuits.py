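"""CAM, CMA and CA circuit semantics, costs, and decoding."""

import numpy as np
import pytest

from _oracles import hamming_rows, membership_verdicts
from hequery.circuits import (
    BoundViolation,
    ca_eval,
    cam_decode,
    cam_eval,
    cma_eval,
    layout_direct,
    layout_hashed_dataset,
    layout_hashed_query,
    layout_query_direct,
)
from hequery.cuckoo import HashSeeds, hash_dataset, pack_multiquery
from hequery.simd_backend import OpLedger, SlotVector, derive_params


def _direct_instance(rng, n, t, B, ell, b=2):
    """Random direct-mode digit matrix with its params."""
    p = derive_params(n=n, t=t, d=3, b=b, ell=ell)
    L = ell if b == 2 else None
    rows = rng.integers(0, b, size=(B * n, ell))
    return p, rows


def _hashed_instance(rng, n=32, d=3, ell=10, b=4, N=12, k=3, hits=1):
    """Hashed toy instance: records, queries with planted hits, layouts."""
    p = derive_params(n=n, t=65537, d=d, b=b, ell=ell, N_prime=max(N, 1))
    records = [int(v) for v in rng.choice(2**ell, size=N + k, replace=False)]
    dataset, extra = records[:N], records[N:]
    queries = list(rng.choice(dataset, size=hits, replace=False).astype(int)) \
        if hits else []
    queries += extra[: k - hits]
    seeds = HashSeeds.generate(d, rng)
    tables = hash_dataset(dataset, p, seeds, rng)
    packed = pack_multiquery(queries, k, p, seeds)
    return p, dataset, queries, seeds, tables, packed


class TestCamCosts:
    def test_operation_counts_and_depth_for_13_batches(self, rng):
        # (2*3-1)*13 = 65 adds, 3*13 = 39 squares, 12 mults, depth 5
        p = derive_params(n=8, t=65537, d=3, b=2, ell=3)
        ds = layout_direct(rng.integers(0, 2, size=(13 * 8, 3)), p)
        q = layout_query_direct([0, 1, 0], p)
        led = OpLedger()
        out = cam_eval(ds, q, led)
        assert (led.adds, led.squares, led.mults) == (65, 39, 12)
        assert out.depth == 5

    def test_bound_violation_is_refused(self, rng):
        p = derive_params(n=8, t=17, d=3, b=2, ell=20)  # t = 17 <= ell = 20
        ds = layout_direct(rng.integers(0, 2, size=(8, 20)), p)
        q = layout_query_direct([0] * 20, p)
        with pytest.raises(BoundViolation):
            cam_eval(ds, q)


class TestCamDirect:
    def test_matching_row_slot_decodes_to_zero(self, rng):
        p = derive_params(n=8, t=65537, d=3, b=2, ell=6)
        rows = rng.integers(0, 2, size=(8, 6))
        ds = layout_direct(rows, p)
        q = layout_query_direct(list(rows[3]), p)
        out = cam_eval(ds, q)
        assert out.slots[3] == 0

    def test_zero_slots_reproduce_brute_force_membership(self, rng):
        for _ in range(20):
            p = derive_params(n=16, t=65537, d=3, b=2, ell=8)
            rows = rng.integers(0, 2, size=(3 * 16, 8))
            q_bits = rows[int(rng.integers(0, 48))] if rng.random() < 0.5 \
                else rng.integers(0, 2, size=8)
            ds = layout_direct(rows, p)
            out = cam_eval(ds, layout_query_direct(list(q_bits), p))
            for k in range(16):
                slot_rows = rows[[k, k + 16, k + 32]]  # rows sharing slot k
                expect_zero = any(np.array_equal(r, q_bits) for r in slot_rows)
                assert (out.slots[k] == 0) == expect_zero

    def test_padding_rows_never_match(self, rng):
        # N=10 rows at n=8: 6 padded rows filled with the impossible digit b;
        # zero-filled padding would falsely match an all-zero query
        p = derive_params(n=8, t=65537, d=3, b=2, ell=4)
        rows = np.ones((10, 4), dtype=np.int64)
        ds = layout_direct(rows, p)
        assert ds.B == 2
        out = cam_eval(ds, layout_query_direct([0, 0, 0, 0], p))
        assert np.all(out.slots != 0)


class TestCamHashed:
    def test_planted_hits_decode_exactly(self, rng):
        for _ in range(20):
            p, dataset, queries, seeds, tables, packed = _hashed_instance(
                rng, k=5, hits=2, N=14
            )
            ds = layout_hashed_dataset(tables, p)
            q = layout_hashed_query(packed, p)
            results = [cam_eval(ds, row) for row in q.data]
            res = cam_decode(results, packed.placement, "hashed", k=packed.k)
            assert res.verdicts == membership_verdicts(dataset, queries)
            assert res.match_count == sum(
                v == "MATCH" for v in res.verdicts
            )  # distinct rows: at most one zero per query

    def test_all_nonzero_means_no_match(self):
        sv = SlotVector.encrypt([5, 3, 9], 17)
        res = cam_decode([sv], {(0, 0): (0, 1)}, "hashed", k=1)
        assert res.verdicts == ["NO-MATCH"]

    def test_zero_outside_placement_is_integrity_error(self):
        sv = SlotVector.encrypt([0, 3, 9], 17)
        with pytest.raises(RuntimeError, match="integrity"):
            cam_decode([sv], {(0, 0): (0, 1)}, "hashed", k=1)


class TestCma:
    def test_operation_counts_and_depth_for_13_batches(self, rng):
        # (ell+1)B - 1 = 51 adds, ell*B = 39 squares, (ell-1)B = 26 mults
        p = derive_params(n=8, t=65537, d=3, b=2, ell=3)
        ds = layout_direct(rng.integers(0, 2, size=(13 * 8, 3)), p)
        q = layout_query_direct([1, 0, 1], p)
        led = OpLedger()
        out = cma_eval(ds, q, ledger=led)
        assert (led.adds, led.squares, led.mults) == (51, 39, 26)
        assert out.depth == 3  # 1 + ceil(log2 3)

    def test_slot_sum_counts_all_matches(self, rng):
        p = derive_params(n=8, t=65537, d=3, b=2, ell=5)
        rows = rng.integers(0, 2, size=(24, 5))
        target = rng.integers(0, 2, size=5)
        plant = rng.choice(24, size=3, replace=False)
        rows[plant] = target
        ds = layout_direct(rows, p)
        out = cma_eval(ds, layout_query_direct(list(target), p))
        matches = sum(np.array_equal(r, target) for r in rows)
        assert int(out.slots.sum()) == matches

    def test_masked_cma_agrees_with_membership_on_hashed_toys(self, rng):
        for _ in range(20):
            p, dataset, queries, seeds, tables, packed = _hashed_instance(
                rng, b=2, k=4, hits=2, N=12
            )
            ds = layout_hashed_dataset(tables, p, with_masks=True)
            q = layout_hashed_query(packed, p, with_masks=True)
            matched = set()
            total = 0
            for tbl_idx, row in enumerate(q.data):
                out = cma_eval(ds, row, q_mask=q.masks[tbl_idx])
                total += int(out.slots.sum())
                for s in np.flatnonzero(out.slots != 0):
                    for (qi, _i), ref in packed.placement.items():
                        if ref == (tbl_idx, int(s)):
                            matched.add(qi)
            verdicts = ["MATCH" if qi in matched else "NO-MATCH"
                        for qi in range(len(queries))]
            assert verdicts == membership_verdicts(dataset, queries)
            assert total == sum(v == "MATCH" for v in verdicts)

    def test_all_zero_query_mask_zeroes_the_result(self, rng):
        p, dataset, queries, seeds, tables, packed = _hashed_instance(
            rng, b=2, k=2, hits=1
        )
        ds = layout_hashed_dataset(tables, p, with_masks=True)
        q = layout_hashed_query(packed, p, with_masks=True)
        zero_mask = SlotVector.encrypt(np.zeros(p.n, dtype=np.int64), p.t)
        out = cma_eval(ds, q.data[0], q_mask=zero_mask)
        assert not out.slots.any()

    def test_missing_masks_in_hashed_mode_are_rejected(self, rng):
        p, dataset, queries, seeds, tables, packed = _hashed_instance(
            rng, b=2, k=2, hits=1
        )
        ds = layout_hashed_dataset(tables, p, with_masks=False)
        q = layout_hashed_query(packed, p, with_masks=False)
        with pytest.raises(ValueError, match="mask"):
            cma_eval(ds, q.data[0])


class TestCa:
    def test_slots_hold_brute_force_hamming_distances(self, rng):
        p = derive_params(n=16, t=65537, d=3, b=2, ell=12)
        rows = rng.integers(0, 2, size=(16, 12))
        q_bits = rng.integers(0, 2, size=12)
        ds = layout_direct(rows, p)
        out = ca_eval(ds, layout_query_direct(list(q_bits), p))
        assert out.depth == 1
        assert list(out.slots) == list(hamming_rows(rows, q_bits))

    def test_identical_row_gives_distance_zero(self, rng):
        p = derive_params(n=8, t=65537, d=3, b=2, ell=6)
        rows = rng.integers(0, 2, size=(8, 6))
        out = ca_eval(layout_direct(rows, p), layout_query_direct(list(rows[2]), p))
        assert out.slots[2] == 0

    def test_complement_row_gives_distance_ell(self, rng):
        p = derive_params(n=8, t=65537, d=3, b=2, ell=6)
        rows = rng.integers(0, 2, size=(8, 6))
        out = ca_eval(layout_direct(rows, p),
                      layout_query_direct(list(1 - rows[4]), p))
        assert out.slots[4] == 6

    def test_multiple_batches_are_rejected(self, rng):
        p = derive_params(n=8, t=65537, d=3, b=2, ell=6)
        ds = layout_direct(rng.integers(0, 2, size=(16, 6)), p)
        with pytest.raises(ValueError, match="B=1"):
            ca_eval(ds, layout_query_direct([0] * 6, p))


class TestWraparound:
    def test_unsafe_modulus_fabricates_a_match(self, rng):
        """With t <= ell, a maximally distant row wraps to a zero slot."""
        from hequery.synthdata import gen_adversarial

        p_tmp = derive_params(n=8, t=65537, d=3, b=2, ell=13)
        adv = gen_adversarial("wraparound", p_tmp)
        t_unsafe = adv["t_unsafe"]  # == ell
        rows = np.tile(adv["row_bits"], (8, 1))
        # bypass layout's bound refusal: evaluate the sum manually mod t
        diffs = (rows - np.array(adv["query_bits"])[None, :]) % t_unsafe
        wrapped = (diffs**2).sum(axis=1) % t_unsafe
        assert np.all(wrapped == 0)  # every slot falsely signals MATCH
        # and the circuit itself refuses to run at this modulus
        p_bad = derive_params(n=8, t=t_unsafe, d=3, b=2, ell=13)
        ds = layout_direct(rows, p_bad)
        with pytest.raises(BoundViolation):
            cam_eval(ds, layout_query_direct(adv["query_bits"], p_bad))

    def test_near_miss_is_no_match_in_cam_and_distance_one_in_ca(self, rng):
        from hequery.synthdata import gen_adversarial

        p = derive_params(n=8, t=65537, d=3, b=2, ell=12)
        adv = gen_adversarial("near-miss", p)
        row_bits = [(adv["row"] >> j) & 1 for j in range(12)]
        q_bits = [(adv["query"] >> j) & 1 for j in range(12)]
        rows = np.tile(row_bits, (8, 1))
        ds = layout_direct(rows, p)
        cam_out = cam_eval(ds, layout_query_direct(q_bits, p))
        assert np.all(cam_out.slots != 0)
        ca_out = ca_eval(ds, layout_query_direct(q_bits, p))
        assert np.all(ca_out.slots == 1)


class TestCrossCircuit:
    def test_cma_slot_sum_equals_cam_zero_count(self, rng):
        for _ in range(10):
            p, dataset, queries, seeds, tables, packed = _hashed_instance(
                rng, b=2, k=4, hits=2, N=12
            )
            ds_cam = layout_hashed_dataset(tables, p)
            ds_cma = layout_hashed_dataset(tables, p, with_masks=True)
            q_cam = layout_hashed_query(packed, p)
            q_cma = layout_hashed_query(packed, p, with_masks=True)
            cam_zeros = 0
            cma_sum = 0
            for tbl_idx in range(packed.B_X):
                cam_out = cam_eval(ds_cam, q_cam.data[tbl_idx])
                placed = {s for (qi, i), (ti, s) in packed.placement.items()
                          if ti == tbl_idx}
                cam_zeros += sum(
                    1 for s in placed if cam_out.slots[s] == 0
                )
                cma_out = cma_eval(ds_cma, q_cma.data[tbl_idx],
                                   q_mask=q_cma.masks[tbl_idx])
                cma_sum += int(cma_out.slots.sum())
            assert cma_sum == cam_zeros
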