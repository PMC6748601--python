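"""Best-match search: index vs exhaustive oracle, tie-breaking, planted
recovery, streaming profile and pairwise identities."""

import numpy as np
import pytest

from abmatch import (
    Chain,
    Mode,
    best_match,
    build_index,
    exhaustive_best_match,
    extract_cdrs,
    pairs_above,
    pairwise_within_set,
    positional_identity,
    streaming_best_matches,
)
from abmatch.simulate import PlantedQuerySpec, SyntheticConfig, generate_repertoire, plant_queries

from conftest import make_chain

ALL_MODES = (Mode.FULL_CHAIN, Mode.CDR_TRIPLET, Mode.CDRH3)


def assert_same_result(a, b):
    assert (a is None) == (b is None)
    if a is not None:
        assert a.exact == b.exact
        assert a.best_template_id == b.best_template_id
        assert a.tie_count == b.tie_count


class TestIndex:
    def test_chain_partitions(self, small_repertoire):
        light = [g.numbered for g in generate_repertoire(
            SyntheticConfig(n_records=3, chain=Chain.LIGHT, seed=5, study_id="SYN2"))]
        index = build_index(small_repertoire[:3] + light[:2])
        assert len(index.by_chain[Chain.HEAVY]) == 3
        assert len(index.by_chain[Chain.LIGHT]) == 2

    def test_equal_cdrh3_bucketed_together(self):
        a = make_chain("A" * 120, record_id="a")
        b = make_chain("A" * 120, record_id="b")
        index = build_index([a, b])
        cdr3 = extract_cdrs(a)[2]
        assert len(index.cdrh3_exact[(Chain.HEAVY, cdr3)]) == 2

    def test_empty_index_returns_no_match(self):
        index = build_index([])
        q = make_chain("EVQLV")
        assert all(best_match(q, index, m) is None for m in ALL_MODES)

    def test_every_record_in_exactly_one_length_bucket(self, small_repertoire):
        index = build_index(small_repertoire)
        total = sum(len(v) for v in index.by_cdr_lengths.values())
        assert total == len(small_repertoire)


class TestOracleEquivalence:
    def test_identical_template_found(self, small_repertoire):
        q = small_repertoire[7]
        index = build_index(small_repertoire)
        res = best_match(q, index, Mode.FULL_CHAIN)
        assert res.best_value == 1.0

    @pytest.mark.parametrize("mode", ALL_MODES)
    def test_matches_plain_scan(self, small_repertoire, mode):
        index = build_index(small_repertoire)
        queries, _ = plant_queries(
            small_repertoire, [PlantedQuerySpec(i * 23, k, seed=i) for i, k in
                               enumerate([0, 1, 3, 6, 12, 20])]
        )
        for q in queries:
            assert_same_result(
                best_match(q, index, mode),
                exhaustive_best_match(q, small_repertoire, mode),
            )

    def test_single_record_repertoire(self):
        t = make_chain("EVQLVESGG", record_id="only")
        q = make_chain("EVQLVESGA", record_id="q")
        res = exhaustive_best_match(q, [t], Mode.FULL_CHAIN)
        assert res.best_template_id == "only"
        assert res.matches == 8

    def test_empty_repertoire(self):
        assert exhaustive_best_match(make_chain("EVQ"), [], Mode.FULL_CHAIN) is None

    def test_tie_broken_to_earliest_insertion(self):
        t1 = make_chain("AAAA", record_id="first")
        t2 = make_chain("AAAA", record_id="second")
        q = make_chain("AAAT", record_id="q")
        for finder in (
            lambda: best_match(q, build_index([t1, t2]), Mode.FULL_CHAIN),
            lambda: exhaustive_best_match(q, [t1, t2], Mode.FULL_CHAIN),
        ):
            res = finder()
            assert res.best_template_id == "first"
            assert res.tie_count == 2

    def test_cdrh3_absent_length_gives_no_match(self, small_repertoire):
        lengths = {len(extract_cdrs(t)[2]) for t in small_repertoire}
        missing = next(l for l in range(1, 40) if l not in lengths)
        # build a query whose CDR3 length is absent from the repertoire
        from abmatch import ImgtPosition, NumberedChain
        from abmatch.imgt import junction_positions
        residues = {ImgtPosition(i): "A" for i in range(1, 105)}
        for pos in junction_positions(missing):
            residues[pos] = "G"
        q = NumberedChain(record_id="q", chain=Chain.HEAVY, residues=residues)
        index = build_index(small_repertoire)
        assert best_match(q, index, Mode.CDRH3) is None
        assert exhaustive_best_match(q, small_repertoire, Mode.CDRH3) is None


class TestPlantedRecovery:
    def test_exact_recovery_with_separation(self, small_repertoire):
        specs = [PlantedQuerySpec(i * 40, 6, seed=900 + i) for i in range(10)]
        queries, answers = plant_queries(small_repertoire, specs)
        index = build_index(small_repertoire)
        for q, ans in zip(queries, answers):
            res = best_match(q, index, Mode.FULL_CHAIN)
            assert res.best_template_id == ans.template_id
            assert res.best_value == pytest.approx(ans.expected_identity, abs=1e-12)


class TestStreamingProfile:
    @pytest.mark.parametrize("early_exit", [True, False])
    def test_matches_exhaustive(self, small_repertoire, early_exit):
        repertoire = small_repertoire[:120]
        queries, _ = plant_queries(repertoire, [PlantedQuerySpec(i * 11, 4, seed=i)
                                                for i in range(5)])
        found = streaming_best_matches(queries, repertoire, ALL_MODES,
                                       early_exit=early_exit)
        for q in queries:
            for mode in ALL_MODES:
                assert_same_result(
                    found[(q.record_id, mode)],
                    exhaustive_best_match(q, repertoire, mode),
                )


class TestPairwise:
    def test_metric_properties(self, small_repertoire):
        chains = small_repertoire[:20]
        mat = pairwise_within_set(chains)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)
        # equals nested metric calls
        for i in range(0, 20, 7):
            for j in range(1, 20, 5):
                assert mat[i, j] == pytest.approx(
                    positional_identity(chains[i], chains[j]).value)

    def test_identical_pair_reported_once(self):
        a = make_chain("EVQLV", record_id="a")
        b = make_chain("EVQLV", record_id="b")
        pairs = pairs_above([a, b], 0.9)
        assert len(pairs) == 1 and pairs[0][:2] == ("a", "b")

    def test_requires_two_chains_of_one_type(self):
        with pytest.raises(ValueError):
            pairwise_within_set([make_chain("EVQ")])
        with pytest.raises(ValueError):
            pairwise_within_set(
                [make_chain("EVQ"), make_chain("EVQ", chain=Chain.LIGHT)])
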