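import numpy as np
import pandas as pd
import pytest

from mirtide.enrichment import (
    intersect_targets,
    ora_test,
    read_gmt,
    read_target_table,
    union_targets,
    write_gmt,
    write_target_table,
)

from _oracles import bh_adjust_direct, hypergeom_tail_by_enumeration


def _tables():
    scored = pd.DataFrame(
        {"mirna": ["m1", "m1", "m2"], "gene": ["gA", "gB", "gC"], "score": [85.0, 70.0, 80.0]}
    )
    unscored = pd.DataFrame({"mirna": ["m1", "m1", "m2"], "gene": ["gA", "gB", "gC"]})
    return scored, unscored


def test_intersection_applies_inclusive_score_rule():
    scored, unscored = _tables()
    targets = intersect_targets(scored, unscored)
    assert targets["m1"] == {"gA"}  # gB scores 70 < 80
    assert targets["m2"] == {"gC"}  # score exactly 80 is included


def test_disjoint_tables_give_empty_sets():
    scored, _ = _tables()
    unscored = pd.DataFrame({"mirna": ["m9"], "gene": ["gZ"]})
    targets = intersect_targets(scored, unscored)
    assert all(len(v) == 0 for v in targets.values())


def test_threshold_monotonicity_never_adds_genes(rng):
    mirnas = [f"m{i}" for i in range(5)]
    genes = [f"g{i}" for i in range(30)]
    rows = [
        (m, g, float(rng.uniform(50, 100)))
        for m in mirnas
        for g in rng.choice(genes, size=10, replace=False)
    ]
    scored = pd.DataFrame(rows, columns=["mirna", "gene", "score"])
    unscored = scored[["mirna", "gene"]].sample(frac=0.8, random_state=1)
    prev = None
    for tau in (0.0, 50.0, 80.0, 95.0, 100.0):
        current = intersect_targets(scored, unscored, score_threshold=tau)
        if tau == 0.0:
            # vacuous threshold: plain table intersection
            plain = scored.merge(unscored, on=["mirna", "gene"])
            assert union_targets(current) == set(plain["gene"])
        if prev is not None:
            for m in current:
                assert current[m] <= prev[m]
        prev = current
    with pytest.raises(ValueError):
        intersect_targets(scored, unscored, score_threshold=101.0)


def test_duplicate_pairs_and_bad_scores_are_rejected():
    scored = pd.DataFrame({"mirna": ["m", "m"], "gene": ["g", "g"], "score": [90.0, 91.0]})
    unscored = pd.DataFrame({"mirna": ["m"], "gene": ["g"]})
    with pytest.raises(ValueError, match="duplicate"):
        intersect_targets(scored, unscored)
    scored2 = pd.DataFrame({"mirna": ["m"], "gene": ["g"], "score": [120.0]})
    with pytest.raises(ValueError, match="\\[0, 100\\]"):
        intersect_targets(scored2, unscored)


def test_hypergeometric_p_matches_exhaustive_enumeration():
    """For universes of <= 25 genes, the upper-tail p equals the fraction of
    all possible query draws with at least the observed overlap."""
    cases = [(20, 5, 5, 5), (20, 5, 5, 2), (15, 6, 4, 1), (12, 4, 6, 3), (25, 8, 4, 0)]
    universe = [f"g{i}" for i in range(25)]
    for M, K, n, k in cases:
        genes = universe[:M]
        sets = {"S": genes[:K]}
        query = genes[:k] + genes[K : K + (n - k)]
        result = ora_test(query, sets, universe=genes)
        oracle = hypergeom_tail_by_enumeration(M, K, n, k)
        assert result.loc[0, "p_value"] == pytest.approx(oracle, abs=1e-12)
        assert result.loc[0, ["overlap", "query_size", "set_size", "universe_size"]].tolist() == [
            k, n, K, M
        ]


def test_full_overlap_in_small_universe_is_one_over_choose():
    from math import comb

    genes = [f"g{i}" for i in range(20)]
    result = ora_test(genes[:5], {"S": genes[:5]}, universe=genes)
    assert result.loc[0, "p_value"] == pytest.approx(1.0 / comb(20, 5), abs=1e-15)


def test_zero_overlap_gives_p_of_one():
    genes = [f"g{i}" for i in range(10)]
    result = ora_test(genes[5:8], {"S": genes[:3], "T": genes[5:8]}, universe=genes)
    row = result.set_index("set_name").loc["S"]
    assert row["overlap"] == 0
    assert row["p_value"] == pytest.approx(1.0)


def test_bh_adjustment_matches_direct_computation(rng):
    # the classic staircase: [0.01, 0.02, 0.03] all adjust to 0.03
    assert np.allclose(bh_adjust_direct([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    genes = [f"g{i}" for i in range(24)]
    sets = {f"S{j}": list(rng.choice(genes, size=6, replace=False)) for j in range(8)}
    result = ora_test(genes[:6], sets, universe=genes)
    oracle = bh_adjust_direct(result["p_value"].to_numpy())
    assert np.allclose(result["adjusted_p"].to_numpy(), oracle, atol=1e-12)
    assert (result["adjusted_p"].to_numpy() >= result["p_value"].to_numpy() - 1e-15).all()
    # sorted by adjusted p ascending, ties by name
    adj = result["adjusted_p"].to_numpy()
    assert (np.diff(adj) >= -1e-15).all()


def test_query_outside_universe_warns_and_empty_inputs_raise():
    genes = [f"g{i}" for i in range(10)]
    with pytest.warns(UserWarning, match="outside the universe"):
        ora_test(genes[:2] + ["NOT_A_GENE"], {"S": genes[:5]}, universe=genes)
    with pytest.raises(ValueError, match="empty query"):
        ora_test([], {"S": genes[:5]})
    with pytest.raises(ValueError, match="no gene sets"):
        ora_test(genes[:2], {})


def test_gmt_and_target_tables_round_trip(tmp_path):
    sets = {"PATH_A": ["g1", "g2", "g3"], "PATH_B": ["g2", "g4"]}
    write_gmt(sets, tmp_path / "sets.gmt")
    assert read_gmt(tmp_path / "sets.gmt") == sets
    scored, _ = _tables()
    write_target_table(scored, tmp_path / "scored.tsv")
    back = read_target_table(tmp_path / "scored.tsv", scored=True)
    pd.testing.assert_frame_equal(back, scored)
    with pytest.raises(ValueError, match="malformed"):
        (tmp_path / "bad.gmt").write_text("name_only\n")
        read_gmt(tmp_path / "bad.gmt")
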