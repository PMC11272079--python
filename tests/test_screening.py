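"""Gene screens: fold thresholds, branch attribution, saturation,
ranking, overlap and exclusive upregulation."""

import numpy as np
import pandas as pd
import pytest

from ovorate import datasets
from ovorate import simulate as sim
from ovorate.ratetable import BranchRateRecord, GenomeRateTable, OmegaCode, make_record
from ovorate.screening import (
    ConfigError,
    UndefinedMaxError,
    branch_max,
    exclusive_upregulation,
    fold_screen,
    fold_screen_with_trace,
    hawaiian_branch_screen,
    overlap_screen,
    rank_top_upregulated,
    saturation_filter,
)


def _table_with_planted(n=400, seed=6, planted_omega=0.5, n_planted=50):
    planted = {f"G{g:05d}": planted_omega for g in range(n_planted)}
    return (
        sim.simulate_genome_rates(n_genes=n, seed=seed, m0_median=0.10, planted=planted),
        set(planted),
    )


def test_fold_screen_recovers_planted_genes_exactly():
    table, planted = _table_with_planted()
    # empirical median stays near 0.10 << 0.5/1.5, so planted genes separate
    vals = table.m0["omega"].to_numpy()
    median = np.median(vals)
    expected = {g for g, w in zip(table.m0["gene_id"], vals) if w >= 1.5 * median}
    assert fold_screen(table, 1.5, scope="m0") == expected
    assert planted <= expected


def test_fold_screen_monotone_in_threshold():
    table, _ = _table_with_planted()
    inner = fold_screen(table, 2.2)
    outer = fold_screen(table, 1.5)
    assert inner <= outer


def test_fold_screen_trace_reevaluates_to_passed():
    table, _ = _table_with_planted(n=100)
    for res in fold_screen_with_trace(table, 1.5):
        assert res.reevaluate() == res.passed
        assert res.criteria_trace


def test_fold_screen_row_order_invariant():
    table, _ = _table_with_planted(n=120)
    rng = np.random.default_rng(0)
    shuffled = GenomeRateTable(
        table.m0.sample(frac=1.0, random_state=1),
        table.branches.sample(frac=1.0, random_state=2),
    )
    assert fold_screen(table, 1.5) == fold_screen(shuffled, 1.5)


def test_gt1_sentinel_passes_any_branch_threshold():
    recs = [
        make_record("g1", "b1", 0.02, 1e-6),  # GT1
        make_record("g2", "b1", 0.01, 0.1),  # omega 0.1
    ]
    table = GenomeRateTable.from_records(recs, {"g1": 0.1, "g2": 0.1})
    assert "g1" in fold_screen(table, 3.0, scope="any_branch")
    assert "g2" not in fold_screen(table, 3.0, scope="any_branch")


def test_hawaiian_screen_thresholds_and_boundaries():
    # Dmur median set high enough that its fold threshold (0.375) is above
    # the absolute cut, isolating the strict-inequality boundary at 0.33
    medians = {"Dmur": 0.25, "Dspr": 0.164, "Dgri": 0.160}
    recs = [
        make_record("at_cut", "Dmur", 0.33, 1.0),  # omega exactly 0.33
        make_record("above_cut", "Dmur", 0.34, 1.0),
        make_record("fold_pass", "Dspr", 0.246, 1.0),  # 1.5 x 0.164
        make_record("low", "Dgri", 0.05, 1.0),
    ]
    table = GenomeRateTable.from_records(recs, {r.gene_id: 0.1 for r in recs})
    got = hawaiian_branch_screen(table, 0.33, 1.5, medians)
    assert got == {"above_cut", "fold_pass"}  # 0.33 fails the strict cut


def test_hawaiian_screen_missing_median_is_config_error():
    recs = [make_record("g", "Dxxx", 0.1, 0.2)]
    table = GenomeRateTable.from_records(recs, {"g": 0.1})
    with pytest.raises(ConfigError):
        hawaiian_branch_screen(table, 0.33, 1.5, {"Dmur": 0.15})


def test_branch_max_published_upd2_row():
    """upd2: (-, 0.4168, 0.0347, 0.0793, 0.1667) -> Dsec carries the max."""
    records = datasets.gene_branch_records("FBgn0030904")
    assert branch_max(records) == {"Dsec"}


def test_branch_max_gt1_dominates_and_ties_return_all():
    recs = [
        BranchRateRecord("g", "b1", np.nan, np.nan, OmegaCode.GT1),
        BranchRateRecord("g", "b2", np.nan, np.nan, OmegaCode.VALUE, 0.99),
    ]
    assert branch_max(recs) == {"b1"}
    ties = [
        BranchRateRecord("g", "b1", np.nan, np.nan, OmegaCode.VALUE, 0.5),
        BranchRateRecord("g", "b2", np.nan, np.nan, OmegaCode.VALUE, 0.5),
    ]
    assert branch_max(ties) == {"b1", "b2"}
    only_lowdiv = [BranchRateRecord("g", "b1", np.nan, np.nan, OmegaCode.LOWDIV)]
    with pytest.raises(UndefinedMaxError):
        branch_max(only_lowdiv)


def test_saturation_filter_partitions_records():
    recs = [
        make_record("ok", "b", 0.2, 0.4),
        make_record("sat", "b", 1.6, 0.3),
        make_record("low", "b", 0.0005, 0.0004),
    ]
    out = saturation_filter(recs, cap=1.5)
    assert [r.gene_id for r in out.kept] == ["ok"]
    assert [r.gene_id for r in out.saturated] == ["sat"]
    assert [r.gene_id for r in out.low_divergence] == ["low"]


def _de_frame():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5"],
            "context": ["soma", "soma", "soma", "soma", "germ"],
            "log2_fold_change": [10.012, 9.389, 9.389, -2.0, 5.0],
            "p_value": [1e-6, 1e-5, 1e-5, 1e-6, 1e-6],
            "direction": ["up", "up", "up", "down", "up"],
        }
    )


def test_rank_top_upregulated_orders_and_breaks_ties_by_gene_id():
    de = _de_frame()
    assert rank_top_upregulated(de, "soma", 10) == ["g1", "g2", "g3"]
    # permuting rows leaves the result unchanged
    permuted = de.sample(frac=1.0, random_state=3)
    assert rank_top_upregulated(permuted, "soma", 10) == ["g1", "g2", "g3"]
    with pytest.raises(KeyError):
        rank_top_upregulated(de, "unknown", 3)


def test_overlap_screen_planted_construction():
    """Exactly the genes satisfying all three gates are returned."""
    genes = [f"g{i}" for i in range(10)]
    m0 = dict.fromkeys(genes, 0.05)
    for g in ("g0", "g1", "g2", "g3", "g4"):
        m0[g] = 0.5  # rapid
    recs = [make_record(g, "b", m0[g] * 0.2, 0.2) for g in genes]
    rates = GenomeRateTable.from_records(recs, m0)
    bulk = {"early": ["g0", "g1", "g5"], "late": ["g2", "g3", "g4", "g6"]}
    sc = pd.DataFrame(
        {
            "gene_id": ["g0", "g1", "g2", "g3", "g4", "g5", "g6", "g4"],
            "context": ["TFa"] * 8,
            "log2_fold_change": [2.0] * 8,
            "p_value": [0.01, 0.01, 0.01, 0.2, 0.01, 0.01, 0.01, 0.5],
            "direction": ["up"] * 8,
        }
    )
    got = overlap_screen(bulk, sc, rates, omega_cut=0.20)
    assert got == {"g0", "g1", "g2", "g4"}
    # impossible omega cut empties the overlap
    assert overlap_screen(bulk, sc, rates, omega_cut=1e9) == set()
    assert overlap_screen({"early": []}, sc, rates) == set()


def test_exclusive_upregulation_pooling():
    pooling = {"SHa": "SH", "SHm": "SH", "TFa": "TF", "TFb": "TF"}
    de = pd.DataFrame(
        {
            "gene_id": ["a", "a", "b", "b", "c"],
            "context": ["SHa", "SHm", "SHa", "TFa", "TFb"],
            "log2_fold_change": [1.0] * 5,
            "p_value": [0.01] * 5,
            "direction": ["up"] * 5,
        }
    )
    groups = exclusive_upregulation(de, pooling)
    assert groups["SH"] == {"a"}  # up in SHa+SHm only
    assert groups["TF"] == {"c"}
    assert "b" not in groups["SH"] | groups["TF"]  # spans both groups


def test_exclusive_upregulation_recovers_planted_counts():
    """Planted instance sized to the published counts: 8 SH-exclusive and
    26 TF-exclusive genes come back exactly."""
    pooling = {"SHa": "SH", "SHm": "SH", "TFa": "TF", "TFb": "TF", "CC": "CC"}
    rows = []
    for i in range(8):
        rows.append((f"sh{i}", "SHa" if i % 2 else "SHm"))
    for i in range(26):
        rows.append((f"tf{i}", "TFa" if i % 2 else "TFb"))
        if i < 5:
            rows.append((f"tf{i}", "TFa"))  # second TF context stays exclusive
    for i in range(4):
        rows.append((f"mix{i}", "SHa"))
        rows.append((f"mix{i}", "CC"))
    de = pd.DataFrame(
        {
            "gene_id": [g for g, _ in rows],
            "context": [c for _, c in rows],
            "log2_fold_change": 1.0,
            "p_value": 0.01,
            "direction": "up",
        }
    )
    groups = exclusive_upregulation(de, pooling)
    assert len(groups["SH"]) == 8
    assert len(groups["TF"]) == 26
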