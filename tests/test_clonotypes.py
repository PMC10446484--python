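"""Clonotype calling and clonal statistics, checked against a set-based
brute-force oracle on small fixtures."""

import numpy as np
import pandas as pd
import pytest

from clonogem import ContigRecord, SimConfig, call_clonotypes, \
    clone_occupancy, clone_sharing, cluster_clonal_stats, \
    count_unique_clones, simulate_clonotypes
from clonogem.io_formats import contigs_to_frame


def rec(bc, chain="TRB", v="TRBV1", j="TRBJ1-1", nt="TGTAAA", prod=True,
        umis=5):
    return ContigRecord(barcode=bc, chain=chain, v_gene=v, j_gene=j,
                        cdr3_nt=nt, cdr3_aa="CASF", productive=prod,
                        umis=umis)


# ---------------------------------------------------------------------------
# brute-force oracle: pure python sets over (barcode, clone, cluster, cond)
# ---------------------------------------------------------------------------

def oracle_stats(cells):
    """cells: list of (barcode, clone, cluster, cond).  Returns per
    (cluster, cond): n, n_unique, pct_expanded, mean_clone_size."""
    out = {}
    conds = {c for *_, c in cells}
    for cond in conds:
        sub = [x for x in cells if x[3] == cond]
        sizes = {}
        for _, clone, _, _ in sub:
            sizes[clone] = sizes.get(clone, 0) + 1
        for k in {cl for _, _, cl, _ in sub}:
            members = [x for x in sub if x[2] == k]
            clones = {c for _, c, _, _ in members}
            expanded = [x for x in members if sizes[x[1]] >= 2]
            out[(k, cond)] = {
                "n": len(members),
                "n_unique": len(clones),
                "pct_expanded": 100.0 * len(expanded) / len(members),
                "mean_clone_size": sum(sizes[c] for c in clones) / len(clones),
            }
    return out


def oracle_sharing(cells):
    """Per cond: matrix[(i, j)] = pct of expanded cells in i whose clone has
    a cell in j; shared_any[i]."""
    out = {}
    for cond in {c for *_, c in cells}:
        sub = [x for x in cells if x[3] == cond]
        sizes = {}
        clone_clusters = {}
        for _, clone, cl, _ in sub:
            sizes[clone] = sizes.get(clone, 0) + 1
            clone_clusters.setdefault(clone, set()).add(cl)
        clusters = sorted({cl for _, _, cl, _ in sub})
        mat, any_ = {}, {}
        for ki in clusters:
            clonal = [x for x in sub if x[2] == ki and sizes[x[1]] >= 2]
            for kj in clusters:
                if ki == kj:
                    mat[(ki, kj)] = 100.0
                elif clonal:
                    mat[(ki, kj)] = 100.0 * sum(
                        kj in clone_clusters[x[1]] for x in clonal) / len(clonal)
                else:
                    mat[(ki, kj)] = 0.0
            any_[ki] = (100.0 * sum(len(clone_clusters[x[1]] - {ki}) > 0
                                    for x in clonal) / len(clonal)
                        if clonal else 0.0)
        out[cond] = (mat, any_)
    return out


# ---------------------------------------------------------------------------
# clonotype calling rules
# ---------------------------------------------------------------------------

def test_identical_trb_same_clone():
    a = call_clonotypes([rec("b1"), rec("b2")])
    assert a.barcode_to_clone["b1"] == a.barcode_to_clone["b2"]


def test_umi_majority_rule_and_tie_break():
    recs = [rec("b1", nt="TGTCCC", umis=7), rec("b1", nt="TGTAAA", umis=3)]
    a = call_clonotypes(recs)
    assert a.clone_keys[a.barcode_to_clone["b1"]][2] == "TGTCCC"
    # tie: lexicographically smallest cdr3_nt wins
    recs = [rec("b2", nt="TGTCCC", umis=5), rec("b2", nt="TGTAAA", umis=5)]
    a = call_clonotypes(recs)
    assert a.clone_keys[a.barcode_to_clone["b2"]][2] == "TGTAAA"


def test_nonproductive_ignored_and_unassigned_reported():
    recs = [rec("b1", prod=False), rec("b2")]
    a = call_clonotypes(recs)
    assert a.unassigned == ["b1"]
    assert "b2" in a.barcode_to_clone


def test_paired_mode_distinguishes_tra():
    recs = [rec("b1"), rec("b1", chain="TRA", v="TRAV1", j="TRAJ1",
                nt="TGTGGG"),
            rec("b2"), rec("b2", chain="TRA", v="TRAV2", j="TRAJ1",
                nt="TGTTTT")]
    trb_only = call_clonotypes(recs, mode="trb_only")
    paired = call_clonotypes(recs, mode="paired")
    assert trb_only.barcode_to_clone["b1"] == trb_only.barcode_to_clone["b2"]
    assert paired.barcode_to_clone["b1"] != paired.barcode_to_clone["b2"]


def test_per_condition_scope_splits_clones():
    recs = [rec("b1"), rec("b2")]
    a = call_clonotypes(recs, scope="per_condition",
                        conditions={"b1": "x", "b2": "y"})
    assert a.barcode_to_clone["b1"] != a.barcode_to_clone["b2"]


def test_planted_partition_recovered():
    cfg = SimConfig(n_cells=8, n_clusters=2, seed=1)
    contigs, truth = simulate_clonotypes(
        cfg, np.random.default_rng(0).integers(0, 2, 8))
    from clonogem.io_formats import read_contigs
    records = []
    for row in contigs.itertuples(index=False):
        records.append(ContigRecord(
            barcode=row.barcode, chain=row.chain, v_gene=row.v_gene,
            j_gene=row.j_gene, cdr3_nt=row.cdr3_nt, cdr3_aa=row.cdr3,
            productive=row.productive == "True", umis=row.umis))
    a = call_clonotypes(records)
    # same planted clone <=> same called clone
    for b1 in truth.clone_of_cell:
        for b2 in truth.clone_of_cell:
            same_truth = truth.clone_of_cell[b1] == truth.clone_of_cell[b2]
            same_called = a.barcode_to_clone[b1] == a.barcode_to_clone[b2]
            assert same_truth == same_called


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _assignment(clone_of):
    recs = [rec(bc, nt=f"TGT{'ACGT'[c % 4] * 3}{c:03d}")
            for bc, c in clone_of.items()]
    return call_clonotypes(recs)


def test_unique_clone_counts():
    # clones {3, 2, 1, 1} -> 4 unique
    clone_of = {"b1": 0, "b2": 0, "b3": 0, "b4": 1, "b5": 1, "b6": 2, "b7": 3}
    a = _assignment(clone_of)
    conds = {b: "c" for b in clone_of}
    assert count_unique_clones(a, conds)["c"] == 4


def test_worked_cluster_stats_fixture():
    """Cluster X: 3 cells of clone A (size 3), 1 cell of clone B (size 2,
    other cell elsewhere), 1 singleton -> 80% expanded, 3 unique clones,
    mean size 2.0."""
    clone_of = {"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1, "s1": 2}
    labels = {"a1": 0, "a2": 0, "a3": 0, "b1": 0, "s1": 0, "b2": 1}
    conds = {b: "c" for b in clone_of}
    a = _assignment(clone_of)
    stats = cluster_clonal_stats(a, labels, conds)
    row = stats[(stats["cluster_id"] == 0)].iloc[0]
    assert row["pct_expanded"] == pytest.approx(80.0)
    assert row["n_unique_clones"] == 3
    assert row["mean_clone_size"] == pytest.approx(2.0)


def test_all_singletons():
    clone_of = {f"b{i}": i for i in range(6)}
    labels = {f"b{i}": i % 2 for i in range(6)}
    conds = {b: "c" for b in clone_of}
    stats = cluster_clonal_stats(_assignment(clone_of), labels, conds)
    assert (stats["pct_expanded"] == 0).all()
    assert (stats["mean_clone_size"] == 1.0).all()


def test_sharing_worked_fixture():
    """One clone spans clusters 0 and 1; everything else private."""
    clone_of = {"x1": 0, "x2": 0, "y1": 1, "y2": 1, "s": 2}
    labels = {"x1": 0, "x2": 1, "y1": 0, "y2": 0, "s": 1}
    conds = {b: "c" for b in clone_of}
    sharing = clone_sharing(_assignment(clone_of), labels, conds)["c"]
    mat = sharing["matrix"]
    # cluster 0 clonal cells: x1 (clone spans 0,1), y1, y2 (private to 0)
    assert mat.loc[0, 1] == pytest.approx(100.0 / 3.0)
    assert mat.loc[0, 0] == 100.0
    assert sharing["pct_shared_any"][0] == pytest.approx(100.0 / 3.0)


def test_occupancy():
    clone_of = {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0, "f": 1}
    labels = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 2}
    occ = clone_occupancy(_assignment(clone_of), labels, 0)
    assert occ.to_dict() == {0: 3, 1: 2}
    assert occ.sum() == 5


def test_permutation_invariance():
    rng = np.random.default_rng(0)
    clone_of = {f"b{i}": int(rng.integers(0, 5)) for i in range(20)}
    labels = {f"b{i}": int(rng.integers(0, 3)) for i in range(20)}
    conds = {b: "c" for b in clone_of}
    a = _assignment(clone_of)
    base = cluster_clonal_stats(a, labels, conds)
    perm = {0: 2, 1: 0, 2: 1}
    permuted = cluster_clonal_stats(a, {b: perm[k] for b, k in labels.items()},
                                    conds)
    for k in (0, 1, 2):
        lhs = base[base["cluster_id"] == k].iloc[0]
        rhs = permuted[permuted["cluster_id"] == perm[k]].iloc[0]
        assert lhs["pct_expanded"] == rhs["pct_expanded"]
        assert lhs["mean_clone_size"] == rhs["mean_clone_size"]


@pytest.mark.parametrize("seed", range(10))
def test_bruteforce_oracle_equivalence(seed):
    """All five clonal operations agree with exhaustive set computations on
    random fixtures of <= 50 cells."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 51))
    cells = [(f"b{i}", int(rng.integers(0, max(2, n // 3))),
              int(rng.integers(0, 4)), str(rng.choice(["c1", "c2"])))
             for i in range(n)]
    clone_of = {bc: cl for bc, cl, _, _ in cells}
    labels = {bc: k for bc, _, k, _ in cells}
    conds = {bc: c for bc, _, _, c in cells}
    # scope clones per condition: clone ids must not bridge conditions in
    # the oracle either, so rebuild ids as (clone, cond) pairs
    cells = [(bc, (cl, cond), k, cond) for bc, cl, k, cond in cells]
    recs = [rec(bc, nt=f"TGT{cond}{cl:03d}")
            for bc, (cl, cond), _, _ in cells]
    a = call_clonotypes(recs)

    expected = oracle_stats(cells)
    stats = cluster_clonal_stats(a, labels, conds)
    for (k, cond), exp in expected.items():
        row = stats[(stats["cluster_id"] == k)
                    & (stats["condition"] == cond)].iloc[0]
        assert row["n_cells_with_tcr"] == exp["n"]
        assert row["n_unique_clones"] == exp["n_unique"]
        assert row["pct_expanded"] == pytest.approx(exp["pct_expanded"])
        assert row["mean_clone_size"] == pytest.approx(exp["mean_clone_size"])

    uniq = count_unique_clones(a, conds)
    for cond in set(conds.values()):
        exp_u = len({cl for _, cl, _, c in cells if c == cond})
        assert uniq[cond] == exp_u

    exp_sharing = oracle_sharing(cells)
    got = clone_sharing(a, labels, conds)
    for cond, (mat_exp, any_exp) in exp_sharing.items():
        mat = got[cond]["matrix"]
        for (ki, kj), v in mat_exp.items():
            assert mat.loc[ki, kj] == pytest.approx(v)
        for ki, v in any_exp.items():
            assert got[cond]["pct_shared_any"][ki] == pytest.approx(v)

    # occupancy conservation for every clone
    for clone_id in a.clone_keys:
        occ = clone_occupancy(a, labels, clone_id)
        size = sum(1 for bc, cl in a.barcode_to_clone.items()
                   if cl == clone_id)
        assert occ.sum() == size


def test_sum_of_cluster_counts_equals_global_size():
    cfg = SimConfig(n_cells=200, n_clusters=4, sharing_rate=0.3, seed=6)
    clusters = np.random.default_rng(3).integers(0, 4, 200)
    contigs, truth = simulate_clonotypes(cfg, clusters)
    for info in truth.clone_table.values():
        assert sum(info["occupancy"].values()) == info["size"]
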