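"""Fingerprints, Tanimoto similarity and Butina clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketclique.fixtures import BUILTIN_SMILES
from pocketclique.ligand_clustering import (
    ClusterTable,
    LigandRecord,
    N_BITS,
    build_cluster_table,
    cluster_ligands,
    fingerprint,
    make_records,
    read_cluster_table,
    resolve_backend,
    tanimoto,
    write_cluster_table,
)

BACKENDS_AVAILABLE = ["kgram"]
if resolve_backend("auto") == "rdkit":
    BACKENDS_AVAILABLE.append("rdkit")


class TestFingerprint:
    @pytest.mark.parametrize("backend", BACKENDS_AVAILABLE)
    def test_deterministic(self, backend):
        a = fingerprint("CCO", backend=backend)
        b = fingerprint("CCO", backend=backend)
        assert a is not None and np.array_equal(a, b)

    @pytest.mark.parametrize("backend", BACKENDS_AVAILABLE)
    def test_empty_smiles_flagged_invalid(self, backend):
        assert fingerprint("", backend=backend) is None

    @pytest.mark.parametrize("backend", BACKENDS_AVAILABLE)
    def test_benzene_differs_from_cyclohexane(self, backend):
        benzene = fingerprint("c1ccccc1", backend=backend)
        cyclohexane = fingerprint("C1CCCCC1", backend=backend)
        assert tanimoto(benzene, cyclohexane) < 1.0

    @pytest.mark.skipif("rdkit" not in BACKENDS_AVAILABLE, reason="no rdkit")
    def test_unparseable_smiles_flagged_under_chem_backend(self):
        assert fingerprint("not-a-molecule((", backend="rdkit") is None

    def test_builtin_smiles_all_parse(self):
        """The generator's SMILES pool is valid under every backend."""
        for backend in BACKENDS_AVAILABLE:
            for smi in BUILTIN_SMILES:
                assert fingerprint(smi, backend=backend) is not None


class TestTanimoto:
    def test_identical_vectors(self):
        v = np.zeros(8, bool)
        v[[1, 5]] = True
        assert tanimoto(v, v) == 1.0

    def test_disjoint_vectors(self):
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([0, 0, 1, 1], bool)
        assert tanimoto(a, b) == 0.0

    def test_hand_counted_example(self):
        # a=1100, b=1010: intersection 1, union 3
        a = np.array([1, 1, 0, 0], bool)
        b = np.array([1, 0, 1, 0], bool)
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_all_zero_pair_defined_as_one(self):
        z = np.zeros(16, bool)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(8, bool), np.zeros(4, bool))

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.lists(st.booleans(), min_size=1, max_size=64))
    def test_symmetry_and_range(self, xs, ys):
        n = min(len(xs), len(ys))
        a, b = np.array(xs[:n], bool), np.array(ys[:n], bool)
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)


def _block_records(n_per_block=5, n_blocks=2, flip=2, seed=0):
    """Block-structured fingerprints: dense within a block, disjoint across."""
    rng = np.random.default_rng(seed)
    records = []
    for b in range(n_blocks):
        base = np.zeros(N_BITS, bool)
        base[b * 200 : b * 200 + 60] = True
        for m in range(n_per_block):
            fp = base.copy()
            on = np.flatnonzero(fp)
            fp[rng.choice(on, size=flip, replace=False)] = False
            records.append(LigandRecord(f"B{b}M{m}", "synthetic", fp))
    return records


def _connected_components_at_threshold(records, threshold):
    """Union-find oracle: components of the Tanimoto-≥-threshold graph."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(records[i].fingerprint, records[j].fingerprint) >= threshold:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(records[i].ligand_code)
    return {frozenset(c) for c in comps.values()}


class TestClusterLigands:
    def test_identical_smiles_form_one_cluster(self):
        table = {"AAA": "CCO", "BBB": "CCO", "CCC": "CCO"}
        clusters = cluster_ligands(make_records(table))
        assert len(clusters) == 1
        assert clusters[0].members == {"AAA", "BBB", "CCC"}
        assert clusters[0].rel_size == 1.0

    def test_mutually_dissimilar_become_singletons(self):
        records = [
            LigandRecord("AAA", "x", np.eye(3, N_BITS, k=0, dtype=bool)[0]),
            LigandRecord("BBB", "y", np.eye(3, N_BITS, k=100, dtype=bool)[0]),
            LigandRecord("CCC", "z", np.eye(3, N_BITS, k=200, dtype=bool)[0]),
        ]
        clusters = cluster_ligands(records, sim_threshold=0.7)
        assert len(clusters) == 3
        assert all(c.rel_size == 1.0 for c in clusters)  # largest cluster = 1

    def test_two_block_fixture_recovered_exactly(self):
        """Two 5-member similarity blocks match the components oracle."""
        records = _block_records()
        clusters = cluster_ligands(records, sim_threshold=0.7)
        found = {frozenset(c.members) for c in clusters}
        assert found == _connected_components_at_threshold(records, 0.7)
        assert sorted(c.size for c in clusters) == [5, 5]
        assert all(c.rel_size == 1.0 for c in clusters)

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        records = _block_records(4, 3, flip=3) + [
            LigandRecord(f"R{i}", "r",
                         rng.random(N_BITS) < 0.02) for i in range(10)
        ]
        clusters = cluster_ligands(records, sim_threshold=0.6)
        all_members = [code for c in clusters for code in c.members]
        assert len(all_members) == len(set(all_members)) == len(records)

    def test_invalid_records_excluded(self):
        records = make_records({"AAA": "CCO", "BAD": ""})
        clusters = cluster_ligands(records)
        assert {m for c in clusters for m in c.members} == {"AAA"}

    def test_deterministic_across_runs(self):
        table = {f"L{i:02d}": BUILTIN_SMILES[i % len(BUILTIN_SMILES)]
                 for i in range(25)}
        a = cluster_ligands(make_records(table))
        b = cluster_ligands(make_records(table))
        assert a == b

    def test_rel_size_range_and_max(self):
        records = _block_records(5, 2) + _block_records(3, 1, seed=9)[:3]
        clusters = cluster_ligands(records, sim_threshold=0.7)
        assert all(0 < c.rel_size <= 1 for c in clusters)
        assert max(c.rel_size for c in clusters) == 1.0

    def test_total_normalization_option(self):
        table = {"AAA": "CCO", "BBB": "CCO", "CCC": "c1ccccc1"}
        clusters = cluster_ligands(make_records(table), norm="total")
        by_size = sorted(clusters, key=lambda c: c.size)
        assert by_size[-1].rel_size == pytest.approx(2 / 3)


class TestClusterTable:
    def test_fallback_for_unknown_ligand(self):
        table = build_cluster_table({"AAA": "CCO", "BBB": "CCO"})
        assert table.rel_size("AAA") == 1.0
        assert table.rel_size("ZZZ") == pytest.approx(1 / 2)  # singleton fallback

    def test_csv_roundtrip(self, tmp_path):
        table = build_cluster_table(
            {f"L{i}": BUILTIN_SMILES[i] for i in range(8)}
        )
        path = tmp_path / "clusters.csv"
        write_cluster_table(table, path)
        loaded = read_cluster_table(path)
        for code in table.rel_size_by_code:
            assert loaded.rel_size(code) == pytest.approx(table.rel_size(code))
        assert loaded.largest_size == table.largest_size
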