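"""Cross-link filtering, consensus, geometry, and conformer clustering."""

import numpy as np
import pandas as pd
import pytest

import aggscan as ag
from aggscan.simulate import make_extended_chain, simulate_ensemble, simulate_xlms
from aggscan.xlms import (
    XLMS_COLUMNS,
    ConsensusLinkMap,
    filter_ids,
    read_xlms_tsv,
    superposed_rmsd,
    write_xlms_tsv,
)


from _oracles import xlms_row as base_row


@pytest.mark.parametrize(
    "kw,kept",
    [
        ({}, True),
        ({"score": 31.0}, True),
        ({"score": 30.0}, False),                 # strict >30
        ({"mass_error": -2.2}, True),             # inclusive lower edge
        ({"mass_error": 3.8}, True),              # inclusive upper edge
        ({"mass_error": -2.3}, False),
        ({"mass_error": 3.9}, False),
        ({"tic_pct": 10.0}, False),               # strict >10
        ({"pep_a": "ACDEF"}, False),              # length 5 < 6
        ({"pep_a": "ACDEFG"}, True),              # length 6 ok
        ({"frags_a": 3, "contig_a": 3}, True),    # contiguous alternative
        ({"frags_a": 3, "contig_a": 2}, False),
        ({"frags_b": 3, "contig_b": 2}, False),
        ({"frags_a": 4, "contig_a": 0}, True),
    ],
)
def test_filter_boundaries(kw, kept):
    df = pd.DataFrame([base_row(**kw)])
    assert (len(filter_ids(df)) == 1) is kept


def test_filter_idempotent_and_order_independent():
    rows = [base_row(score=s, res_a=i) for i, s in enumerate([45, 30, 31, 10, 50], 1)]
    df = pd.DataFrame(rows)
    once = filter_ids(df)
    twice = filter_ids(once)
    pd.testing.assert_frame_equal(once, twice)
    shuffled = filter_ids(df.sample(frac=1, random_state=0))
    assert sorted(shuffled["res_a"]) == sorted(once["res_a"])


class TestConsensus:
    def _tables(self, spec):
        """spec: pair -> list of per-replicate counts (0 = absent)."""
        n = max(len(v) for v in spec.values())
        tables = [[] for _ in range(n)]
        for pair, counts in spec.items():
            for rep, c in enumerate(counts):
                for _ in range(c):
                    tables[rep].append(base_row(res_a=pair[0], res_b=pair[1]))
        return [pd.DataFrame(t, columns=XLMS_COLUMNS) for t in tables]

    def test_mean_frequency(self):
        tables = self._tables({(13, 45): [3, 2, 4, 3, 3]})
        cmap = ag.consensus(tables)
        assert cmap.pairs == {(13, 45): pytest.approx(3.0)}

    def test_five_of_five_rule_drops_partial_pairs(self):
        tables = self._tables({(13, 45): [1, 1, 1, 1, 1], (46, 97): [2, 2, 2, 2, 0]})
        cmap = ag.consensus(tables)
        assert set(cmap.pairs) == {(13, 45)}

    def test_empty_intersection(self):
        tables = self._tables({(1, 5): [1, 0], (2, 6): [0, 1]})
        assert ag.consensus(tables).pairs == {}

    def test_unordered_pair_key(self):
        t1 = pd.DataFrame([base_row(res_a=45, res_b=13)], columns=XLMS_COLUMNS)
        t2 = pd.DataFrame([base_row(res_a=13, res_b=45)], columns=XLMS_COLUMNS)
        assert set(ag.consensus([t1, t2]).pairs) == {(13, 45)}

    def test_raising_required_never_adds_pairs(self):
        tables = self._tables(
            {(1, 9): [1, 1, 1, 0, 0], (2, 8): [1, 1, 1, 1, 0], (3, 7): [1, 1, 1, 1, 1]}
        )
        sets = [set(ag.consensus(tables, required=r).pairs) for r in range(1, 6)]
        for a, b in zip(sets, sets[1:]):
            assert b <= a
        per_replicate = [set(ag.xlms._pair_counts(t)) for t in tables]
        for s in per_replicate:
            assert sets[-1] <= s

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            ag.consensus([])


class TestRegionCount:
    CMAP = ConsensusLinkMap({(5, 20): 2.0, (10, 30): 1.5, (13, 45): 3.0}, 5, 5)

    def test_both_endpoints_rule(self):
        freq, n = ag.region_link_count(self.CMAP, (1, 35))
        assert freq == pytest.approx(3.5) and n == 2

    def test_any_endpoint_rule(self):
        freq, n = ag.region_link_count(self.CMAP, (1, 35), mode="any")
        assert freq == pytest.approx(6.5) and n == 3

    def test_whole_protein(self):
        freq, _ = ag.region_link_count(self.CMAP, (1, 140))
        assert freq == pytest.approx(self.CMAP.total_frequency())

    def test_empty_map(self):
        assert ag.region_link_count(ConsensusLinkMap({}, 5, 5), (1, 35)) == (0.0, 0)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            ag.region_link_count(self.CMAP, (10, 5))


class TestCompatibility:
    def test_extended_chain_analytic_distances(self):
        xyz = make_extended_chain(140)
        cmap = ConsensusLinkMap({(1, 5): 1.0, (1, 10): 1.0}, 5, 5)
        n_ok, n_tot, d = ag.compatibility(cmap, xyz)
        assert d[(1, 5)] == pytest.approx(4 * 3.8)     # 15.2 A, compatible
        assert d[(1, 10)] == pytest.approx(9 * 3.8)    # 34.2 A, not
        assert (n_ok, n_tot) == (1, 2)

    def test_cutoff_is_strict(self):
        xyz = np.array([[0.0, 0, 0], [30.0, 0, 0], [10.0, 0, 0]])
        cmap = ConsensusLinkMap({(1, 2): 1.0, (1, 3): 1.0}, 5, 5)
        n_ok, _, d = ag.compatibility(cmap, xyz, cutoff=30.0)
        assert d[(1, 2)] == pytest.approx(30.0)
        assert n_ok == 1   # exactly 30.0 A is NOT compatible

    def test_monotone_in_cutoff(self):
        xyz = make_extended_chain(60)
        pairs = {(1, k): 1.0 for k in range(2, 60, 5)}
        cmap = ConsensusLinkMap(pairs, 5, 5)
        counts = [ag.compatibility(cmap, xyz, cutoff=c)[0] for c in (10, 20, 30, 50, 300)]
        assert counts == sorted(counts)

    def test_residue_outside_model_rejected(self):
        cmap = ConsensusLinkMap({(1, 99): 1.0}, 5, 5)
        with pytest.raises(ValueError, match="outside"):
            ag.compatibility(cmap, make_extended_chain(50))


class TestSuperposition:
    def test_identity_rmsd_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(35, 3))
        assert superposed_rmsd(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance_and_symmetry(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        a = rng.normal(size=(35, 3))
        b = a + rng.normal(scale=0.3, size=a.shape)
        moved = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).apply(b) + [5.0, -2.0, 7.0]
        assert superposed_rmsd(a, moved) == pytest.approx(superposed_rmsd(a, b), abs=1e-8)
        assert superposed_rmsd(a, b) == pytest.approx(superposed_rmsd(b, a), abs=1e-8)


class TestClusterRegion:
    def test_duplicated_conformers_split_evenly(self):
        ens, _ = simulate_ensemble(
            n_models=100, occupancies=(0.5, 0.5), noise=0.0, n_residues=40, seed=2
        )
        res = ag.cluster_region(ens, (1, 35), k=2, seed=0)
        np.testing.assert_allclose(res.occupancies, [0.5, 0.5])
        # zero within-cluster RMSD: every member matches its medoid exactly
        for c in range(2):
            members = ens.coords[res.labels == c][:, :35]
            medoid = ens.coords[res.medoid_models[c]][:35]
            for m in members:
                assert superposed_rmsd(m, medoid) == pytest.approx(0.0, abs=1e-9)

    def test_planted_occupancy_recovery(self):
        ens, labels = simulate_ensemble(
            n_models=100, occupancies=(0.4, 0.3, 0.2, 0.1), noise=0.2, seed=5
        )
        res = ag.cluster_region(ens, (1, 35), k=4, seed=0)
        np.testing.assert_allclose(
            res.occupancies, [0.4, 0.3, 0.2, 0.1], atol=0.05
        )

    def test_k_exceeding_models_rejected(self):
        ens, _ = simulate_ensemble(n_models=3, occupancies=(1.0,), noise=0.1, seed=0,
                                   n_residues=20)
        with pytest.raises(ValueError):
            ag.cluster_region(ens, (1, 10), k=5)


def test_xlms_tsv_round_trip(tmp_path):
    df = pd.DataFrame([base_row(), base_row(res_a=7, res_b=30)])
    p = tmp_path / "ids.tsv"
    write_xlms_tsv(df, p)
    back = read_xlms_tsv(p)
    pd.testing.assert_frame_equal(back[XLMS_COLUMNS], df[XLMS_COLUMNS])
    with pytest.raises(ValueError, match="missing"):
        bad = tmp_path / "bad.tsv"
        df.drop(columns=["score"]).to_csv(bad, sep="\t", index=False)
        read_xlms_tsv(bad)
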