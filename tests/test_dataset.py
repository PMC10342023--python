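"""Event-to-structure mapping, curation, dataset assembly, grouped folds."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from cleavability.dataset import (
    CleavageEvent,
    MappedSite,
    Rejection,
    build_dataset,
    curation_filter,
    events_per_protein,
    global_align,
    group_kfold,
    map_event,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXT = -10.0, -0.5


def brute_force_align_score(a: str, b: str) -> float:
    """Exhaustive affine-gap global alignment score (memoized enumeration)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = -np.inf
        if i < len(a) and j < len(b):
            out = max(out, float(BLOSUM62[a[i], b[j]]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = GAP_EXT if prev == "X" else GAP_OPEN
            out = max(out, cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = GAP_EXT if prev == "Y" else GAP_OPEN
            out = max(out, cost + best(i, j + 1, "Y"))
        return out

    return best(0, 0, "M")


class TestGlobalAlign:
    def test_identical_sequences_identity_map(self):
        res = global_align("ACDEFGHIK", "ACDEFGHIK")
        assert res.posmap == {i: i for i in range(9)}
        assert res.identity == 1.0

    def test_single_unresolved_residue_maps_to_gap(self):
        res = global_align("ACDEFG", "ACDFG")
        assert res.posmap[3] is None  # E has no structural counterpart
        assert {k: v for k, v in res.posmap.items() if k != 3} == {
            0: 0, 1: 1, 2: 2, 4: 3, 5: 4}
        assert res.score == brute_force_align_score("ACDEFG", "ACDFG")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_exhaustive_oracle_on_short_pairs(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, size=rng.integers(3, 9)))
        b = "".join(rng.choice(letters, size=rng.integers(3, 9)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert global_align(a, b).score == pytest.approx(
                brute_force_align_score(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_score_matches_biopython_global_aligner(self, seed):
        rng = np.random.default_rng(100 + seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(letters, size=rng.integers(5, 30)))
        b = "".join(rng.choice(letters, size=rng.integers(5, 30)))
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = GAP_OPEN
        aligner.extend_gap_score = GAP_EXT
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))

    def test_posmap_is_monotone(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = global_align("MKVLITAGAKQW", "MKVITAGARQW")
        mapped = [v for _, v in sorted(res.posmap.items()) if v is not None]
        assert mapped == sorted(mapped)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")


class TestMapEvent:
    def setup_method(self):
        self.sub = "ACDEFG"
        self.struct = "ACDFG"
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.aln = global_align(self.sub, self.struct)

    def _map(self, p1, **kw):
        return map_event(CleavageEvent("s1", p1), self.aln, self.sub, self.struct,
                         "pdb1", "A", **kw)

    def test_resolved_matching_residue_maps(self):
        site = self._map(2)
        assert isinstance(site, MappedSite)
        assert site.residue_index == 1

    def test_gap_is_unresolved(self):
        rej = self._map(4)  # E is unmodelled in the structure
        assert isinstance(rej, Rejection) and rej.reason == "unresolved"

    def test_incomplete_features_rejected(self):
        complete = np.array([True, False, True, True, True])
        rej = self._map(2, complete=complete)
        assert isinstance(rej, Rejection) and rej.reason == "incomplete_features"

    def test_mismatch_policy(self):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aln = global_align("AAAAAA", "AAAWAA")
        rej = map_event(CleavageEvent("s1", 4), aln, "AAAAAA", "AAAWAA", "p", "A")
        assert isinstance(rej, Rejection) and rej.reason == "mismatch"
        site = map_event(CleavageEvent("s1", 4), aln, "AAAAAA", "AAAWAA", "p", "A",
                         allow_mismatch=True)
        assert isinstance(site, MappedSite)

    def test_out_of_range_p1_is_contract_error(self):
        with pytest.raises(ValueError):
            self._map(7)


def _sites(ref_and_n):
    out = []
    for ref, n in ref_and_n:
        for i in range(n):
            out.append(MappedSite("pdb1", "A", i,
                                  CleavageEvent("s1", i + 1, source_ref=ref)))
    return out


class TestCurationFilter:
    def test_mostly_buried_group_excluded(self):
        sites = _sites([("pub1", 3)])
        retained, excluded, log = curation_filter(sites, [0.01, 0.02, 0.40])
        assert retained == [] and len(excluded) == 3
        assert len(log) == 1 and "pub1" in log[0]

    def test_single_buried_site_retained(self):
        sites = _sites([("pub1", 1)])
        retained, excluded, _ = curation_filter(sites, [0.0])
        assert len(retained) == 1 and excluded == []

    def test_exposed_pair_retained(self):
        sites = _sites([("pub1", 2)])
        retained, excluded, _ = curation_filter(sites, [0.3, 0.3])
        assert len(retained) == 2 and excluded == []

    def test_counts_conserved_and_log_justifies(self):
        sites = _sites([("pub1", 3), ("pub2", 2), ("pub3", 1)])
        acc = [0.0, 0.0, 0.0, 0.5, 0.6, 0.01]
        retained, excluded, log = curation_filter(sites, acc)
        assert len(retained) + len(excluded) == len(sites)
        assert len(log) == len({s.event.source_ref for s in excluded})


def _feature_table(n_structures=6, n_res=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_structures):
        for i in range(n_res):
            rows.append({
                "structure_id": f"st{s}", "chain_id": "A", "seq_num": i + 1,
                "icode": "", "res_name": "ALA", "one_letter": "A",
                "f1": rng.random(), "f2": rng.random(), "complete": True,
            })
    return pd.DataFrame(rows)


class TestBuildDataset:
    def test_ratio_counts_and_determinism(self):
        table = _feature_table()
        sites = [MappedSite(f"st{s}", "A", 2, CleavageEvent(f"st{s}", 3))
                 for s in range(5)]
        d1 = build_dataset(table, sites, ["f1", "f2"], neg_ratio=1.0, seed=7)
        d2 = build_dataset(table, sites, ["f1", "f2"], neg_ratio=1.0, seed=7)
        assert (d1["label"] == 1).sum() == 5 and (d1["label"] == 0).sum() == 5
        pd.testing.assert_frame_equal(d1, d2)

    def test_ratio_all_keeps_pool(self):
        table = _feature_table(n_structures=1, n_res=50)
        sites = [MappedSite("st0", "A", 10, CleavageEvent("st0", 11))]
        d = build_dataset(table, sites, ["f1", "f2"], neg_ratio="all")
        assert (d["label"] == 0).sum() == 49

    def test_different_seeds_differ_in_negatives(self):
        table = _feature_table()
        sites = [MappedSite("st0", "A", 2, CleavageEvent("st0", 3))]
        d1 = build_dataset(table, sites, ["f1"], neg_ratio=5.0, seed=1)
        d2 = build_dataset(table, sites, ["f1"], neg_ratio=5.0, seed=2)
        assert not d1[d1.label == 0].equals(d2[d2.label == 0])
        pd.testing.assert_frame_equal(d1[d1.label == 1], d2[d2.label == 1])

    def test_insufficient_negatives_is_contract_error(self):
        table = _feature_table(n_structures=1, n_res=3)
        sites = [MappedSite("st0", "A", 0, CleavageEvent("st0", 1))]
        with pytest.raises(ValueError, match="pool"):
            build_dataset(table, sites, ["f1"], neg_ratio=10.0)


class TestGroupKfold:
    def test_each_group_tested_once(self):
        groups = np.array([f"g{i}" for i in range(10)])
        folds = list(group_kfold(groups, k=10, seed=0))
        tested = sorted(int(t[0]) for _, t in folds)
        assert tested == list(range(10))

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        groups = rng.choice([f"g{i}" for i in range(15)], size=120)
        folds = list(group_kfold(groups, k=5, seed=1))
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(120))
        for train, test in folds:
            assert not set(groups[train]) & set(groups[test])

    def test_23_groups_into_10_folds(self):
        groups = np.repeat([f"g{i}" for i in range(23)], 2)
        sizes = sorted(len(set(groups[t])) for _, t in group_kfold(groups, 10, seed=4))
        assert sizes == [2] * 7 + [3] * 3

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            list(group_kfold(np.array(["a", "b"]), k=3))


class TestEventsPerProtein:
    def test_mean_and_median(self):
        events = [CleavageEvent("a", 1), CleavageEvent("a", 5),
                  CleavageEvent("b", 2), CleavageEvent("c", 3)]
        mean, median = events_per_protein(events)
        assert mean == pytest.approx(4 / 3)
        assert median == 1.0
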