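import itertools

import numpy as np
import pytest

from chiscan.core import (
    DistanceMatrix,
    MarkerAlignment,
    best_reciprocal_hits,
    build_pseudo_core,
    closest_relatives,
    filter_alignment_columns,
    global_identity,
    pairwise_distance_matrix,
)


class TestFilterAlignmentColumns:
    def test_gap_fraction_threshold(self):
        # columns: A/A (0 gaps), A/- (0.5), -/- (1.0); keep <= 0.4
        aln = MarkerAlignment(["s1", "s2"], ["AA-", "A--"])
        out = filter_alignment_columns(aln, 0.4)
        assert out.rows == ["A", "A"]

    def test_threshold_one_is_identity(self):
        aln = MarkerAlignment(["s1", "s2"], ["A-C", "AG-"])
        assert filter_alignment_columns(aln, 1.0).rows == aln.rows

    def test_threshold_zero_on_gapfree(self):
        aln = MarkerAlignment(["s1", "s2"], ["ACD", "AGD"])
        assert filter_alignment_columns(aln, 0.0).rows == aln.rows

    def test_all_columns_removed_warns(self):
        aln = MarkerAlignment(["s1", "s2"], ["--", "A-"])
        with pytest.warns(UserWarning):
            out = filter_alignment_columns(aln, 0.1)
        assert out.rows == ["", ""]


class TestPairwiseDistance:
    def test_identical_rows(self):
        aln = MarkerAlignment(["a", "b"], ["ACDEF", "ACDEF"])
        assert pairwise_distance_matrix(aln).get("a", "b") == 0.0

    def test_one_in_ten(self):
        aln = MarkerAlignment(["a", "b"], ["ACDEFGHIKL", "ACDEFGHIKV"])
        assert pairwise_distance_matrix(aln).get("a", "b") == pytest.approx(
            0.1
        )

    def test_gap_exclusion(self):
        aln = MarkerAlignment(["a", "b"], ["AC-G", "AT-G"])
        # comparable columns 3, mismatches 1
        assert pairwise_distance_matrix(aln).get("a", "b") == pytest.approx(
            1 / 3
        )

    def test_no_comparable_columns_warns(self):
        aln = MarkerAlignment(["a", "b"], ["A-", "-A"])
        with pytest.warns(UserWarning):
            d = pairwise_distance_matrix(aln)
        assert d.get("a", "b") == 1.0

    def test_triangle_inequality_on_gapfree(self):
        rng = np.random.default_rng(0)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        rows = [
            "".join(rng.choice(list(aa), size=60)) for _ in range(5)
        ]
        d = pairwise_distance_matrix(
            MarkerAlignment([f"s{i}" for i in range(5)], rows)
        )
        for i, j, k in itertools.permutations(range(5), 3):
            si, sj, sk = f"s{i}", f"s{j}", f"s{k}"
            assert d.get(si, sk) <= d.get(si, sj) + d.get(sj, sk) + 1e-12


class TestClosestRelatives:
    def _matrix(self, dab, dac, dbc=0.5):
        return DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, dab, dac], [dab, 0, dbc], [dac, dbc, 0]]),
        )

    def test_ascending_order(self):
        assert closest_relatives(self._matrix(0.1, 0.3), "A", 2) == ["B", "C"]

    def test_tie_broken_by_label(self):
        assert closest_relatives(self._matrix(0.2, 0.2), "A", 2) == ["B", "C"]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            closest_relatives(self._matrix(0.1, 0.2), "A", 3)

    def test_unknown_species(self):
        with pytest.raises(KeyError):
            closest_relatives(self._matrix(0.1, 0.2), "Z", 1)


class TestBestReciprocalHits:
    def test_identical_proteomes(self):
        p = {"x": "MKVLLIAGGA"}
        assert best_reciprocal_hits(p, {"y": "MKVLLIAGGA"}) == [("x", "y")]

    def test_length_conservation_threshold(self):
        a = {"x": "M" + "A" * 99}  # length 100
        b = {"y": "M" + "A" * 78}  # length 79; 79/100 < 0.80
        assert best_reciprocal_hits(a, b, min_identity=0.0) == []

    def test_non_reciprocal_pair_excluded(self):
        # a1 prefers b1, but b1 prefers a2 (exact copy): no a1 pair
        a = {"a1": "MKVLLIAGGADEF", "a2": "MKVLLIAGGAWWW"}
        b = {"b1": "MKVLLIAGGAWWW"}
        pairs = best_reciprocal_hits(a, b, min_identity=0.5)
        assert pairs == [("a2", "b1")]
        # exhaustive identity check confirms the preference structure
        assert global_identity(a["a1"], b["b1"]) < global_identity(
            a["a2"], b["b1"]
        )

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        a = {
            f"a{i}": "".join(rng.choice(list(aa), size=30))
            for i in range(4)
        }
        b = {
            f"b{i}": "".join(rng.choice(list(aa), size=30))
            for i in range(4)
        }
        fwd = best_reciprocal_hits(a, b, min_identity=0.0,
                                   min_length_conservation=0.0)
        rev = best_reciprocal_hits(b, a, min_identity=0.0,
                                   min_length_conservation=0.0)
        assert sorted((x, y) for y, x in rev) == fwd

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(2)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        base = "".join(rng.choice(list(aa), size=40))
        a = {f"a{i}": base[:35] for i in range(2)}
        b = {"b0": base[:35], "b1": base[:28]}
        loose = set(
            best_reciprocal_hits(a, b, min_identity=0.0,
                                 min_length_conservation=0.0)
        )
        strict = set(
            best_reciprocal_hits(a, b, min_identity=0.9,
                                 min_length_conservation=0.9)
        )
        assert strict <= loose

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            best_reciprocal_hits({}, {"y": "MKV"})


class TestBuildPseudoCore:
    GENES = {"g1": "ATGAAA", "g2": "ATGTGC"}
    PROTS = {"g1": "MK", "g2": "MC"}

    def test_neighbors_identical_to_species(self):
        core = build_pseudo_core(
            "sp", self.GENES, self.PROTS,
            {"n1": dict(self.PROTS), "n2": dict(self.PROTS)},
        )
        assert core.gene_ids == ["g1", "g2"]
        assert core.sequences == ["ATGAAA", "ATGTGC"]

    def test_gene_in_single_neighbor_excluded(self):
        core = build_pseudo_core(
            "sp", self.GENES, self.PROTS,
            {"n1": dict(self.PROTS), "n2": {"g1": "MK"}},
        )
        assert core.gene_ids == ["g1"]

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning):
            core = build_pseudo_core(
                "sp", self.GENES, self.PROTS,
                {"n1": {"x": "WWWWW"}, "n2": {"y": "HHHHH"}},
            )
        assert len(core) == 0

    def test_inconsistent_ids_rejected(self):
        with pytest.raises(ValueError):
            build_pseudo_core(
                "sp", self.GENES, {"g1": "MK"},
                {"n1": dict(self.PROTS), "n2": dict(self.PROTS)},
            )
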