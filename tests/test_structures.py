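import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gemmi

from acecontact import structures as stx
from acecontact.structures import (
    ChainMappingError,
    ContactMap,
    StructureContentError,
    build_dual_fold_map,
    categorize_predictions,
    contact_map,
    determine_dominant,
    map_to_query,
    parse_structure,
)
from acecontact.synthetic import toy_pdb_string


def write_pdb(tmp_path, coords, seq, name="toy.pdb", chain="A"):
    p = tmp_path / name
    p.write_text(toy_pdb_string(coords, seq, chain))
    return p


def hairpin_coords(L, spacing=4.0, gap=5.0):
    """CA trace going out and folding back, giving long-range contacts."""
    half = L // 2
    out = [(spacing * k, 0.0, 0.0) for k in range(half)]
    back = [(spacing * (L - 1 - k), gap, 0.0) for k in range(half, L)]
    return out + back


class TestParse:
    def test_minimal_two_residue_pdb(self, tmp_path):
        p = write_pdb(tmp_path, [(0, 0, 0), (3.8, 0, 0)], "AG")
        st_ = parse_structure(p, "pdb")
        assert len(st_.chains) == 1
        assert st_.chains[0].seq == "AG"
        np.testing.assert_allclose(st_.chains[0].coords[1][0], [3.8, 0, 0])

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C\n"
            "END\n"
        )
        st_ = parse_structure(p, "pdb")
        assert len(st_.chains[0].coords[0]) == 1
        np.testing.assert_allclose(st_.chains[0].coords[0][0], [0, 0, 0])

    def test_mmcif_and_pdb_agree(self, tmp_path):
        pdb = write_pdb(tmp_path, [(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)], "AGC")
        st_pdb = parse_structure(pdb, "pdb")
        doc = gemmi.read_structure(str(pdb))
        doc.setup_entities()
        cif = tmp_path / "toy.cif"
        doc.make_mmcif_document().write_file(str(cif))
        st_cif = parse_structure(cif, "mmcif")
        assert st_cif.chains[0].seq == st_pdb.chains[0].seq
        for a, b in zip(st_cif.chains[0].coords, st_pdb.chains[0].coords):
            np.testing.assert_allclose(a, b, atol=1e-3)

    def test_no_protein_rejected(self, tmp_path):
        p = tmp_path / "water.pdb"
        p.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
        )
        with pytest.raises(StructureContentError):
            parse_structure(p, "pdb")


class TestMapToQuery:
    def test_identical_sequence_identity_map(self, tmp_path):
        seq = "ACDEFGHIKL"
        p = write_pdb(tmp_path, [(4.0 * k, 0, 0) for k in range(10)], seq)
        st_ = map_to_query(parse_structure(p), seq)
        np.testing.assert_array_equal(st_.chains[0].to_query, np.arange(10))

    def test_nterminal_truncation_offsets_map(self, tmp_path):
        query = "MKLVAACDEFGHIKL"
        chain_seq = query[5:]
        p = write_pdb(tmp_path, [(4.0 * k, 0, 0) for k in range(10)], chain_seq)
        st_ = map_to_query(parse_structure(p), query)
        np.testing.assert_array_equal(st_.chains[0].to_query, np.arange(5, 15))

    def test_unrelated_sequence_refused(self, tmp_path):
        p = write_pdb(tmp_path, [(4.0 * k, 0, 0) for k in range(8)], "WWWWWWWW")
        with pytest.warns(RuntimeWarning):
            with pytest.raises(ChainMappingError):
                map_to_query(parse_structure(p), "ACDEFGHIKLMNPQRSTVYA")


class TestContactMap:
    def _structure(self, tmp_path, x2, name):
        # three CA atoms on a line; x2 is the third residue's coordinate
        seq = "ACD"
        coords = [(0, 0, 0), (4.0, 0, 0), (x2, 0, 0)]
        p = write_pdb(tmp_path, coords, seq, name)
        return map_to_query(parse_structure(p), seq)

    def test_cutoff_boundary(self, tmp_path):
        st_in = self._structure(tmp_path, 7.9, "in.pdb")
        assert (0, 2) in contact_map(st_in, min_separation=2).intra
        st_out = self._structure(tmp_path, 8.1, "out.pdb")
        assert (0, 2) not in contact_map(st_out, min_separation=2).intra

    def test_sequential_pair_excluded_by_separation(self, tmp_path):
        st_ = self._structure(tmp_path, 7.0, "seq.pdb")
        cm = contact_map(st_, min_separation=2)
        assert (1, 2) not in cm.intra
        assert (1, 2) in contact_map(st_, min_separation=1).intra

    def test_homodimer_interchain_contacts(self, tmp_path):
        # two parallel CA traces 9.5 A apart (plus a 2 A register shift so
        # distinct residues come within 10 A across chains but not within
        # 8 A inside a chain beyond sequence neighbors)
        seq = "ACDEFGHIKL"
        coords_a = [(4.0 * k, 0.0, 0.0) for k in range(10)]
        coords_b = [(4.0 * k + 2.0, 9.5, 0.0) for k in range(10)]
        text = toy_pdb_string(coords_a, seq, "A").replace("END\n", "") + toy_pdb_string(
            coords_b, seq, "B"
        )
        p = tmp_path / "dimer.pdb"
        p.write_text(text)
        st_ = map_to_query(parse_structure(p), seq)
        cm = contact_map(st_, min_separation=2)
        # A_k to B_{k-1} sit at sqrt(2^2 + 9.5^2) ~ 9.71 A -> interchain only
        assert (0, 1) in cm.inter
        assert (0, 1) not in cm.intra
        assert (0, 2) not in cm.inter  # ~11.2 A, beyond the 10 A cutoff
        assert all(j - i == 1 for i, j in cm.inter)

    def test_cutoff_monotonicity(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = "ACDEFGHIKLMNPQRSTVYA"
        coords = np.cumsum(rng.normal(scale=2.2, size=(20, 3)), axis=0)
        p = write_pdb(tmp_path, coords.tolist(), seq)
        st_ = map_to_query(parse_structure(p), seq)
        small = contact_map(st_, intra_cutoff=6.0).intra
        large = contact_map(st_, intra_cutoff=9.0).intra
        assert small <= large


def cmap(src, intra, inter=(), L=12):
    return ContactMap(src, frozenset(intra), frozenset(inter), L)


class TestDualFoldMap:
    def test_identical_folds_have_empty_uniques(self):
        a = cmap("a", [(1, 9), (2, 12)])
        b = cmap("b", [(1, 9), (2, 12)])
        dm = build_dual_fold_map(a, b)
        assert dm.unique["a"] == dm.unique["b"] == frozenset()
        assert dm.common == {(1, 9), (2, 12)}

    def test_disjoint_toy(self):
        dm = build_dual_fold_map(cmap("a", [(1, 9)]), cmap("b", [(2, 12)]))
        assert dm.unique["a"] == {(1, 9)}
        assert dm.unique["b"] == {(2, 12)}
        assert dm.common == frozenset()

    def test_two_fold_fixture_partition(self):
        # 12-residue two-fold toy, hand-enumerated partition
        fold_a = [(0, 5), (1, 6), (2, 7), (3, 9), (4, 10)]
        fold_b = [(0, 5), (1, 6), (2, 11), (5, 10), (6, 11)]
        dm = build_dual_fold_map(cmap("a", fold_a), cmap("b", fold_b))
        assert dm.common == {(0, 5), (1, 6)}
        assert dm.unique["a"] == {(2, 7), (3, 9), (4, 10)}
        assert dm.unique["b"] == {(2, 11), (5, 10), (6, 11)}

    def test_symmetric_up_to_label_swap(self):
        a = cmap("a", [(1, 9), (3, 7)])
        b = cmap("b", [(2, 12), (3, 7)])
        dm1 = build_dual_fold_map(a, b)
        dm2 = build_dual_fold_map(b, a)
        assert dm1.unique["a"] == dm2.unique["a"]
        assert dm1.common == dm2.common


class TestDominant:
    def test_one_sided_overlap(self):
        dm = build_dual_fold_map(cmap("a", [(1, 9)]), cmap("b", [(5, 11)]))
        assert determine_dominant(dm, [(1, 9), (2, 8)]) == "a"

    def test_zero_overlap_ties_to_first_with_warning(self):
        dm = build_dual_fold_map(cmap("a", [(1, 9)]), cmap("b", [(5, 11)]))
        with pytest.warns(RuntimeWarning):
            assert determine_dominant(dm, [(20, 30)]) == "a"

    def test_synthetic_dominant_fold(self, default_ace_result):
        spec, truth, res = default_ace_result
        from acecontact.synthetic import truth_dual_fold_map

        dm = truth_dual_fold_map(truth, spec.L)
        dom = determine_dominant(dm, res.superfamily_superposition.retained_points)
        assert dom == "dominant_fold"


class TestCategorize:
    def _dualmap(self):
        fold_a = [(0, 5), (1, 6), (2, 7), (3, 9), (4, 10)]
        fold_b = [(0, 5), (1, 6), (2, 11), (5, 10), (6, 11)]
        return build_dual_fold_map(cmap("a", fold_a), cmap("b", fold_b)).with_dominant("a")

    def test_exact_common_hit(self):
        cat = categorize_predictions([(0, 5)], self._dualmap())
        assert cat.common == {(0, 5)}

    def test_tolerance_box_edge_is_alternative(self):
        # (i+2, j-2) of alternative-unique (5, 10), nothing else within +/-2
        fold_a = [(20, 40)]
        fold_b = [(5, 12)]
        dm = build_dual_fold_map(cmap("a", fold_a, L=50), cmap("b", fold_b, L=50))
        cat = categorize_predictions([(7, 10)], dm.with_dominant("a"))
        assert cat.alternative == {(7, 10)}

    def test_ten_prediction_partition(self):
        # Hand-enumerated four-way partition against the 12-residue fixture
        # (common {(0,5),(1,6)}; dominant uniques {(2,7),(3,9),(4,10)};
        # alternative uniques {(2,11),(5,10),(6,11)}; tolerance +/-2,
        # precedence common > dominant > alternative).
        preds = [
            (0, 5),   # exact common hit
            (2, 4),   # (0,5) box: offsets (2,1) -> common
            (2, 7),   # exact dominant, but (1,6) box offsets (1,1) -> common wins
            (1, 4),   # (0,5) box: (1,1) -> common
            (5, 11),  # (3,9) box: (2,2) -> dominant (precedence over alt (6,11))
            (2, 9),   # (3,9) box: (1,0) -> dominant
            (3, 10),  # (3,9) box: (0,1) -> dominant
            (7, 9),   # (5,10) box: (2,1) -> alternative; no dominant within 2
            (9, 11),  # nearest contact (6,11) at offset (3,0) -> unobserved
            (10, 11),  # nearest is (6,11), offset (4,0) -> unobserved
        ]
        cat = categorize_predictions(preds, self._dualmap())
        assert cat.common == {(0, 5), (2, 4), (2, 7), (1, 4)}
        assert cat.dominant == {(5, 11), (2, 9), (3, 10)}
        assert cat.alternative == {(7, 9)}
        assert cat.unobserved == {(9, 11), (10, 11)}
        assert cat.total == 10

    @given(st.integers(0, 2**31 - 1))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        dm = self._dualmap()
        preds = {(int(a), int(b)) for a, b in rng.integers(0, 12, size=(15, 2)) if a < b}
        if not preds:
            return
        cat = categorize_predictions(preds, dm)
        assert cat.total == len(preds)
        union = cat.dominant | cat.alternative | cat.common | cat.unobserved
        assert union == preds


class TestPlot:
    def test_plot_writes_figure(self, tmp_path):
        dm = build_dual_fold_map(cmap("a", [(1, 9)]), cmap("b", [(2, 11)]))
        out = tmp_path / "map.png"
        stx.plot_dual_fold_map(dm, [(3, 9)], out)
        assert out.stat().st_size > 0
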