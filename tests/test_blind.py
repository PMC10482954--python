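import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acecontact import core, synthetic
from acecontact.blind import (
    SsParseError,
    alternative_signal_clusters,
    classify_blind,
    corroborate,
    dominant_only_positions,
    find_divergent_regions,
    read_dssp,
    simplify_ss,
)
from acecontact.structures import CategorizedPredictions, DualFoldMap


def brute_divergent_positions(ss_a, ss_b, min_len=15, min_frac=0.5):
    """Oracle: mark positions covered by any qualifying window, by full scan."""
    n = len(ss_a)
    diff = [
        (ss_a[k] == "H" and ss_b[k] == "E") or (ss_a[k] == "E" and ss_b[k] == "H")
        for k in range(n)
    ]
    marked = set()
    for s in range(n):
        for e in range(s + min_len, n + 1):
            if sum(diff[s:e]) >= min_frac * (e - s):
                marked.update(range(s, e))
    return marked


def spans_to_positions(spans):
    out = set()
    for s, e in spans:
        out.update(range(s, e + 1))
    return out


class TestSimplify:
    def test_eight_state_collapse(self):
        assert simplify_ss("HGIEB TS") == "HHHEECCC"

    def test_empty(self):
        assert simplify_ss("") == ""

    def test_coil_variants(self):
        assert simplify_ss("TS-CP") == "CCCCC"

    def test_unknown_code_rejected(self):
        with pytest.raises(SsParseError):
            simplify_ss("HQX")


class TestDssp:
    def test_reads_classic_format(self, tmp_path):
        lines = [
            "==== Secondary Structure Definition by the program DSSP ====",
            "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
        ]
        ss = "HHHHEEEE"
        for k, s in enumerate(ss, start=1):
            lines.append(f"{k:5d}{k:5d} A A  {s}" + " " * 50)
        p = tmp_path / "toy.dssp"
        p.write_text("\n".join(lines) + "\n")
        chains = read_dssp(p)
        assert chains == {"A": "HHHHEEEE"}

    def test_no_records_rejected(self, tmp_path):
        p = tmp_path / "bad.dssp"
        p.write_text("nothing here\n")
        with pytest.raises(SsParseError):
            read_dssp(p)


class TestDivergence:
    def test_identical_strings(self):
        assert find_divergent_regions("H" * 40, "H" * 40) == []

    def test_full_alpha_beta_window(self):
        spans = find_divergent_regions("H" * 15, "E" * 15)
        assert spans == [(0, 14)]

    def test_density_threshold_boundary(self):
        # 7/15 alpha<->beta differences (46.7%) -> no call; 8/15 -> call
        base = list("C" * 15)
        a7, b7 = base[:], base[:]
        a8, b8 = base[:], base[:]
        for k in range(7):
            a7[2 * k], b7[2 * k] = "H", "E"
        for k in range(8):
            a8[k], b8[k] = "H", "E"
        assert find_divergent_regions("".join(a7), "".join(b7)) == []
        assert find_divergent_regions("".join(a8), "".join(b8)) != []

    def test_symmetric_in_arguments(self):
        a = "H" * 10 + "C" * 10 + "E" * 10
        b = "E" * 10 + "C" * 10 + "H" * 10
        assert find_divergent_regions(a, b) == find_divergent_regions(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            find_divergent_regions("HH", "H")

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_window_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 60))
        a = "".join(rng.choice(list("HEC"), size=n))
        b = "".join(rng.choice(list("HEC"), size=n))
        assert spans_to_positions(find_divergent_regions(a, b)) == brute_divergent_positions(a, b)


def toy_dualmap():
    return DualFoldMap(
        source_ids=("pa", "pb"),
        unique={"pa": frozenset({(10, 40), (11, 41)}), "pb": frozenset({(20, 60), (21, 61)})},
        common=frozenset({(5, 30)}),
        interchain={"pa": frozenset(), "pb": frozenset()},
        L=80,
    )


def filtered_from(clusters, noise=()):
    return core.FilteredPredictions(
        clusters=tuple(np.array(c) for c in clusters),
        noise=np.array(list(noise)).reshape(-1, 2),
        eps=2.0,
        min_samples=3,
    )


class TestCorroborate:
    def test_one_sided_support(self):
        filt = filtered_from([[(10, 40), (11, 41), (12, 42)]])
        counts = corroborate(toy_dualmap(), filt)
        assert counts == {"pa": 1, "pb": 0}

    def test_identical_structures_zero_by_definition(self):
        dm = DualFoldMap(
            source_ids=("pa", "pb"),
            unique={"pa": frozenset(), "pb": frozenset()},
            common=frozenset({(10, 40)}),
            interchain={"pa": frozenset(), "pb": frozenset()},
            L=80,
        )
        filt = filtered_from([[(10, 40), (11, 41), (12, 42)]])
        assert corroborate(dm, filt) == {"pa": 0, "pb": 0}

    def test_small_clusters_ignored(self):
        filt = filtered_from([[(10, 40), (11, 41)]])
        assert corroborate(toy_dualmap(), filt, min_cluster=3) == {"pa": 0, "pb": 0}


class TestAlternativeSignal:
    def test_cluster_on_contacts_is_explained(self):
        filt = filtered_from([[(10, 40), (11, 41), (12, 42), (13, 43), (14, 44)]])
        assert alternative_signal_clusters(filt, toy_dualmap()) == []

    def test_unexplained_cluster_detected(self):
        filt = filtered_from([[(50, 70), (51, 71), (52, 72), (53, 73), (54, 74), (55, 75)]])
        assert len(alternative_signal_clusters(filt, toy_dualmap())) == 1

    def test_near_diagonal_cluster_excluded(self):
        filt = filtered_from([[(50, 52), (51, 53), (52, 54), (53, 55), (54, 56)]])
        assert alternative_signal_clusters(filt, toy_dualmap()) == []


class TestClassify:
    def test_divergence_plus_dual_corroboration_is_category1(self):
        call = classify_blind("H" * 20, "E" * 20, {"pa": 1, "pb": 2}, [])
        assert call.category == "category1"
        assert call.flags == ()

    def test_single_corroboration_flags_low_confidence(self):
        call = classify_blind("H" * 20, "E" * 20, {"pa": 1, "pb": 0}, [])
        assert call.category == "category1"
        assert "low_confidence_single_corroboration" in call.flags

    def test_agreement_without_signal_is_single_fold(self):
        call = classify_blind("H" * 20, "H" * 20, {"pa": 0, "pb": 0}, [])
        assert call.category == "single_fold"

    def test_agreement_with_unexplained_cluster_is_category2(self):
        cluster = np.array([[50, 70], [51, 71], [52, 72], [53, 73], [54, 74], [55, 75]])
        call = classify_blind("H" * 20, "H" * 20, {"pa": 0, "pb": 0}, [cluster])
        assert call.category == "category2"
        assert "possible_multimer_interface" in call.flags

    def test_uncorroborated_divergence_is_single_fold(self):
        call = classify_blind("H" * 20, "E" * 20, {"pa": 0, "pb": 0}, [])
        assert call.category == "single_fold"


class TestDominantOnlyPositions:
    def _cat(self, dominant, alternative):
        return CategorizedPredictions(
            dominant=frozenset(dominant),
            alternative=frozenset(alternative),
            common=frozenset(),
            unobserved=frozenset(),
            dominant_fold_id="a",
        )

    def test_all_dominant_returns_all_touched(self):
        cat = self._cat([(1, 9), (2, 8)], [])
        assert dominant_only_positions(cat) == {1, 2, 8, 9}

    def test_position_in_both_categories_excluded(self):
        cat = self._cat([(1, 9)], [(9, 20)])
        assert dominant_only_positions(cat) == {1}

    def test_hand_labeled_toy(self):
        # 12-residue toy: dominant pairs touch {0,5,1,6,2,7}; alternative
        # pairs touch {2,11,5,10}; dominant-only = {0,1,6,7}
        cat = self._cat([(0, 5), (1, 6), (2, 7)], [(2, 11), (5, 10)])
        assert dominant_only_positions(cat) == {0, 1, 6, 7}


class TestScenarios:
    def test_single_fold_scenarios_yield_single_fold(self):
        for seed in range(5):
            sc = synthetic.generate_blind_scenario(False, seed=seed)
            filt = core.dbscan_filter(sc.points, eps=2.0)
            call = classify_blind(
                sc.ss_a,
                sc.ss_b,
                corroborate(sc.dualmap, filt),
                alternative_signal_clusters(filt, sc.dualmap),
            )
            assert call.category == "single_fold"

    def test_fold_switcher_scenarios_yield_category1(self):
        for seed in range(5):
            sc = synthetic.generate_blind_scenario(True, seed=100 + seed)
            filt = core.dbscan_filter(sc.points, eps=2.0)
            call = classify_blind(
                sc.ss_a,
                sc.ss_b,
                corroborate(sc.dualmap, filt),
                alternative_signal_clusters(filt, sc.dualmap),
            )
            assert call.category == "category1"
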