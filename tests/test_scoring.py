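"""Scoring: frequency profiles, pseudo-counts, inversion/SSA scores, scanning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_grouped, random_profile
from parinv import scoring, synth
from parinv.scoring import (
    EmptyGroupError,
    PseudoCountConfig,
    column_frequencies,
    inversion_score,
    map_column_to_reference,
    match_prob,
    ortholog_paralog_matching,
    percentile_threshold,
    scan_alignment,
    ssa_score,
)

AA = "ARNDCQEGHILKMFPSTWYV"
UNIFORM_PC = PseudoCountConfig(beta=5.0, background=np.full(20, 0.05))


def two_step_joint_score(xa, yb, ya, xb):
    """Independent oracle: conditional probability times both cross matches."""
    m_cross1 = float(xa @ yb)
    m_cross2 = float(ya @ xb)
    conditional = sum(
        (xa[i] * yb[i] / m_cross1) * (1.0 - ya[i] * xb[i] / m_cross2)
        for i in range(20)
    )
    return conditional * m_cross1 * m_cross2


def one_hot(residue):
    v = np.zeros(20)
    v[AA.index(residue)] = 1.0
    return v


class TestColumnFrequencies:
    def test_monomorphic_column_is_one_hot(self):
        grouped = make_grouped({c: ["A", "A"] for c in ("Xa", "Ya", "Xb", "Yb")})
        prof = column_frequencies(grouped, 1)
        assert prof.freq["Xa"][AA.index("A")] == 1.0
        assert prof.freq["Xa"].sum() == pytest.approx(1.0)

    def test_beta_zero_equals_raw_frequencies(self):
        grouped = make_grouped({c: ["A", "C"] for c in ("Xa", "Ya", "Xb", "Yb")})
        raw = column_frequencies(grouped, 1, pc=None)
        zero = column_frequencies(grouped, 1, pc=PseudoCountConfig(beta=0.0))
        np.testing.assert_allclose(raw.freq["Xa"], zero.freq["Xa"])

    def test_hand_computed_pseudo_count_value(self):
        # n=2 with residues {A, C}, beta=5, uniform background 1/20:
        # f'_A = (2*0.5 + 5*0.05) / (2 + 5) = 0.17857...
        grouped = make_grouped({c: ["A", "C"] for c in ("Xa", "Ya", "Xb", "Yb")})
        prof = column_frequencies(grouped, 1, pc=UNIFORM_PC)
        assert prof.freq["Xa"][AA.index("A")] == pytest.approx(1.25 / 7, abs=1e-12)
        assert prof.freq["Xa"][AA.index("W")] == pytest.approx(0.25 / 7, abs=1e-12)
        assert prof.freq["Xa"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_gaps_and_unknowns_excluded(self):
        grouped = make_grouped({c: ["A", "-", "X"] for c in ("Xa", "Ya", "Xb", "Yb")})
        prof = column_frequencies(grouped, 1)
        assert prof.counts["Xa"] == 1
        assert prof.gap_fraction == pytest.approx(4 / 12)

    def test_empty_cell_is_flagged(self):
        grouped = make_grouped(
            {"Xa": ["-"], "Ya": ["A"], "Xb": ["A"], "Yb": ["A"]}
        )
        prof = column_frequencies(grouped, 1)
        assert prof.empty_cells == ["Xa"]
        with pytest.raises(EmptyGroupError):
            inversion_score(prof)


class TestMatchProb:
    def test_anchors(self):
        a, c = one_hot("A"), one_hot("C")
        u = np.full(20, 0.05)
        assert match_prob(a, a) == 1.0
        assert match_prob(a, c) == 0.0
        assert match_prob(u, u) == pytest.approx(0.05)

    def test_symmetry_and_validation(self):
        rng = np.random.default_rng(0)
        p, q = rng.dirichlet(np.ones(20)), rng.dirichlet(np.ones(20))
        assert match_prob(p, q) == pytest.approx(match_prob(q, p))
        with pytest.raises(ValueError, match="sums to"):
            match_prob(p, q * 0.5)


class TestScores:
    def test_conserved_column_scores_zero(self):
        grouped = make_grouped({c: ["A"] for c in ("Xa", "Ya", "Xb", "Yb")})
        prof = column_frequencies(grouped, 1)
        assert inversion_score(prof) == 0.0
        assert ssa_score(prof) == 0.0

    def test_perfect_inversion_scores_one(self):
        grouped = make_grouped(
            {"Xa": ["A"], "Yb": ["A"], "Ya": ["C"], "Xb": ["C"]}
        )
        prof = column_frequencies(grouped, 1)
        assert inversion_score(prof) == 1.0
        assert ssa_score(prof) == 0.0

    def test_perfect_species_adaptation_scores_one(self):
        grouped = make_grouped(
            {"Xa": ["A"], "Xb": ["A"], "Ya": ["C"], "Yb": ["C"]}
        )
        prof = column_frequencies(grouped, 1)
        assert ssa_score(prof) == 1.0
        assert inversion_score(prof) == 0.0

    def test_mixed_profile_matches_two_step_oracle(self):
        grouped = make_grouped(
            {"Xa": ["A", "C"], "Yb": ["A", "C"], "Ya": ["C"], "Xb": ["C"]}
        )
        prof = column_frequencies(grouped, 1)
        f = prof.freq
        expected = two_step_joint_score(f["Xa"], f["Yb"], f["Ya"], f["Xb"])
        assert inversion_score(prof) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_division_free_form_equals_two_step_formula(self, seed):
        prof = random_profile(np.random.default_rng(seed))
        f = prof.freq
        if f["Xa"] @ f["Yb"] <= 0 or f["Ya"] @ f["Xb"] <= 0:
            return
        assert inversion_score(prof) == pytest.approx(
            two_step_joint_score(f["Xa"], f["Yb"], f["Ya"], f["Xb"]), abs=1e-12
        )
        assert ssa_score(prof) == pytest.approx(
            two_step_joint_score(f["Xa"], f["Xb"], f["Ya"], f["Yb"]), abs=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ssa_equals_inversion_with_b_arrays_swapped(self, seed):
        prof = random_profile(np.random.default_rng(seed))
        swapped = scoring.ColumnProfile(
            column_index=prof.column_index,
            freq={"Xa": prof.freq["Xa"], "Ya": prof.freq["Ya"],
                  "Xb": prof.freq["Yb"], "Yb": prof.freq["Xb"]},
            counts=prof.counts, gap_fraction=0.0,
        )
        assert ssa_score(prof) == pytest.approx(inversion_score(swapped), abs=1e-14)

    def test_pseudo_counts_keep_scores_off_the_boundary(self):
        grouped = make_grouped(
            {"Xa": ["A"], "Yb": ["A"], "Ya": ["C"], "Xb": ["C"]}
        )
        prof = column_frequencies(grouped, 1, pc=PseudoCountConfig(beta=5.0))
        assert 0.0 < inversion_score(prof) < 1.0
        assert 0.0 < ssa_score(prof) < 1.0

    def test_pseudo_counted_scores_converge_to_raw_for_large_groups(self):
        n = 2000
        grouped = make_grouped({
            "Xa": ["A"] * n, "Yb": ["A"] * n, "Ya": ["C"] * n, "Xb": ["C"] * n,
        })
        raw = inversion_score(column_frequencies(grouped, 1))
        smoothed = inversion_score(
            column_frequencies(grouped, 1, pc=PseudoCountConfig(beta=5.0))
        )
        assert smoothed == pytest.approx(raw, abs=0.02)


class TestScanAlignment:
    def test_gappy_columns_excluded(self):
        # column 1: 8 of 13 assigned sequences gapped (61.5% >= 60%)
        cells = {
            "Xa": ["-A", "-A", "-A", "-A"], "Ya": ["-C", "-C", "-C", "-C"],
            "Xb": ["CC", "CC", "CC"], "Yb": ["AA", "AA"],
        }
        grouped = make_grouped(cells)
        scores = scan_alignment(grouped, pc=None)
        assert [s.column_index for s in scores] == [2]

    def test_single_perfect_inversion_column(self):
        grouped = make_grouped(
            {"Xa": ["A"], "Yb": ["A"], "Ya": ["C"], "Xb": ["C"]}
        )
        scores = scan_alignment(grouped, pc=None)
        assert len(scores) == 1
        assert scores[0].inversion_score == 1.0

    def test_planted_columns_rank_first(self):
        cfg = synth.SynthConfig(n_sites=100, n_planted_inversions=5, noise=0.0,
                                seed=11)
        ds = synth.generate_dataset(cfg)
        scores = scan_alignment(ds.grouped(), pc=None)
        ranked = sorted(scores, key=lambda s: -s.inversion_score)
        top5 = {s.column_index for s in ranked[:5]}
        assert top5 == set(ds.truth["column"])
        assert all(s.inversion_score == 1.0 for s in ranked[:5])

    def test_scores_invariant_under_within_group_permutation_and_relabeling(self):
        cfg = synth.SynthConfig(n_sites=60, n_planted_inversions=3, seed=5)
        ds = synth.generate_dataset(cfg)
        base = scan_alignment(ds.grouped(), pc=None)

        # permute sequences within the alignment (grouping is id-based)
        rng = np.random.default_rng(1)
        shuffled = list(ds.records)
        rng.shuffle(shuffled)
        from parinv.align_io import GroupedAlignment
        perm = scan_alignment(
            GroupedAlignment(records=shuffled, groups=ds.groups), pc=None
        )
        for a, b in zip(base, perm):
            assert a.inversion_score == pytest.approx(b.inversion_score, abs=1e-12)

        # consistent residue relabeling across all sequences
        mapping = str.maketrans(AA, AA[1:] + AA[0])
        relabeled = [
            type(r)(id=r.id, residues=r.residues.translate(mapping), species=r.species)
            for r in ds.records
        ]
        rel = scan_alignment(
            GroupedAlignment(records=relabeled, groups=ds.groups), pc=None
        )
        for a, b in zip(base, rel):
            assert a.inversion_score == pytest.approx(b.inversion_score, abs=1e-12)

    def test_best_grouping_reported_per_site(self, default_dataset):
        from parinv.align_io import assign_groups_auto
        cands = assign_groups_auto(default_dataset.tree, min_group=2)
        scores = scan_alignment(default_dataset.grouped(), groupings=cands)
        planted = set(default_dataset.truth["column"])
        best = {s.column_index: s for s in scores}
        truth_id = "auto_" + "+".join(f"g1s{i}" for i in range(1, 9))
        hits = [best[c].grouping_id for c in planted if c in best]
        assert hits.count(truth_id) >= len(hits) - 1

    def test_no_scoreable_columns_returns_empty(self):
        grouped = make_grouped({c: ["-"] for c in ("Xa", "Ya", "Xb", "Yb")})
        assert scan_alignment(grouped) == []


class TestPercentileThreshold:
    def test_linear_interpolation_convention(self):
        scores = np.arange(100) / 100.0
        assert percentile_threshold(scores, 99) == pytest.approx(0.9801, abs=1e-12)

    def test_constant_and_max(self):
        assert percentile_threshold([0.3] * 10, 99) == pytest.approx(0.3)
        assert percentile_threshold([0.1, 0.9, 0.4], 100) == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 99)


class TestOrthologParalogMatching:
    def test_anchor_patterns(self):
        conserved = make_grouped({c: ["A"] for c in ("Xa", "Ya", "Xb", "Yb")})
        df = ortholog_paralog_matching(conserved)
        assert df.iloc[0]["ortholog_match"] == pytest.approx(1.0)
        assert df.iloc[0]["paralog_match"] == pytest.approx(1.0)

        inverted = make_grouped(
            {"Xa": ["A"], "Yb": ["A"], "Ya": ["C"], "Xb": ["C"]}
        )
        df = ortholog_paralog_matching(inverted)
        assert df.iloc[0]["ortholog_match"] == pytest.approx(0.0)
        assert df.iloc[0]["paralog_match"] == pytest.approx(1.0)

        copy_specific = make_grouped(
            {"Xa": ["A"], "Ya": ["A"], "Xb": ["C"], "Yb": ["C"]}
        )
        df = ortholog_paralog_matching(copy_specific)
        assert df.iloc[0]["ortholog_match"] == pytest.approx(1.0)
        assert df.iloc[0]["paralog_match"] == pytest.approx(0.0)


class TestReferenceMapping:
    def test_ungapped_and_gapped_positions(self):
        from parinv.align_io import SequenceRecord
        records = [SequenceRecord(id="ref", residues="A-CD"),
                   SequenceRecord(id="other", residues="AACD")]
        assert map_column_to_reference(records, "ref", 3) == (2, "C", True)
        assert map_column_to_reference(records, "ref", 1) == (1, "A", True)
        pos, res, exact = map_column_to_reference(records, "ref", 2)
        assert (pos, res, exact) == (1, "A", False)

    def test_single_residue_reference(self):
        from parinv.align_io import SequenceRecord
        records = [SequenceRecord(id="ref", residues="MKV")]
        assert map_column_to_reference(records, "ref", 1) == (1, "M", True)

    def test_unknown_reference_rejected(self):
        from parinv.align_io import SequenceRecord
        records = [SequenceRecord(id="a", residues="M")]
        with pytest.raises(KeyError):
            map_column_to_reference(records, "nope", 1)
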