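"""Log-odds profiles, backgrounds, and motif topology prediction."""

import math

import numpy as np
import pytest

from motifgraph.graph import UNCLASSIFIED, MotifGraph
from motifgraph.motifs import MotifLabel
from motifgraph.profiles import (AA_INDEX, BackgroundFrequencies,
                                 PositionCounts, annotate_graph, build_lop,
                                 classify_all, classify_motif,
                                 collect_position_counts, dataset_background,
                                 natural_background)
from motifgraph.sequence_io import (AMINO_ACIDS, NTM, TM, ProteinRecord,
                                    TMSegment)
from motifgraph.motifs import extract_occurrences
from motifgraph.synthetic import (DEFAULT_NTM_COMPOSITION,
                                  DEFAULT_TM_COMPOSITION,
                                  sample_position_counts)

UNIFORM = BackgroundFrequencies({aa: 0.05 for aa in AMINO_ACIDS})


def uniform_counts(label, state, per_cell):
    """Counts exactly proportional to the uniform background."""
    counts = np.full((label.n - 1, 20), per_cell, dtype=np.int64)
    return PositionCounts(label=label, state=state, counts=counts,
                          total_occurrences=20 * per_cell)


class TestBackground:
    def test_builtin_sums_to_one(self):
        bg = natural_background("builtin")
        assert math.isclose(sum(bg.q.values()), 1.0, abs_tol=1e-12)
        assert all(v > 0 for v in bg.q.values())

    def test_dataset_mode_degenerate_composition(self):
        bg = dataset_background([ProteinRecord("p1", "A" * 1000)])
        assert bg.q["A"] > 0.95
        floor = bg.q["W"]
        assert 0 < floor < 0.01  # pseudocount keeps others positive
        assert all(math.isclose(bg.q[a], floor) for a in AMINO_ACIDS
                   if a != "A")

    def test_dataset_mode_rejects_empty(self):
        with pytest.raises(ValueError, match="at least one residue"):
            natural_background("dataset", records=[])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            BackgroundFrequencies({aa: 0.04 for aa in AMINO_ACIDS})
        bad = {aa: 0.05 for aa in AMINO_ACIDS}
        bad.pop("A")
        with pytest.raises(ValueError, match="20 amino acids"):
            BackgroundFrequencies(bad)


class TestCollectPositionCounts:
    def make_occurrences(self, residue_strings, label_n=5):
        """LG-anchored occurrences with prescribed variable residues."""
        occs = []
        for i, var in enumerate(residue_strings):
            assert len(var) == label_n - 1
            seq = "L" + var + "G"
            seg = TMSegment(f"p{i}", 0, len(seq), seq)
            occs.extend(o for o in extract_occurrences(seg, {label_n})
                        if o.offset == 0)
        return occs

    def test_column_sums_equal_occurrence_count(self):
        occs = self.make_occurrences(["AVIL"] * 10)
        counts = collect_position_counts({TM: occs})
        pc = counts[("LG5", TM)]
        assert pc.total_occurrences == 10
        assert pc.counts.sum(axis=1).tolist() == [10, 10, 10, 10]
        assert pc.counts[0, AA_INDEX["A"]] == 10
        assert pc.counts[3, AA_INDEX["L"]] == 10

    def test_state_exclusive_motifs_have_single_entry(self):
        occs = self.make_occurrences(["AVIL"] * 3)
        counts = collect_position_counts({TM: occs, NTM: []})
        assert ("LG5", TM) in counts
        assert ("LG5", NTM) not in counts

    def test_x_at_variable_position_skipped(self, caplog):
        occs = self.make_occurrences(["AVIL", "AVIL"])
        # hand-build an occurrence with 'X' in the variable window
        with caplog.at_level("WARNING"):
            seg = TMSegment("px", 0, 5, "LAXVG")
            from motifgraph.motifs import MotifOccurrence, make_label
            bad = MotifOccurrence(seg, 0, make_label("L", "G", 4))
            counts = collect_position_counts({TM: occs + [bad]})
        assert counts[("LG5", TM)].total_occurrences == 2
        assert ("LG4", TM) not in counts
        assert any("skipping" in m for m in caplog.messages)


class TestBuildLop:
    def test_background_matching_counts_give_zero(self):
        pc = uniform_counts(MotifLabel("L", "G", 5), TM, per_cell=3)
        lop = build_lop(pc, UNIFORM, pseudocount=0.0)
        assert np.allclose(lop.values, 0.0)

    def test_doubled_frequency_is_one_bit(self):
        # all 20 cells observed once (f = 0.05 everywhere); background
        # halved for 'A' so f(A) = 2 q(A) exactly
        pc = uniform_counts(MotifLabel("L", "G", 4), TM, per_cell=1)
        q = {aa: 0.05 * 0.975 / 0.95 for aa in AMINO_ACIDS}
        q["A"] = 0.025
        lop = build_lop(pc, BackgroundFrequencies(q), pseudocount=0.0)
        assert np.allclose(lop.values[:, AA_INDEX["A"]], 1.0)

    def test_pseudocount_keeps_values_finite(self):
        counts = np.zeros((3, 20), dtype=np.int64)
        counts[:, AA_INDEX["A"]] = 7
        pc = PositionCounts(MotifLabel("L", "G", 4), TM, counts, 7)
        lop = build_lop(pc, UNIFORM, pseudocount=1.0)
        assert np.isfinite(lop.values).all()

    def test_zero_pseudocount_with_zero_count_errors(self):
        counts = np.zeros((3, 20), dtype=np.int64)
        counts[:, AA_INDEX["A"]] = 7
        pc = PositionCounts(MotifLabel("L", "G", 4), TM, counts, 7)
        with pytest.raises(ValueError, match="positive pseudocount"):
            build_lop(pc, UNIFORM, pseudocount=0.0)

    def test_pseudocount_continuity_toward_raw_log_odds(self):
        pc = uniform_counts(MotifLabel("L", "G", 4), TM, per_cell=5)
        pc.counts[0, AA_INDEX["A"]] += 4
        pc.counts[0, AA_INDEX["C"]] -= 4
        raw = build_lop(pc, UNIFORM, pseudocount=0.0).values
        deviations = [
            np.max(np.abs(build_lop(pc, UNIFORM, pseudocount=eps).values
                          - raw))
            for eps in (1.0, 0.1, 0.01)
        ]
        assert deviations == sorted(deviations, reverse=True)
        assert deviations[-1] < 0.01


class TestClassifyMotif:
    label = MotifLabel("L", "G", 5)

    def tm_heavy_counts(self, n=50):
        rng = np.random.default_rng(0)
        return sample_position_counts(self.label, TM, n,
                                      DEFAULT_TM_COMPOSITION, rng)

    def test_single_profile_above_guard_wins(self):
        # mirrors calling a motif seen only outside the membrane as nTM
        rng = np.random.default_rng(1)
        pc = sample_position_counts(self.label, NTM, 50,
                                    DEFAULT_NTM_COMPOSITION, rng)
        lop = build_lop(pc, UNIFORM)
        cls = classify_motif(self.label, lop_tm=None, lop_ntm=lop,
                             min_occurrences=5)
        assert cls.state == NTM
        assert cls.n_ntm == 50 and cls.n_tm == 0

    def test_single_profile_below_guard_is_unclassified(self):
        rng = np.random.default_rng(2)
        pc = sample_position_counts(self.label, TM, 3,
                                    DEFAULT_TM_COMPOSITION, rng)
        lop = build_lop(pc, UNIFORM)
        cls = classify_motif(self.label, lop_tm=lop, min_occurrences=5)
        assert cls.state == UNCLASSIFIED

    def test_identical_evidence_ties_to_unclassified(self):
        pc_tm = uniform_counts(self.label, TM, 2)
        pc_ntm = uniform_counts(self.label, NTM, 2)
        cls = classify_motif(self.label,
                             build_lop(pc_tm, UNIFORM),
                             build_lop(pc_ntm, UNIFORM))
        assert cls.state == UNCLASSIFIED
        assert cls.score_tm == cls.score_ntm

    def test_score_symmetry_under_state_swap(self):
        rng = np.random.default_rng(3)
        a = sample_position_counts(self.label, TM, 40,
                                   DEFAULT_TM_COMPOSITION, rng)
        b = sample_position_counts(self.label, NTM, 40,
                                   DEFAULT_NTM_COMPOSITION, rng)
        fwd = classify_motif(self.label, build_lop(a, UNIFORM),
                             build_lop(b, UNIFORM))
        a_sw = PositionCounts(self.label, TM, b.counts, b.total_occurrences)
        b_sw = PositionCounts(self.label, NTM, a.counts, a.total_occurrences)
        rev = classify_motif(self.label, build_lop(a_sw, UNIFORM),
                             build_lop(b_sw, UNIFORM))
        assert fwd.score_tm == pytest.approx(rev.score_ntm)
        assert fwd.score_ntm == pytest.approx(rev.score_tm)

    def test_no_profiles_is_an_error(self):
        with pytest.raises(ValueError, match="no profile"):
            classify_motif(self.label)


def mixture_background():
    q = {aa: 0.5 * DEFAULT_TM_COMPOSITION[aa]
         + 0.5 * DEFAULT_NTM_COMPOSITION[aa] for aa in AMINO_ACIDS}
    return BackgroundFrequencies(q)


def recovery_accuracy(seed, n_labels=20, n_occ=200):
    """Fraction of state-exclusive labels classified to their state."""
    rng = np.random.default_rng(seed)
    counts = {}
    truth = {}
    hydrophobic = "ALVIGF"
    polar = "SNPYDK"
    for i in range(n_labels):
        n = 4 + i % 4
        if i % 2 == 0:
            lab = MotifLabel(hydrophobic[i % 6], hydrophobic[(i + 1) % 6], n)
            state, comp = TM, DEFAULT_TM_COMPOSITION
        else:
            lab = MotifLabel(polar[i % 6], polar[(i + 1) % 6], n)
            state, comp = NTM, DEFAULT_NTM_COMPOSITION
        truth[lab.text] = state
        counts[(lab.text, state)] = sample_position_counts(
            lab, state, n_occ, comp, rng)
    cls = classify_all(counts, mixture_background())
    return np.mean([cls[t].state == truth[t] for t in truth])


class TestParameterRecovery:
    def test_compositions_are_well_separated(self):
        p = np.array([DEFAULT_TM_COMPOSITION[a] for a in AMINO_ACIDS])
        q = np.array([DEFAULT_NTM_COMPOSITION[a] for a in AMINO_ACIDS])
        m = (p + q) / 2
        jsd = 0.5 * np.sum(p * np.log2(p / m)) + \
            0.5 * np.sum(q * np.log2(q / m))
        assert jsd >= 0.1

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_generating_state_recovered(self, seed):
        assert recovery_accuracy(seed) >= 0.9


class TestAnnotateGraph:
    def make_graph(self):
        g = MotifGraph()
        for lab in ("LL4", "AG4", "LG5"):
            g.add_motif(lab, count=1)
        g.add_edge_weight("LL4", "AG4")
        g.add_edge_weight("AG4", "LG5")
        return g

    def test_states_applied_from_table(self):
        g = self.make_graph()
        out = annotate_graph(g, {"LL4": TM, "AG4": NTM})
        assert out.node_attrs("LL4")["topology_state"] == TM
        assert out.node_attrs("AG4")["topology_state"] == NTM
        assert out.node_attrs("LG5")["topology_state"] == UNCLASSIFIED

    def test_empty_table_leaves_all_unclassified(self):
        out = annotate_graph(self.make_graph(), {})
        assert {out.node_attrs(n)["topology_state"]
                for n in out.nodes()} == {UNCLASSIFIED}

    def test_edges_and_input_untouched(self):
        g = self.make_graph()
        out = annotate_graph(g, {"LL4": TM})
        assert out.edges() == g.edges()
        assert g.node_attrs("LL4")["topology_state"] == UNCLASSIFIED
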