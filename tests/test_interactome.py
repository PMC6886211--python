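"""Interactome I/O, evidence-based weighting, and weight coarseness."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from locpath import (
    Interactome,
    estimate_evidence_probabilities,
    read_interactome,
    sample_negative_edges,
    weight_distribution,
    weight_edges,
    write_interactome,
)


def _write(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadInteractome:
    def test_three_line_file_reads_back(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.5\nB\tC\t0.5\nA\tC\t0.25\n")
        g = read_interactome(p)
        assert g.nodes == {"A", "B", "C"}
        assert g.n_edges() == 3
        assert g.weight("A", "C") == 0.25

    def test_duplicate_edge_keeps_max_weight_and_evidence_union(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.5\tx\nA\tB\t0.7\ty\n")
        g = read_interactome(p)
        assert g.n_edges() == 1
        assert g.weight("A", "B") == 0.7
        assert g.evidence("A", "B") == {"x", "y"}

    def test_weight_above_one_rejected_with_line_number(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.5\nA\tC\t1.5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_interactome(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.5\nA\tB\n")
        with pytest.raises(ValueError, match="line 2"):
            read_interactome(p)

    def test_zero_weight_edge_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-weight"):
            g = Interactome.from_edges([("A", "B", 0.0), ("B", "C", 0.5)])
        assert g.n_edges() == 1

    def test_roundtrip(self, tmp_path, diamond):
        p = tmp_path / "out.tsv"
        write_interactome(diamond, p)
        assert read_interactome(p) == diamond

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        p = _write(tmp_path, "# header\nA\tB\t0.5\n\n")
        assert read_interactome(p).n_edges() == 1


class TestEvidenceProbabilities:
    def _graph(self, n_pos, n_neg, label="t"):
        edges = []
        for i in range(n_pos):
            edges.append((f"p{i}", f"q{i}", 0.5, {label}))
        for i in range(n_neg):
            edges.append((f"n{i}", f"m{i}", 0.5, {label}))
        return Interactome.from_edges(edges), \
            {(f"p{i}", f"q{i}") for i in range(n_pos)}, \
            {(f"n{i}", f"m{i}") for i in range(n_neg)}

    @pytest.mark.parametrize(
        "n_pos, n_neg, pseudocount, expected",
        [
            (8, 2, 0.0, 0.8),       # direct count ratio
            (0, 0, 1.0, 0.5),       # symmetric smoothing (label only on held-out edge)
            (5, 0, 1.0, 6 / 7),     # smoothed one-sided counts
        ],
    )
    def test_probability_formula(self, n_pos, n_neg, pseudocount, expected):
        g, pos, neg = self._graph(max(n_pos, 1), n_neg)
        if n_pos == 0:
            # positives exist but carry a different label; 't' sees no counts
            g = Interactome.from_edges([("p0", "q0", 0.5, {"other"})])
            pos = {("p0", "q0")}
            model = estimate_evidence_probabilities(g, pos, set(), pseudocount=pseudocount)
            assert model.probability("t") == pytest.approx(expected)
            return
        model = estimate_evidence_probabilities(g, pos, neg, pseudocount=pseudocount)
        assert model.probabilities["t"] == pytest.approx(expected)

    def test_empty_positive_set_rejected(self):
        g, _, neg = self._graph(1, 1)
        with pytest.raises(ValueError, match="positive"):
            estimate_evidence_probabilities(g, set(), neg)

    def test_pseudocount_zero_matches_exhaustive_count_ratio(self):
        # independent oracle: count label occurrences by hand enumeration
        edges = [
            ("a", "b", 0.5, {"y2h"}),
            ("c", "d", 0.5, {"y2h", "coip"}),
            ("e", "f", 0.5, {"coip"}),
            ("g", "h", 0.5, {"y2h"}),
        ]
        g = Interactome.from_edges(edges)
        pos = {("a", "b"), ("c", "d")}
        neg = {("e", "f"), ("g", "h")}
        model = estimate_evidence_probabilities(g, pos, neg, pseudocount=0.0)
        # y2h: 2 positive, 1 negative; coip: 1 positive, 1 negative
        assert model.probabilities["y2h"] == pytest.approx(2 / 3)
        assert model.probabilities["coip"] == pytest.approx(1 / 2)


class TestWeightEdges:
    def _model(self, probs, ceiling=0.75):
        g = Interactome.from_edges([("p", "q", 0.5, {"t"})])
        m = estimate_evidence_probabilities(g, {("p", "q")}, set(), pseudocount=1.0)
        m.probabilities = dict(probs)
        m.weight_ceiling = ceiling
        return m

    def test_noisy_or_capped_at_ceiling(self):
        g = Interactome.from_edges([("A", "B", 0.5, {"t1", "t2"})])
        m = self._model({"t1": 0.8, "t2": 0.5})
        out = weight_edges(g, m)
        # raw 1 - 0.2*0.5 = 0.9, capped at 0.75
        assert out.weight("A", "B") == pytest.approx(0.75)

    def test_single_evidence_identity(self):
        g = Interactome.from_edges([("A", "B", 0.9, {"t"})])
        out = weight_edges(g, self._model({"t": 0.5}))
        assert out.weight("A", "B") == pytest.approx(0.5)

    def test_repeated_label_idempotent(self):
        g = Interactome.from_edges([("A", "B", 0.9, {"t1", "t1"})])
        out = weight_edges(g, self._model({"t1": 0.6}))
        assert out.weight("A", "B") == pytest.approx(0.6)

    def test_no_labels_requires_default(self):
        g = Interactome.from_edges([("A", "B", 0.9)])
        with pytest.raises(ValueError, match="no evidence"):
            weight_edges(g, self._model({"t": 0.5}))
        out = weight_edges(g, self._model({"t": 0.5}), default_label="t")
        assert out.weight("A", "B") == pytest.approx(0.5)

    @given(
        probs=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=4),
        extra=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_added_evidence_and_never_above_ceiling(self, probs, extra):
        labels = {f"t{i}": p for i, p in enumerate(probs)}
        g1 = Interactome.from_edges([("A", "B", 0.5, set(labels))])
        g2 = Interactome.from_edges([("A", "B", 0.5, set(labels) | {"x"})])
        m = self._model({**labels, "x": extra})
        raw1 = 1 - math.prod(1 - p for p in probs)
        raw2 = 1 - (1 - raw1) * (1 - extra)
        assert raw2 >= raw1
        w1, w2 = weight_edges(g1, m).weight("A", "B"), weight_edges(g2, m).weight("A", "B")
        assert w1 <= m.weight_ceiling + 1e-15
        assert w2 >= w1 - 1e-15


class TestNegativeSampling:
    def _grid(self, n=120):
        return Interactome.from_edges(
            [(f"u{i}", f"v{i}", 0.5) for i in range(n)]
        )

    def test_ratio_times_positives_sampled(self):
        g = self._grid()
        pos = {("u0", "v0"), ("u1", "v1")}
        neg = sample_negative_edges(g, pos, ratio=10, seed=7)
        assert len(neg) == 20
        assert not neg & pos

    def test_same_seed_reproducible(self):
        g = self._grid()
        pos = {("u0", "v0")}
        a = sample_negative_edges(g, pos, ratio=10, seed=3)
        b = sample_negative_edges(g, pos, ratio=10, seed=3)
        assert a == b

    def test_small_pool_returns_all_with_warning(self):
        g = self._grid(5)
        with pytest.warns(UserWarning, match="pool"):
            neg = sample_negative_edges(g, {("u0", "v0")}, ratio=20, seed=0)
        assert len(neg) == 4

    def test_annotated_endpoints_excluded(self):
        g = self._grid(10)
        neg = sample_negative_edges(
            g, {("u0", "v0")}, ratio=2, seed=0, annotated_nodes={"u1", "v2"}
        )
        assert all(u not in {"u1", "v2"} and v not in {"u1", "v2"} for u, v in neg)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            sample_negative_edges(self._grid(5), {("u0", "v0")}, ratio=0)


class TestWeightDistribution:
    def test_direct_count(self):
        g = Interactome.from_edges(
            [("A", "B", 0.6), ("B", "C", 0.6), ("C", "D", 0.6), ("D", "E", 0.3)]
        )
        assert weight_distribution(g, 1) == pytest.approx(0.75)

    def test_all_distinct_top_one(self):
        g = Interactome.from_edges([("A", "B", 0.1), ("B", "C", 0.2), ("C", "D", 0.3)])
        assert weight_distribution(g, 1) == pytest.approx(1 / 3)

    def test_monotone_in_top_m_and_saturates_at_one(self):
        g = Interactome.from_edges(
            [("A", "B", 0.6), ("B", "C", 0.6), ("C", "D", 0.3), ("D", "E", 0.2)]
        )
        fracs = [weight_distribution(g, m) for m in range(1, 5)]
        assert fracs == sorted(fracs)
        assert fracs[2] == 1.0  # top_m >= number of distinct weights

    def test_top_m_below_one_rejected(self, diamond):
        with pytest.raises(ValueError):
            weight_distribution(diamond, 0)
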