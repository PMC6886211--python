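"""Compartment dynamic program vs exhaustive labeling enumeration; re-ranking."""

import math

import numpy as np
import pytest

from locpath import (
    CYTOSOL,
    EXTMEM,
    MITOCHONDRIA,
    NUCLEUS,
    CompartmentModel,
    LocalizationTable,
    Path,
    RankedReconstruction,
    brute_force_signaling_score,
    group_ties,
    rerank,
    signaling_score,
)

TIERS = (0.0, 0.0, 0.25, 0.5, 1.0)  # zeros common enough to exercise infinities


def random_table(rng, proteins):
    return LocalizationTable(
        {
            p: {c: float(rng.choice(TIERS)) for c in (EXTMEM, CYTOSOL, NUCLEUS)}
            for p in proteins
        }
    )


class TestSignalingScore:
    def test_worked_three_node_instance(self, worked_table):
        """A:(ext 1, cyt .5, nuc 0), B:(.25, 1, .5), C:(0, .5, 1) -> -ln 0.25."""
        sa = signaling_score(("A", "B", "C"), worked_table)
        assert sa.cost == pytest.approx(-math.log(0.25), abs=1e-12)
        assert sa.cost == pytest.approx(
            brute_force_signaling_score(("A", "B", "C"), worked_table)
        )
        assert sa.labels[0] == EXTMEM and sa.labels[-1] == NUCLEUS

    def test_all_scores_one_zero_cost(self, all_ones_table):
        sa = signaling_score(("A", "B", "C", "D"), all_ones_table)
        assert sa.cost == 0.0

    def test_two_node_path_always_infinite(self, all_ones_table):
        """Single interactions cannot both start at the membrane and end in
        the nucleus, so length-one reconstructions are excluded."""
        sa = signaling_score(("A", "B"), all_ones_table)
        assert sa.cost == math.inf
        assert sa.labels is None

    def test_single_node_rejected(self, all_ones_table):
        with pytest.raises(ValueError):
            signaling_score(("A",), all_ones_table)

    def test_all_zero_protein_forces_infinity(self, all_ones_table):
        t = LocalizationTable(
            {
                "A": {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0},
                "B": {EXTMEM: 0.0, CYTOSOL: 0.0, NUCLEUS: 0.0},
                "C": {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0},
            }
        )
        assert signaling_score(("A", "B", "C"), t).cost == math.inf
        assert brute_force_signaling_score(("A", "B", "C"), t) == math.inf

    def test_matches_brute_force_on_random_paths(self):
        """DP == exhaustive enumeration on 1,000 seeded random instances."""
        rng = np.random.default_rng(11)
        for trial in range(1000):
            m = int(rng.integers(2, 9))
            proteins = [f"v{i}" for i in range(m)]
            table = random_table(rng, proteins)
            dp = signaling_score(proteins, table).cost
            bf = brute_force_signaling_score(proteins, table)
            if math.isinf(bf):
                assert math.isinf(dp), f"trial {trial}"
            else:
                assert dp == pytest.approx(bf, abs=1e-12), f"trial {trial}"

    def test_labels_obey_transition_relation_and_endpoints(self):
        rng = np.random.default_rng(5)
        model = CompartmentModel.default()
        checked = 0
        for _ in range(300):
            m = int(rng.integers(2, 8))
            proteins = [f"v{i}" for i in range(m)]
            table = random_table(rng, proteins)
            sa = signaling_score(proteins, table, model)
            if sa.labels is None:
                continue
            checked += 1
            assert sa.labels[0] == model.start and sa.labels[-1] == model.end
            for a, b in zip(sa.labels, sa.labels[1:]):
                assert model.allows(a, b)
        assert checked > 20

    def test_raising_a_score_never_increases_cost(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = int(rng.integers(2, 7))
            proteins = [f"v{i}" for i in range(m)]
            scores = {
                p: {c: float(rng.choice(TIERS)) for c in (EXTMEM, CYTOSOL, NUCLEUS)}
                for p in proteins
            }
            base_cost = signaling_score(proteins, LocalizationTable(scores)).cost
            p = proteins[int(rng.integers(0, m))]
            c = (EXTMEM, CYTOSOL, NUCLEUS)[int(rng.integers(0, 3))]
            raised = {q: dict(v) for q, v in scores.items()}
            raised[p][c] = min(1.0, scores[p][c] + float(rng.uniform(0.1, 1.0)))
            new_cost = signaling_score(proteins, LocalizationTable(raised)).cost
            assert new_cost <= base_cost + 1e-12

    def test_log_base_rescales_and_preserves_order(self):
        rng = np.random.default_rng(23)
        proteins = [f"v{i}" for i in range(5)]
        tables = [random_table(rng, proteins) for _ in range(20)]
        nat = [signaling_score(proteins, t).cost for t in tables]
        b10 = [signaling_score(proteins, t, base=10.0).cost for t in tables]
        for a, b in zip(nat, b10):
            if math.isinf(a):
                assert math.isinf(b)
            else:
                assert b == pytest.approx(a / math.log(10), rel=1e-9)
        assert np.argsort(nat, kind="stable").tolist() == np.argsort(b10, kind="stable").tolist()

    def test_generalized_chain_with_mitochondria(self):
        model = CompartmentModel.chain((EXTMEM, CYTOSOL, MITOCHONDRIA, NUCLEUS))
        table = LocalizationTable(
            {
                "A": {EXTMEM: 1.0, CYTOSOL: 0.5, MITOCHONDRIA: 0.0, NUCLEUS: 0.0},
                "B": {EXTMEM: 0.0, CYTOSOL: 1.0, MITOCHONDRIA: 0.5, NUCLEUS: 0.0},
                "C": {EXTMEM: 0.0, CYTOSOL: 0.0, MITOCHONDRIA: 1.0, NUCLEUS: 0.5},
                "D": {EXTMEM: 0.0, CYTOSOL: 0.0, MITOCHONDRIA: 0.0, NUCLEUS: 1.0},
            },
            compartments=(EXTMEM, CYTOSOL, MITOCHONDRIA, NUCLEUS),
        )
        dp = signaling_score(("A", "B", "C", "D"), table, model)
        bf = brute_force_signaling_score(("A", "B", "C", "D"), table, model)
        assert dp.cost == pytest.approx(bf)
        assert math.isfinite(dp.cost)


def _rec_from_scores(scores):
    paths = [
        Path((f"a{i}", f"b{i}", f"c{i}"), -math.log(s), s) for i, s in enumerate(scores)
    ]
    return RankedReconstruction(paths=paths, tie_groups=group_ties(paths))


class TestRerank:
    def _table(self, costs_by_protein):
        # protein localization chosen so path signaling cost is finite iff flagged
        return costs_by_protein

    def test_finite_beats_infinite_within_group(self):
        # two tied paths; second one localization-coherent, first not
        t = LocalizationTable(
            {
                "a0": {EXTMEM: 1.0, CYTOSOL: 0.0, NUCLEUS: 0.0},
                "b0": {EXTMEM: 0.0, CYTOSOL: 0.0, NUCLEUS: 1.0},
                "c0": {EXTMEM: 0.0, CYTOSOL: 0.0, NUCLEUS: 1.0},
                "a1": {EXTMEM: 1.0, CYTOSOL: 0.5, NUCLEUS: 0.0},
                "b1": {EXTMEM: 0.0, CYTOSOL: 1.0, NUCLEUS: 0.0},
                "c1": {EXTMEM: 0.0, CYTOSOL: 0.5, NUCLEUS: 1.0},
            }
        )
        rec = _rec_from_scores([0.25, 0.25])
        out = rerank(rec, t)
        assert [p.nodes[0] for p in out.paths] == ["a1", "a0"]
        assert math.isinf(out.signaling_costs[1])

    def test_equal_signaling_costs_keep_original_order(self, all_ones_table):
        paths = [
            Path(("A", "B", "C"), -math.log(0.5), 0.5),
            Path(("D", "E", "F"), -math.log(0.5), 0.5),
        ]
        t = LocalizationTable(
            {p: {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0} for p in "ABCDEF"}
        )
        rec = RankedReconstruction(paths=paths)
        out = rerank(rec, t)
        assert [p.nodes for p in out.paths] == [p.nodes for p in paths]

    def test_only_middle_group_permutes(self):
        # 3 groups; middle group's order flips, outer groups untouched
        t = LocalizationTable(
            {
                **{x: {EXTMEM: 1.0, CYTOSOL: 0.5, NUCLEUS: 0.5} for x in ("a0", "a1", "a3")},
                **{x: {EXTMEM: 0.5, CYTOSOL: 1.0, NUCLEUS: 0.5} for x in ("b0", "b1", "b3")},
                **{x: {EXTMEM: 0.5, CYTOSOL: 0.5, NUCLEUS: 1.0} for x in ("c0", "c1", "c3")},
                "a2": {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0},
                "b2": {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0},
                "c2": {EXTMEM: 1.0, CYTOSOL: 1.0, NUCLEUS: 1.0},
            }
        )
        rec = _rec_from_scores([0.5, 0.25, 0.25, 0.1])  # groups [0], [1,2], [3]
        out = rerank(rec, t)
        assert out.paths[0].nodes[0] == "a0"
        assert out.paths[3].nodes[0] == "a3"
        # within the middle group, the all-ones path (zero cost) wins
        assert out.paths[1].nodes[0] == "a2"
        assert out.paths[2].nodes[0] == "a1"

    def test_conservation_of_paths_scores_and_groups(self):
        rng = np.random.default_rng(31)
        scores = sorted(
            [float(rng.choice([0.5, 0.25, 0.25, 0.25, 0.125])) for _ in range(12)],
            reverse=True,
        )
        rec = _rec_from_scores(scores)
        proteins = {n for p in rec.paths for n in p.nodes}
        t = random_table(rng, proteins)
        out = rerank(rec, t)
        assert sorted(p.nodes for p in out.paths) == sorted(p.nodes for p in rec.paths)
        assert out.scores() == rec.scores()
        assert group_ties(out.paths) == rec.tie_groups
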