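import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import loop_strength_bruteforce, reachable_targets_bruteforce
from conftest import make_profile
from retcomm.profiles import summarize_profiles
from retcomm.scoring import (LRPair, ScoringParams, SignalingNetwork,
                             aggregate_celltype_scores, combine_score,
                             downstream_targets, filter_interactions,
                             find_lr_loops, network_support,
                             score_interactions)

UNIT = st.floats(0.0, 1.0, allow_nan=False)


def random_network(rng, n_nodes=12, n_edges=25):
    nodes = [f"n{i}" for i in range(n_nodes)]
    n_edges = min(n_edges, n_nodes * (n_nodes - 1))  # feasibility cap
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.choice(n_nodes, 2, replace=False)
        kind = "signaling" if rng.random() < 0.6 else "regulatory"
        edges.add((nodes[i], nodes[j], kind))
    return SignalingNetwork(sorted(edges))


class TestNetworkSupport:
    def toy(self):
        # receptor R -> a -> b (signaling); b -> t1..t4 (regulatory)
        edges = [("R", "a", "signaling"), ("a", "b", "signaling")]
        edges += [("b", f"t{i}", "regulatory") for i in range(1, 5)]
        return SignalingNetwork(edges)

    def test_all_targets_expressed(self):
        prof = make_profile("x", "control", {f"t{i}": 1.0 for i in range(1, 5)},
                            {f"t{i}": 0.9 for i in range(1, 5)})
        assert network_support("R", prof, self.toy(), ScoringParams()) == 1.0

    def test_empty_target_set(self):
        prof = make_profile("x", "control", {"g": 1.0})
        net = SignalingNetwork([("a", "b", "signaling")])
        assert network_support("R", prof, net, ScoringParams()) == 0.0

    def test_half_expressed_on_toy_graph(self):
        det = {"t1": 0.5, "t2": 0.5, "t3": 0.05, "t4": 0.0}
        prof = make_profile("x", "control", {k: 1.0 for k in det}, det)
        net = self.toy()
        params = ScoringParams()
        assert network_support("R", prof, net, params) == 0.5
        oracle = reachable_targets_bruteforce("R", net.edges, params.K)
        assert downstream_targets("R", net, params.K) == oracle == {"t1", "t2", "t3", "t4"}

    def test_k_limits_path_length(self):
        edges = [(f"n{i}", f"n{i+1}", "signaling") for i in range(5)]
        edges.append(("n5", "t", "regulatory"))
        net = SignalingNetwork(edges)
        assert downstream_targets("n0", net, 5) == {"t"}
        assert downstream_targets("n0", net, 4) == set()

    def test_matches_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            net = random_network(rng, n_nodes=rng.integers(5, 30),
                                 n_edges=rng.integers(5, 60))
            k = int(rng.integers(0, 5))
            for node in sorted(net.nodes):
                assert downstream_targets(node, net, k) == \
                    reachable_targets_bruteforce(node, net.edges, k)


class TestCombineScore:
    def test_maximal_case(self):
        s0, s_lr = combine_score(1.0, 1.0, 1.0, 0.0, 0.5, 0.5)
        assert s0 == 1.0 and s_lr == 1.0

    def test_zero_expression_gates_everything(self):
        s0, s_lr = combine_score(0.0, 1.0, 1.0, 0.9, 0.5, 0.9)
        assert s0 == 0.0 and s_lr == 0.0

    def test_hand_worked_example(self):
        s0, s_lr = combine_score(0.81, 0.49, 0.5, 0.4, 0.5, 0.5)
        assert s0 == pytest.approx(0.4725)
        assert s_lr == pytest.approx(0.578)

    @settings(max_examples=300, deadline=None)
    @given(e_l=UNIT, e_r=UNIT, n=UNIT, loop=UNIT, alpha=UNIT, gamma=UNIT)
    def test_bounds_and_ordering(self, e_l, e_r, n, loop, alpha, gamma):
        s0, s_lr = combine_score(e_l, e_r, n, loop, alpha, gamma)
        assert 0.0 <= s0 <= 1.0
        assert 0.0 <= s_lr <= 1.0 + 1e-12
        assert s_lr >= s0

    @settings(max_examples=200, deadline=None)
    @given(e_l=UNIT, e_r=UNIT, n=UNIT, loop=UNIT, alpha=UNIT, gamma=UNIT,
           bump=st.floats(1e-6, 1.0), coord=st.integers(0, 3))
    def test_monotone_in_each_coordinate(self, e_l, e_r, n, loop, alpha, gamma,
                                         bump, coord):
        args = [e_l, e_r, n, loop]
        _, before = combine_score(*args, alpha, gamma)
        args[coord] = min(1.0, args[coord] + bump)
        _, after = combine_score(*args, alpha, gamma)
        assert after >= before - 1e-12


def loop_toy():
    """Two cell groups with a reciprocal pair of interactions wired
    through the network."""
    pairs = [LRPair("Bdnf", "Ntrk2"), LRPair("Vegfa", "Flt1")]
    edges = [
        ("Ntrk2", "tfA", "signaling"), ("tfA", "Vegfa", "regulatory"),
        ("tfA", "h1", "regulatory"), ("tfA", "h2", "regulatory"),
        ("Flt1", "tfB", "signaling"), ("tfB", "Bdnf", "regulatory"),
        ("tfB", "h1", "regulatory"),
    ]
    network = SignalingNetwork(edges)
    # h2 is never expressed, so the forward receptor's support is 2/3
    # and the loop bonus is visible (S0 < 1)
    mean = {"Bdnf": 0.0, "Ntrk2": 0.0, "Vegfa": 0.0, "Flt1": 0.0,
            "h1": 1.0, "h2": 0.0}
    profiles = []
    for tp in ("control", "12h"):
        a = dict(mean); b = dict(mean)
        a["Bdnf"] = 1.0; a["Flt1"] = 0.72  # sender A expresses fwd ligand + rev receptor
        b["Ntrk2"] = 1.0; b["Vegfa"] = 0.5  # receiver B expresses fwd receptor + rev ligand
        det_a = {k: (0.9 if v > 0 else 0.0) for k, v in a.items()}
        det_b = {k: (0.9 if v > 0 else 0.0) for k, v in b.items()}
        profiles.append(make_profile("A", tp, a, det_a))
        profiles.append(make_profile("B", tp, b, det_b))
    return pairs, network, profiles


class TestFindLRLoops:
    def test_empty_network_no_loops(self):
        pairs, _, profiles = loop_toy()
        net = SignalingNetwork([])
        for pair in pairs:
            assert find_lr_loops(pair, "A", "B", pairs, net, profiles,
                                 ScoringParams()) == 0.0

    def test_symmetric_two_pair_toy(self):
        pairs, network, profiles = loop_toy()
        params = ScoringParams(alpha=0.5, gamma=0.5, K=3)
        # reverse pair Vegfa->Flt1 from B to A: e_L = 0.5/0.5 = 1 (gene max
        # is in B), e_R = 0.72/0.72 = 1, n_support = 1 -> S0 = 1? scale by
        # design: only B expresses Vegfa, only A expresses Flt1.
        lam = find_lr_loops(pairs[0], "A", "B", pairs, network, profiles, params)
        # independent enumeration
        def s0_lookup(rev, sender, receiver, tp):
            from retcomm.scoring import _ProfileIndex, _base_score
            idx = _ProfileIndex(profiles)
            s0, _ = _base_score(LRPair(*rev), sender, receiver, idx, network, params, tp)
            return s0
        expected, partners = loop_strength_bruteforce(
            ("Bdnf", "Ntrk2"), "A", "B", [("Bdnf", "Ntrk2"), ("Vegfa", "Flt1")],
            network.edges, s0_lookup, params.K, ["control", "12h"])
        assert partners == [("Vegfa", "Flt1")]
        assert lam == pytest.approx(expected)
        assert lam > 0.0

    def test_one_direction_only_no_loop(self):
        pairs, network, profiles = loop_toy()
        edges = [e for e in network.edges if e != ("tfB", "Bdnf", "regulatory")]
        net = SignalingNetwork(edges)
        assert find_lr_loops(pairs[0], "A", "B", pairs, net, profiles,
                             ScoringParams()) == 0.0

    def test_loop_strength_with_known_reverse_s0(self):
        # engineer the reverse S0 to 0.6 and confirm it propagates
        pairs, network, profiles = loop_toy()
        params = ScoringParams(alpha=0.2, gamma=0.5)
        from retcomm.scoring import _ProfileIndex, _base_score
        idx = _ProfileIndex(profiles)
        rev_s0, _ = _base_score(pairs[1], "B", "A", idx, network, params, "12h")
        lam = find_lr_loops(pairs[0], "A", "B", pairs, network, profiles, params)
        assert lam == pytest.approx(rev_s0)


class TestScoreInteractions:
    def test_scores_table_shape_and_bounds(self):
        pairs, network, profiles = loop_toy()
        scores = score_interactions(profiles, pairs, network, ScoringParams())
        # 2 pairs x 2 senders x 2 receivers x 2 timepoints
        assert len(scores) == 16
        for col in ("e_L", "e_R", "n_support", "S0", "loop_strength", "S_LR"):
            assert scores[col].between(0, 1).all()
        assert (scores["S_LR"] >= scores["S0"] - 1e-12).all()
        assert ((scores["S0"] > 0) | (scores["S_LR"] == 0)).all()

    def test_loop_bonus_applied(self):
        pairs, network, profiles = loop_toy()
        params = ScoringParams()
        scores = score_interactions(profiles, pairs, network, params)
        row = scores[(scores.sender == "A") & (scores.receiver == "B") &
                     (scores.ligand == "Bdnf") & (scores.timepoint == "12h")].iloc[0]
        assert row["loop_strength"] > 0
        s0, s_lr = combine_score(row["e_L"], row["e_R"], row["n_support"],
                                 row["loop_strength"], params.alpha, params.gamma)
        assert row["S0"] == pytest.approx(s0)
        assert row["S_LR"] == pytest.approx(s_lr)
        assert row["S_LR"] > row["S0"]

    def test_loop_symmetry_both_directions_qualify(self):
        pairs, network, profiles = loop_toy()
        scores = score_interactions(profiles, pairs, network, ScoringParams())
        fwd = scores[(scores.sender == "A") & (scores.receiver == "B") &
                     (scores.ligand == "Bdnf")]
        rev = scores[(scores.sender == "B") & (scores.receiver == "A") &
                     (scores.ligand == "Vegfa")]
        for tp in ("control", "12h"):
            f = fwd[fwd.timepoint == tp].iloc[0]
            r = rev[rev.timepoint == tp].iloc[0]
            if f["loop_strength"] > 0:
                assert r["loop_strength"] >= f["S0"] - 1e-12

    def test_missing_gene_skipped_with_warning(self):
        pairs, network, profiles = loop_toy()
        with pytest.warns(UserWarning, match="absent"):
            scores = score_interactions(profiles, pairs + [LRPair("nope", "Ntrk2")],
                                        network, ScoringParams())
        assert "nope" not in set(scores["ligand"])

    def test_autocrine_pairs_scored(self):
        pairs, network, profiles = loop_toy()
        scores = score_interactions(profiles, pairs, network, ScoringParams())
        assert ((scores.sender == "A") & (scores.receiver == "A")).any()

    def test_matches_exhaustive_loop_oracle_on_random_networks(self):
        rng = np.random.default_rng(5)
        params = ScoringParams(K=2)
        for _ in range(5):
            genes = [f"n{i}" for i in range(10)]
            net = random_network(rng, n_nodes=10, n_edges=20)
            pairs = []
            while len(pairs) < 4:
                l, r = rng.choice(10, 2, replace=False)
                p = LRPair(genes[l], genes[r])
                if p not in pairs:
                    pairs.append(p)
            profiles = []
            for group in ("A", "B"):
                for tp in ("control", "12h"):
                    mean = dict(zip(genes, rng.uniform(0, 2, 10)))
                    det = dict(zip(genes, rng.uniform(0, 1, 10)))
                    profiles.append(make_profile(group, tp, mean, det))
            scores = score_interactions(profiles, pairs, net, params)
            from retcomm.scoring import _ProfileIndex, _base_score
            idx = _ProfileIndex(profiles)

            def s0_lookup(rev, sender, receiver, tp):
                s0, _ = _base_score(LRPair(*rev), sender, receiver, idx, net,
                                    params, tp)
                return s0

            for _, row in scores.iterrows():
                lam_tp = 0.0
                _, partners = loop_strength_bruteforce(
                    (row.ligand, row.receptor), row.sender, row.receiver,
                    [(p.ligand, p.receptor) for p in pairs], net.edges,
                    s0_lookup, params.K, [row.timepoint])
                for rev in partners:
                    lam_tp = max(lam_tp, s0_lookup(rev, row.receiver, row.sender,
                                                   row.timepoint))
                assert row.loop_strength == pytest.approx(lam_tp, abs=1e-12)


class TestFilterInteractions:
    def make_scores(self, s_lr_by_tp, sender="A", receiver="B",
                    ligand="Bdnf", receptor="Ntrk2"):
        rows = [(sender, receiver, ligand, receptor, tp, 1, 1, 1, v, 0, v)
                for tp, v in s_lr_by_tp.items()]
        return pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                           "receptor", "timepoint", "e_L", "e_R",
                                           "n_support", "S0", "loop_strength", "S_LR"])

    def profiles(self, det_l=0.5, det_r=0.5):
        mean = {"Bdnf": 1.0, "Ntrk2": 1.0}
        out = []
        for tp in ("control", "12h"):
            out.append(make_profile("A", tp, mean, {"Bdnf": det_l, "Ntrk2": 0.0}))
            out.append(make_profile("B", tp, mean, {"Bdnf": 0.0, "Ntrk2": det_r}))
        return out

    def test_detection_exactly_at_threshold_passes(self):
        scores = self.make_scores({"control": 0.9, "12h": 0.9})
        kept = filter_interactions(scores, self.profiles(det_l=0.10, det_r=0.10))
        assert len(kept) == 2

    def test_all_timepoints_below_half_removed(self):
        scores = self.make_scores({"control": 0.49, "12h": 0.49})
        kept = filter_interactions(scores, self.profiles())
        assert kept.empty

    def test_one_timepoint_above_half_retained_by_default(self):
        scores = self.make_scores({"control": 0.2, "12h": 0.6})
        kept = filter_interactions(scores, self.profiles())
        assert len(kept) == 2
        strict = ScoringParams(score_any_timepoint=False)
        assert filter_interactions(scores, self.profiles(), strict).empty

    def test_low_detection_removed(self):
        scores = self.make_scores({"control": 0.9, "12h": 0.9})
        kept = filter_interactions(scores, self.profiles(det_l=0.05))
        assert kept.empty

    def test_random_triples_match_bruteforce(self):
        rng = np.random.default_rng(7)
        genes = [f"L{i}" for i in range(10)] + [f"R{i}" for i in range(10)]
        tps = ("control", "12h", "24h", "48h")
        profiles = []
        det = {"A": {}, "B": {}}
        for group in ("A", "B"):
            for tp in tps:
                d = dict(zip(genes, rng.uniform(0, 0.4, len(genes))))
                det[group][tp] = d
                profiles.append(make_profile(group, tp, {g: 1.0 for g in genes}, d))
        rows = []
        for i in range(50):
            ligand, receptor = f"L{i % 10}", f"R{(i * 3) % 10}"
            for tp in tps:
                v = float(rng.uniform(0, 1))
                rows.append(("A", "B", ligand, receptor, tp, 1, 1, 1, v, 0, v))
        scores = pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                             "receptor", "timepoint", "e_L", "e_R",
                                             "n_support", "S0", "loop_strength", "S_LR"])
        params = ScoringParams()
        kept = filter_interactions(scores, profiles, params)
        kept_keys = set(map(tuple, kept[["ligand", "receptor"]].drop_duplicates().to_numpy()))
        expected = set()
        for (ligand, receptor), grp in scores.groupby(["ligand", "receptor"]):
            dl = max(det["A"][tp][ligand] for tp in tps)
            dr = max(det["B"][tp][receptor] for tp in tps)
            if dl >= 0.10 and dr >= 0.10 and grp["S_LR"].max() >= 0.5:
                expected.add((ligand, receptor))
        assert kept_keys == expected

    def test_tightening_thresholds_monotone(self):
        rng = np.random.default_rng(11)
        genes = [f"L{i}" for i in range(6)] + [f"R{i}" for i in range(6)]
        tps = ("control", "12h")
        profiles = []
        for group in ("A", "B"):
            for tp in tps:
                d = dict(zip(genes, rng.uniform(0, 0.5, len(genes))))
                profiles.append(make_profile(group, tp, {g: 1.0 for g in genes}, d))
        rows = []
        for i in range(30):
            for tp in tps:
                v = float(rng.uniform(0, 1))
                rows.append(("A", "B", f"L{i % 6}", f"R{(i * 5) % 6}", tp,
                             1, 1, 1, v, 0, v))
        scores = pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                             "receptor", "timepoint", "e_L", "e_R",
                                             "n_support", "S0", "loop_strength", "S_LR"])
        n_base = len(filter_interactions(scores, profiles, ScoringParams()))
        for params in (ScoringParams(detection_min=0.3),
                       ScoringParams(score_min=0.8)):
            assert len(filter_interactions(scores, profiles, params)) <= n_base


class TestAggregate:
    def frame(self, vals):
        rows = [("A", "B", f"l{i}", f"r{i}", "control", 1, 1, 1, v, 0, v)
                for i, v in enumerate(vals)]
        return pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                           "receptor", "timepoint", "e_L", "e_R",
                                           "n_support", "S0", "loop_strength", "S_LR"])

    def test_empty_sum_is_zero(self):
        assert aggregate_celltype_scores(self.frame([]), "A", "B") == 0.0

    def test_hand_sum(self):
        assert aggregate_celltype_scores(self.frame([0.6, 0.7]), "A", "B") == \
            pytest.approx(1.3)

    def test_permutation_invariant(self):
        vals = [0.1, 0.9, 0.4, 0.6]
        a = aggregate_celltype_scores(self.frame(vals), "A", "B")
        b = aggregate_celltype_scores(self.frame(vals[::-1]), "A", "B")
        assert a == pytest.approx(b)

    def test_per_timepoint_breakdown(self):
        frame = self.frame([0.6, 0.7])
        out = aggregate_celltype_scores(frame, "A", "B", per_timepoint=True)
        assert out.loc[0, "overall_score"] == pytest.approx(1.3)
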