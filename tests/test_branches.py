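"""Branch enumeration, flux-processing capacity and synergism."""

import numpy as np
import pytest

from tnfnet.branches import (
    Branch,
    branch_capacity,
    enumerate_branches,
    node_capacity,
    synergism,
    synergism_trace,
)
from tnfnet.flux import FluxTraces
from tnfnet.network import Edge, Term, build_network


def _dfs_all_paths(adj, source, target, max_len):
    """Brute-force simple-path oracle (independent of networkx)."""
    out = []

    def walk(node, path):
        if len(path) - 1 > max_len:
            return
        if node == target:
            out.append(tuple(path))
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in path:
                walk(nxt, path + [nxt])

    walk(source, [source])
    return sorted(out)


def _toy_net(edge_pairs, signs=None):
    nodes = sorted({n for e in edge_pairs for n in e})
    edges = [
        {"source": a, "target": b,
         "sign": (signs or {}).get((a, b), "activation"),
         "rate_law": "mass_action", "params": [f"k_{a}_{b}"]}
        for a, b in edge_pairs
    ]
    return build_network({"entities": nodes, "edges": edges})


def _toy_fluxes(edge_values, time=None):
    """FluxTraces with prescribed constant (or array) per-edge fluxes."""
    time = np.asarray([0.0, 1.0] if time is None else time, dtype=float)
    terms, vals = [], []
    for (a, b), v in edge_values.items():
        e = Edge(a, b, "activation", "mass_action", (f"k_{a}_{b}",))
        terms.append(Term(e.label, "edge", b, 1, lambda y, u: 0.0, e))
        arr = np.broadcast_to(np.asarray(v, dtype=float), time.shape).copy()
        vals.append(arr)
    return FluxTraces(time, tuple(terms), np.array(vals),
                      np.ones(len(terms), dtype=int), "toy")


class TestEnumeration:
    def test_curated_nfkb_to_pakt_path_present(self, net):
        branches = enumerate_branches(net, "NFkB", "AKT")
        seqs = {b.nodes for b in branches}
        assert ("NFkB", "PTEN", "PI3K", "AKT") in seqs
        b = next(b for b in branches if b.nodes == ("NFkB", "PTEN", "PI3K", "AKT"))
        assert b.signs == ("inhibition", "inhibition", "activation")

    def test_triangle_has_two_paths(self):
        net = _toy_net([("A", "B"), ("B", "C"), ("A", "C")])
        assert [b.nodes for b in enumerate_branches(net, "A", "C")] == [
            ("A", "B", "C"), ("A", "C")]

    def test_disconnected_pair_empty(self):
        net = _toy_net([("A", "B"), ("C", "D")])
        assert enumerate_branches(net, "A", "D") == []

    def test_source_equals_target_rejected(self, net):
        with pytest.raises(ValueError):
            enumerate_branches(net, "AKT", "AKT")

    def test_max_len_cutoff(self):
        net = _toy_net([("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")])
        assert len(enumerate_branches(net, "A", "D", max_len=1)) == 1
        assert len(enumerate_branches(net, "A", "D", max_len=3)) == 2

    def test_matches_dfs_oracle_on_random_digraphs(self):
        """100 random DAGs and 20 random digraphs (<= 10 nodes)."""
        rng = np.random.default_rng(2024)
        names = [f"N{i}" for i in range(10)]
        checked = {"dag": 0, "digraph": 0}
        targets = {"dag": 100, "digraph": 20}
        while any(checked[k] < targets[k] for k in checked):
            kind = "dag" if checked["dag"] < targets["dag"] else "digraph"
            n = int(rng.integers(4, 11))
            p = rng.uniform(0.15, 0.5)
            pairs = set()
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    if kind == "dag" and j < i:
                        continue  # DAG: edges only forward
                    if rng.random() < p:
                        pairs.add((names[i], names[j]))
            if not pairs:
                continue
            net = _toy_net(sorted(pairs))
            adj = {}
            for a, b in pairs:
                adj.setdefault(a, set()).add(b)
            src, tgt = names[0], names[n - 1]
            if src not in net.entities or tgt not in net.entities:
                continue
            max_len = int(rng.integers(2, 9))
            got = [b.nodes for b in enumerate_branches(net, src, tgt, max_len)]
            assert got == _dfs_all_paths(adj, src, tgt, max_len)
            checked[kind] += 1


class TestCapacity:
    def test_direct_ratio(self):
        fx = _toy_fluxes({("A", "K"): 4.0, ("K", "B"): 2.0})
        cap = node_capacity("K", fx)
        assert np.allclose(cap.capacity, 0.5)

    def test_balanced_node_is_one(self):
        fx = _toy_fluxes({("A", "K"): 3.0, ("K", "B"): 1.0, ("K", "C"): 2.0})
        assert np.allclose(node_capacity("K", fx).capacity, 1.0)

    def test_zero_inbound_flagged_missing(self):
        fx = _toy_fluxes({("K", "B"): 2.0})
        assert np.all(np.isnan(node_capacity("K", fx).capacity))

    def test_toy_chain_hand_computed(self):
        fx = _toy_fluxes({("A", "B"): [1.0, 2.0, 4.0], ("B", "C"): [3.0, 3.0, 1.0]},
                         time=[0.0, 1.0, 2.0])
        assert np.allclose(node_capacity("B", fx).capacity, [3.0, 1.5, 0.25])

    def test_network_mode(self):
        fx = _toy_fluxes({("A", "K"): 4.0, ("K", "B"): 2.0})
        assert np.allclose(node_capacity("K", fx, mode="network").capacity, 2.0 / 6.0)


class TestBranchCapacity:
    def test_single_edge_branch(self):
        fx = _toy_fluxes({("A", "K"): 4.0, ("K", "B"): 2.0})
        b = Branch("b1", ("A", "K"), ("activation",))
        r = branch_capacity(b, fx)
        # |J_A->K| x C_K = 4 * (2/4)
        assert np.allclose(r, 2.0)

    def test_unit_fluxes_and_capacities_give_one(self):
        fx = _toy_fluxes({("A", "B"): 1.0, ("B", "C"): 1.0, ("C", "D"): 1.0,
                          ("D", "E"): 1.0})
        b = Branch("b", ("A", "B", "C", "D"), ("activation",) * 3)
        assert np.allclose(branch_capacity(b, fx), 1.0)

    def test_three_factor_product_matches_explicit_evaluation(self):
        """R of a 3-edge branch equals |J1| C_1 * |J2| C_2 * |J3| C_3."""
        fx = _toy_fluxes({("N", "P"): 2.0, ("P", "Q"): 3.0, ("Q", "R"): 1.5,
                          ("R", "S"): 0.5})
        b = Branch("b", ("N", "P", "Q", "R"), ("inhibition", "inhibition",
                                               "activation"))
        c_p = 3.0 / 2.0
        c_q = 1.5 / 3.0
        c_r = 0.5 / 1.5
        assert np.allclose(branch_capacity(b, fx), (2.0 * c_p) * (3.0 * c_q)
                           * (1.5 * c_r))


class TestSynergism:
    def test_additive_case_zero(self):
        assert synergism(3.0, 1.0, 2.0) == pytest.approx(0.0)

    def test_superadditive_doubling(self):
        assert synergism(6.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_silent_combination(self):
        assert synergism(0.0, 1.0, 2.0) == pytest.approx(-1.0)

    def test_vanishing_denominator_flagged(self):
        s = synergism(np.array([1.0]), np.array([0.0]), np.array([0.0]))
        assert np.isnan(s[0])

    def test_sign_convention_on_constructed_toys(self):
        assert synergism(5.0, 1.0, 1.0) > 0  # super-additive
        assert synergism(1.0, 1.0, 1.0) < 0  # sub-additive

    def test_lower_bound_for_nonnegative_r(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 5, size=(200, 3))
        s = synergism(r[:, 0], r[:, 1], r[:, 2])
        s = s[~np.isnan(s)]
        assert np.all(s >= -1.0)


class TestSynergismTrace:
    def _fluxes_three_conditions(self, scale_a, scale_b, scale_comb):
        base = {("A", "B"): np.array([1.0, 2.0, 1.5]),
                ("B", "C"): np.array([0.5, 1.0, 2.0]),
                ("C", "D"): np.array([1.0, 1.0, 1.0])}
        t = [0.0, 1.0, 2.0]
        mk = lambda s: _toy_fluxes({k: s * v for k, v in base.items()}, time=t)
        return {"TNFa": mk(scale_a), "TPL": mk(scale_b), "TNFa+TPL": mk(scale_comb)}

    def test_identical_conditions_give_minus_half(self):
        fx = self._fluxes_three_conditions(1.0, 1.0, 1.0)
        b = Branch("b", ("A", "B", "C"), ("activation",) * 2)
        tr = synergism_trace(b, fx)
        assert np.allclose(tr.s, -0.5)

    def test_constructed_additive_case_is_zero(self):
        """Uniform flux scaling multiplies the single-edge branch capacity
        by the scale (node capacities are scale-invariant), so scales
        (1, 2, 3) make the combined condition exactly additive."""
        fx = self._fluxes_three_conditions(1.0, 2.0, 3.0)
        b = Branch("b", ("A", "B"), ("activation",))
        tr = synergism_trace(b, fx)
        assert np.allclose(tr.s, 0.0, atol=1e-12)

    def test_matches_pointwise_equations_on_toy_network(self):
        fx = self._fluxes_three_conditions(1.0, 0.5, 2.5)
        b = Branch("b", ("A", "B", "C"), ("activation",) * 2)
        tr = synergism_trace(b, fx)
        # independent pointwise evaluation
        def r_of(f):
            out = np.ones(3)
            for (a, c) in b.edges:
                j = np.abs(f.edge_flux(f"{a}>{c}"))
                inn = sum(np.abs(f.values[i]) for i, t in enumerate(f.terms)
                          if t.edge.target == c)
                outn = sum(np.abs(f.values[i]) for i, t in enumerate(f.terms)
                           if t.edge.source == c)
                out *= j * (outn / inn)
            return out
        expected = r_of(fx["TNFa+TPL"]) / (r_of(fx["TNFa"]) + r_of(fx["TPL"])) - 1
        assert np.allclose(tr.s, expected)

    def test_missing_condition_named(self):
        fx = self._fluxes_three_conditions(1.0, 1.0, 1.0)
        del fx["TPL"]
        b = Branch("b", ("A", "B"), ("activation",))
        with pytest.raises(KeyError, match="TPL"):
            synergism_trace(b, fx)

    def test_relabeling_off_branch_nodes_leaves_r_invariant(self):
        t = [0.0, 1.0]
        fx1 = _toy_fluxes({("A", "B"): 2.0, ("B", "C"): 1.0, ("X", "B"): 0.5},
                          time=t)
        fx2 = _toy_fluxes({("A", "B"): 2.0, ("B", "C"): 1.0, ("Zed", "B"): 0.5},
                          time=t)
        b = Branch("b", ("A", "B"), ("activation",))
        assert np.allclose(branch_capacity(b, fx1), branch_capacity(b, fx2))
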