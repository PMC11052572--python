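"""Confidence scoring against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusescreen import io as fio
from fusescreen.scoring import (
    PDockQParams,
    aggregate_ensemble,
    interface_contacts,
    interface_pae_summary,
    pdockq_chain_vs_rest,
    ranking_confidence,
)
from fusescreen.synthetic import ChainPlan, ContactPlan, ToyComplexSpec, build_toy_structure
from fusescreen.types import Atom, Chain, ModelScore, PAEMatrix, Residue, Structure


class TestRankingConfidence:
    @pytest.mark.parametrize(
        "iptm,ptm,expected",
        [(1.0, 1.0, 1.0), (1.0, 0.0, 0.8), (0.0, 1.0, 0.2), (0.5, 0.9, 0.58)],
    )
    def test_hand_arithmetic(self, iptm, ptm, expected):
        assert ranking_confidence(iptm, ptm) == pytest.approx(expected, abs=1e-12)

    @given(x=st.floats(0, 1))
    def test_equal_arguments_fixed_point(self, x):
        assert ranking_confidence(x, x) == pytest.approx(x, abs=1e-12)

    @given(
        a=st.floats(0, 1), b=st.floats(0, 1), c=st.floats(0, 1), d=st.floats(0, 1)
    )
    def test_monotone_and_bounded(self, a, b, c, d):
        lo_i, hi_i = sorted((a, c))
        lo_p, hi_p = sorted((b, d))
        assert ranking_confidence(hi_i, lo_p) >= ranking_confidence(lo_i, lo_p)
        assert ranking_confidence(lo_i, hi_p) >= ranking_confidence(lo_i, lo_p)
        rc = ranking_confidence(a, b)
        assert min(a, b) - 1e-12 <= rc <= max(a, b) + 1e-12

    @pytest.mark.parametrize("iptm,ptm", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, iptm, ptm):
        with pytest.raises(ValueError):
            ranking_confidence(iptm, ptm)


def _scores(rcs):
    return [
        ModelScore(f"model_{i + 1}", iptm=rc, ptm=rc, rank=i + 1)
        for i, rc in enumerate(rcs)
    ]


class TestAggregateEnsemble:
    def test_single_model(self):
        e = aggregate_ensemble(_scores([0.9]), ("A", "B"))
        assert e.top_rc == pytest.approx(0.9)
        assert e.mean_rc == pytest.approx(0.9)
        assert e.n_models == 1

    def test_mean_and_top(self):
        e = aggregate_ensemble(_scores([0.8, 0.6]), ("A", "B"))
        assert e.mean_rc == pytest.approx(0.7)
        assert e.top_rc == pytest.approx(0.8)
        assert e.top_iptm == pytest.approx(0.8)

    def test_25_model_ensemble_planted_mean(self):
        rng = np.random.default_rng(5)
        rcs = rng.uniform(0.3, 0.9, size=25)
        e = aggregate_ensemble(_scores(rcs), ("X", "Y"))
        assert e.n_models == 25
        assert e.mean_rc == pytest.approx(float(np.mean(rcs)), abs=1e-9)

    def test_permutation_invariant(self):
        rcs = [0.1, 0.5, 0.9, 0.3]
        a = aggregate_ensemble(_scores(rcs), ("A", "B"))
        b = aggregate_ensemble(_scores(rcs[::-1]), ("A", "B"))
        assert a.mean_rc == pytest.approx(b.mean_rc)
        assert a.top_rc == pytest.approx(b.top_rc)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_ensemble([], ("A", "B"))


def brute_force_contacts(structure, group_a, group_b, cutoff=8.0):
    """Independent double loop over all residue pairs."""
    n = 0
    res_a, res_b = set(), set()
    for ca in group_a:
        for cb in group_b:
            for r1 in structure.chain(ca).residues:
                for r2 in structure.chain(cb).residues:
                    a1, a2 = r1.contact_atom(), r2.contact_atom()
                    if a1 is None or a2 is None:
                        continue
                    if np.linalg.norm(a1.coord - a2.coord) <= cutoff:
                        n += 1
                        res_a.add((ca, r1.seq_id))
                        res_b.add((cb, r2.seq_id))
    return n, res_a, res_b


def random_two_chain_structure(rng, n_a=80, n_b=80, spread=25.0):
    def chain(cid, n):
        residues = []
        for i in range(n):
            pos = rng.uniform(-spread, spread, size=3)
            atoms = [Atom("CA", "C", pos), Atom("CB", "C", pos + rng.normal(scale=0.8, size=3))]
            residues.append(Residue(i + 1, "ALA", atoms))
        return Chain(cid, residues)

    return Structure("rand", [chain("A", n_a), chain("B", n_b)])


class TestInterfaceContacts:
    def test_far_apart_chains_have_none(self):
        spec = ToyComplexSpec(seed=0, chains=[ChainPlan("A", 20), ChainPlan("B", 20)])
        st = build_toy_structure(spec)
        n, residues = interface_contacts(st, ["A"], ["B"])
        assert n == 0 and residues["a"] == set()

    def test_planted_count_recovered(self, toy_structure):
        n, _ = interface_contacts(toy_structure, ["A"], ["B"])
        assert n == 12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        st = random_two_chain_structure(rng)
        n, residues = interface_contacts(st, ["A"], ["B"])
        n_ref, res_a, res_b = brute_force_contacts(st, ["A"], ["B"])
        assert n == n_ref
        assert residues["a"] == res_a and residues["b"] == res_b

    def test_symmetric(self, toy_structure):
        n_ab, _ = interface_contacts(toy_structure, ["A"], ["B"])
        n_ba, _ = interface_contacts(toy_structure, ["B"], ["A"])
        assert n_ab == n_ba

    def test_overlapping_groups_rejected(self, toy_structure):
        with pytest.raises(ValueError):
            interface_contacts(toy_structure, ["A"], ["A", "B"])


def pdockq_oracle(mean_plddt, n_contacts, L=0.724, k=0.052, x0=152.611, b=0.018):
    """Hand-coded sigmoid, independent of the implementation path."""
    if n_contacts == 0:
        return b
    x = mean_plddt * math.log(n_contacts)
    return L / (1.0 + math.exp(-k * (x - x0))) + b


class TestPDockQ:
    def test_no_contacts_floor(self):
        spec = ToyComplexSpec(seed=0, chains=[ChainPlan("A", 20), ChainPlan("B", 20)])
        st = build_toy_structure(spec)
        s = pdockq_chain_vs_rest(st, "A")
        assert s.pdockq == pytest.approx(0.018)
        assert s.n_contacts == 0

    def test_sigmoid_asymptote(self):
        p = PDockQParams()
        assert pdockq_oracle(1e6, 100) == pytest.approx(p.L + p.b, abs=1e-9)

    def test_matches_oracle_on_planted_interface(self):
        # uniform pLDDT 80 on both chains -> interface mean is exactly 80
        spec = ToyComplexSpec(
            seed=3,
            chains=[ChainPlan("A", 60, plddt=80.0), ChainPlan("B", 60, plddt=80.0)],
            contacts=[ContactPlan("A", "B", 12)],
        )
        st = build_toy_structure(spec)
        s = pdockq_chain_vs_rest(st, "A")
        assert s.n_contacts == 12
        assert s.pdockq == pytest.approx(pdockq_oracle(80.0, 12), abs=1e-12)

    def test_strictly_inside_bounds_for_finite_interface(self, toy_structure):
        s = pdockq_chain_vs_rest(toy_structure, "B")
        assert 0.018 < s.pdockq < 0.742

    @given(n1=st.integers(1, 500), n2=st.integers(1, 500), plddt=st.floats(10, 100))
    def test_monotone_in_contacts(self, n1, n2, plddt):
        lo, hi = sorted((n1, n2))
        assert pdockq_oracle(plddt, lo) <= pdockq_oracle(plddt, hi) + 1e-15

    def test_single_chain_rejected(self):
        st = build_toy_structure(ToyComplexSpec(seed=0, chains=[ChainPlan("A", 10)]))
        with pytest.raises(ValueError):
            pdockq_chain_vs_rest(st, "A")


class TestInterfacePAE:
    def test_all_zero(self):
        pae = PAEMatrix(np.zeros((6, 6)), {"A": (0, 3), "B": (3, 6)})
        assert interface_pae_summary(pae, "A", "B") == (0.0, 0.0)

    def test_constant_block(self):
        v = np.zeros((4, 4))
        v[:2, 2:] = 5.0
        v[2:, :2] = 5.0
        pae = PAEMatrix(v, {"A": (0, 2), "B": (2, 4)})
        assert interface_pae_summary(pae, "A", "B") == (5.0, 5.0)

    def test_planted_block_recovered(self, toy_files):
        pae = fio.read_pae(toy_files["pae"], {"A": 60, "B": 60})
        mn, mean = interface_pae_summary(pae, "A", "B")
        assert mn == pytest.approx(12.5) and mean == pytest.approx(12.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_mean_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = 7, 9
        v = rng.uniform(0, 30, size=(n_a + n_b, n_a + n_b))
        pae = PAEMatrix(v, {"A": (0, n_a), "B": (n_a, n_a + n_b)})
        mn, mean = interface_pae_summary(pae, "A", "B")
        vals = [v[i, j] for i in range(n_a) for j in range(n_a, n_a + n_b)]
        vals += [v[i, j] for i in range(n_a, n_a + n_b) for j in range(n_a)]
        assert mn == pytest.approx(min(vals))
        assert mean == pytest.approx(float(np.mean(vals)))

    def test_unknown_chain_raises(self, toy_files):
        pae = fio.read_pae(toy_files["pae"], {"A": 60, "B": 60})
        with pytest.raises(KeyError):
            interface_pae_summary(pae, "A", "Z")
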