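from itertools import permutations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcassembler import geometry, scoring
from mcassembler.assembler import (AssemblyError, add_chain, applicable_actions,
                                   apply_action, assemble, evaluate_against_reference,
                                   initial_state, load_subcomponents)
from mcassembler.mcts import SearchConfig
from mcassembler.network import build_network
from mcassembler.structio import read_structure, write_fasta
from mcassembler.synthetic import (FixtureSpec, corrupt, generate_complex,
                                   slice_subcomponents)


def _net(truth, subs):
    return build_network(subs, truth.stoichiometry), {s.name: s for s in subs}


class TestAddChain:
    def test_identity_placement_from_own_subcomponent(self, cyclic10):
        """Adding B from dimer A-B onto A placed at the dimer's own coordinates
        lands B exactly at its subcomponent position (identity transform)."""
        truth, subs = cyclic10
        net, subs_d = _net(truth, subs)
        state = initial_state(net, subs_d, "S0")
        edge = net.edges[0]
        sub = subs_d[edge.source_sub]
        # seed chain is the subcomponent's own first chain, so the fit is exact
        new = add_chain(state, edge, ("S0", 0), subs_d, direction=0, edge_index=0)
        assert new is not None
        assert new.path[-1].anchor_rmsd == pytest.approx(0.0, abs=1e-9)
        placed_new = new.placed[new.path[-1].new_instance]
        expected = sub.chain(edge.chain_pair[1])
        np.testing.assert_allclose(placed_new.ca_coords, expected.ca_coords, atol=1e-9)

    def test_ring_closure_overlap_rejected(self, cyclic10):
        """Walking one step past a full ring tries to land on the seed chain."""
        truth, subs = cyclic10
        net, subs_d = _net(truth, subs)
        stoich = {"S0": 11}  # one more copy than the ring holds
        state = initial_state(net, subs_d, "S0")
        state = type(state)(state.placed, state.path, stoich, 0.0, iface=state.iface)
        rng = np.random.default_rng(4)
        while True:
            actions = applicable_actions(state, net)
            nxt = None
            for a in actions:
                nxt = apply_action(state, a, net, subs_d)
                if nxt is not None:
                    break
            if nxt is None:
                break
            state = nxt
        # every geometric slot is full: 10 placed, the 11th copy never fits
        assert state.n_placed == 10
        assert state.remaining == {"S0": 1}

    def test_lowest_unplaced_copy_instantiated(self, cyclic10):
        truth, subs = cyclic10
        net, subs_d = _net(truth, subs)
        state = initial_state(net, subs_d, "S0")
        for expected_copy in (1, 2):
            for a in applicable_actions(state, net):
                nxt = apply_action(state, a, net, subs_d)
                if nxt is not None:
                    state = nxt
                    break
            assert state.path[-1].new_instance == ("S0", expected_copy)

    def test_anchor_seq_mismatch_raises(self):
        truth = generate_complex(FixtureSpec("linear_tree", 3, oligomer="hetero", seed=11))
        subs = slice_subcomponents(truth, "native_dimers")
        net, subs_d = _net(truth, subs)
        state = initial_state(net, subs_d, "S0")
        edge_s1s2 = next(e for e in net.edges if "S0" not in e.seq_pair)
        with pytest.raises(AssemblyError, match="anchor"):
            add_chain(state, edge_s1s2, ("S0", 0), subs_d, direction=0)

    def test_input_state_not_mutated(self, cyclic10):
        truth, subs = cyclic10
        net, subs_d = _net(truth, subs)
        state = initial_state(net, subs_d, "S0")
        before = (dict(state.placed), state.path, state.score)
        add_chain(state, net.edges[0], ("S0", 0), subs_d, 0, 0)
        assert (state.placed, state.path, state.score) == before


class TestEvaluateAgainstReference:
    def test_model_equals_reference(self, tree8):
        truth, _ = tree8
        mapping, rmsd = evaluate_against_reference(truth.chains, truth.chains)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert mapping == {i: i for i in range(8)}

    def test_rigid_motion_invariance(self, tree8, rng):
        truth, _ = tree8
        R = Rotation.random(rng=rng).as_matrix()
        moved = [c.transformed(R, np.array([10.0, -5.0, 3.0])) for c in truth.chains]
        _, rmsd = evaluate_against_reference(moved, truth.chains)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_homomer_mapping_via_assignment(self, cyclic10, rng):
        """10 copies of one sequence: the factorial mapping space needs the
        assignment route, which must still recognise a rotated copy exactly."""
        truth, _ = cyclic10
        R = Rotation.from_euler("z", 2 * np.pi / 10).as_matrix()
        moved = [c.transformed(R, np.zeros(3)) for c in truth.chains]
        _, rmsd = evaluate_against_reference(moved, truth.chains)
        assert rmsd == pytest.approx(0.0, abs=1e-7)

    def test_displaced_chain_matches_bruteforce_minimum(self):
        truth = generate_complex(FixtureSpec("cyclic", 4, seed=8))
        model = [c.transformed(np.eye(3), np.zeros(3)) for c in truth.chains]
        model[2] = model[2].transformed(np.eye(3), np.array([10.0, 0, 0]))
        mapping, rmsd = evaluate_against_reference(model, truth.chains)

        def brute():
            best = np.inf
            for perm in permutations(range(4)):
                fixed = np.vstack([truth.chains[p].ca_coords for p in perm])
                mobile = np.vstack([m.ca_coords for m in model])
                _, r = geometry.superpose(fixed, mobile)
                best = min(best, r)
            return best

        assert rmsd == pytest.approx(brute(), abs=1e-9)
        assert rmsd > 1.0

    def test_contract_errors(self, tree8, rng):
        truth, _ = tree8
        with pytest.raises(AssemblyError):
            evaluate_against_reference(truth.chains, truth.chains[:4])
        orphan = truth.chains[0].renamed("Z")
        orphan.seq_id = "missing"
        with pytest.raises(AssemblyError):
            evaluate_against_reference([orphan], truth.chains)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    root = tmp_path_factory.mktemp("cyc6")
    truth = generate_complex(FixtureSpec("cyclic", 6, oligomer="hetero", seed=5))
    truth.write(root)
    slice_subcomponents(truth, "native_trimers", out_dir=root / "subcomponents")
    return root, truth


class TestAssemblePipeline:
    def test_end_to_end_complete_and_consistent(self, fixture_dir, tmp_path):
        root, truth = fixture_dir
        out = tmp_path / "out"
        result, report = assemble(
            root / "subcomponents", root / "sequences.fasta",
            root / "stoichiometry.txt",
            SearchConfig(max_iterations=150, no_improve_stop=40, seed=2,
                         restarts="single"),
            out_dir=out)
        assert result.complete
        assert report.completeness == 1.0
        # the written PDB alone reproduces the reported score (format precision)
        chains = read_structure(out / "assembly.pdb")
        assert scoring.complex_score(chains) == pytest.approx(report.total_score,
                                                              abs=0.5)
        _, rmsd = evaluate_against_reference(result.state.chains(), truth.chains)
        assert rmsd < 0.5
        for name in ("assembly.pdb", "report.json", "path_trace.json",
                     "search_log.jsonl", "chain_map.tsv"):
            assert (out / name).exists()

    def test_unknown_seq_in_stoichiometry(self, fixture_dir):
        root, _ = fixture_dir
        with pytest.raises(AssemblyError, match="unknown seq_id"):
            assemble(root / "subcomponents", root / "sequences.fasta",
                     "GHOST:6", SearchConfig(max_iterations=5, seed=0))

    def test_broken_ring_yields_flagged_partial(self, tmp_path):
        """Removing the only subcomponents realizing one tree edge caps completion."""
        truth = generate_complex(FixtureSpec("linear_tree", 5, oligomer="hetero", seed=6))
        subs = slice_subcomponents(truth, "native_dimers")
        subs = corrupt(subs, [("drop_edge", ("S2", "S3"))])
        sub_dir = tmp_path / "subs"
        sub_dir.mkdir()
        from mcassembler.structio import write_structure
        for s in subs:
            write_structure(s.chains, sub_dir / f"{s.name}.pdb")
        write_fasta(truth.sequences, tmp_path / "seqs.fasta")
        result, report = assemble(sub_dir, tmp_path / "seqs.fasta",
                                  {sid: 1 for sid in truth.sequences},
                                  SearchConfig(max_iterations=100,
                                               no_improve_stop=30, seed=1))
        assert not result.complete
        assert report.completeness < 1.0


def test_load_subcomponents_skips_wrong_chain_counts(tmp_path, cyclic10):
    truth, subs = cyclic10
    from mcassembler.structio import write_structure
    sub_dir = tmp_path / "subs"
    sub_dir.mkdir()
    write_structure(subs[0].chains, sub_dir / "good.pdb")
    write_structure([truth.chains[0]], sub_dir / "single.pdb")  # 1 chain: skipped
    loaded = load_subcomponents(sub_dir, truth.sequences)
    assert [s.name for s in loaded] == ["good"]
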