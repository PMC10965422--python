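import numpy as np
import pytest
from hypothesis import given, strategies as st

from cdrdesign import build_knn_edges, encode_sample, select_context
from cdrdesign.cdr_schemes import CdrSpec
from cdrdesign.graph_prep import (
    DegenerateGraphError,
    MASK_TOKEN,
    RoleError,
    anchor_line_coords,
    load_sample,
    save_sample,
)
from cdrdesign.structure_io import ChainRecord, ComplexRecord, ResidueRecord


def line_chain(chain_id, role, coords, seq=None):
    n = len(coords)
    seq = seq or "A" * n
    return ChainRecord(chain_id, role, [
        ResidueRecord(chain_id, i + 1, "", seq[i], np.asarray(coords[i], float))
        for i in range(n)
    ])


def antigen_at(y_values):
    return line_chain("A", "antigen", [[3.8 * i, y, 0.0] for i, y in enumerate(y_values)])


def design_chain(n=12):
    return line_chain("H", "heavy", [[3.8 * i, 0.0, 0.0] for i in range(n)])


class TestSelectContext:
    def test_distance_threshold_is_inclusive(self):
        cx = ComplexRecord("c", [design_chain(), antigen_at([20.0, 16.0, 10.0])])
        out = select_context(cx, "H", cutoff=16.0)
        ag = out.chain("A")
        # 20.0 Å residue excluded, exactly-16.0 and 10.0 kept
        assert [r.res_number for r in ag.residues] == [2, 3]

    def test_all_antigen_beyond_cutoff_drops_chain(self):
        cx = ComplexRecord("c", [design_chain(), antigen_at([30.0] * 3)])
        out = select_context(cx, "H", cutoff=16.0)
        assert [c.chain_id for c in out.chains] == ["H"]

    def test_design_chain_must_be_antibody(self):
        cx = ComplexRecord("c", [design_chain(), antigen_at([10.0])])
        with pytest.raises(RoleError):
            select_context(cx, "A")

    def test_retained_set_matches_brute_force_oracle(self, toy_complex):
        record, _, _ = toy_complex
        out = select_context(record, "H", cutoff=16.0)
        design_xyz = record.chain("H").coords()
        for chain in record.chains:
            if chain.role != "antigen":
                continue
            expected = []
            for res in chain.residues:  # pure-loop distance oracle
                dmin = min(
                    float(np.linalg.norm(res.ca_coord - x)) for x in design_xyz)
                if dmin <= 16.0:
                    expected.append((res.res_number, res.insertion_code))
            try:
                kept = [(r.res_number, r.insertion_code)
                        for r in out.chain(chain.chain_id).residues]
            except KeyError:
                kept = []
            assert kept == expected

    def test_partner_chain_kept_in_full(self, toy_complex):
        record, _, _ = toy_complex
        out = select_context(record, "H")
        assert len(out.chain("L")) == len(record.chain("L"))


class TestAnchorLineMasking:
    def test_closed_form_even_spacing(self):
        pts = anchor_line_coords(np.zeros(3), np.array([4.0, 0, 0]), 3)
        assert np.allclose(pts, [[1, 0, 0], [2, 0, 0], [3, 0, 0]])

    def test_single_residue_goes_to_midpoint(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([3.0, 0.0, 1.0])
        assert np.allclose(anchor_line_coords(a, b, 1), [(a + b) / 2])

    def test_coincident_anchors_degenerate_to_point(self):
        a = np.array([1.0, 1.0, 1.0])
        assert np.allclose(anchor_line_coords(a, a.copy(), 4), np.tile(a, (4, 1)))

    def test_masked_coords_are_interior_affine_combinations(self, toy_sample):
        rows = np.flatnonzero(toy_sample.mask == 1)
        lo, hi = rows[0] - 1, rows[-1] + 1
        a = toy_sample.truth_coords[lo]
        b = toy_sample.truth_coords[hi]
        n = rows.size
        for j, r in enumerate(rows, start=1):
            w = j / (n + 1)
            assert 0 < w < 1
            assert np.allclose(toy_sample.coords[r], (1 - w) * a + w * b, atol=1e-9)


class TestKnnEdges:
    def test_collinear_chain_connects_adjacent(self):
        coords = np.array([[i, 0.0, 0.0] for i in range(5)], dtype=float)
        edges = build_knn_edges(coords, k_neighbors=2)
        in_edges = {t: sorted(edges[edges[:, 1] == t][:, 0]) for t in range(5)}
        assert in_edges[2] == [1, 3]
        assert in_edges[0] == [1, 2]

    def test_small_graph_clamps_to_complete(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(10, 3))
        edges = build_knn_edges(coords, k_neighbors=64)
        counts = np.bincount(edges[:, 1], minlength=10)
        assert np.all(counts == 9)
        assert not np.any(edges[:, 0] == edges[:, 1])

    def test_matches_exhaustive_sort_oracle(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 30, size=(100, 3))
        edges = build_knn_edges(coords, k_neighbors=8)
        got = {t: set(edges[edges[:, 1] == t][:, 0]) for t in range(100)}
        for t in range(100):  # brute-force nearest-neighbour oracle
            d = [(np.linalg.norm(coords[t] - coords[s]), s)
                 for s in range(100) if s != t]
            d.sort()
            assert got[t] == {s for _, s in d[:8]}

    def test_degenerate_graph_raises(self):
        with pytest.raises(DegenerateGraphError):
            build_knn_edges(np.zeros((1, 3)))

    @given(seed=st.integers(0, 50))
    def test_permutation_consistency(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(20, 3)) * 10
        perm = rng.permutation(20)
        e1 = build_knn_edges(coords, k_neighbors=4)
        e2 = build_knn_edges(coords[perm], k_neighbors=4)
        # map node labels of e1 through the permutation and compare as sets
        inv = np.empty(20, dtype=int)
        inv[perm] = np.arange(20)
        mapped = {(inv[s], inv[t]) for s, t in e1}
        assert mapped == {(s, t) for s, t in e2}


class TestEncodeSample:
    def test_layout_antibody_then_antigen(self, toy_complex):
        record, cdr, _ = toy_complex
        context = select_context(record, "H")
        sample = encode_sample(context, cdr)
        n_ab = len(context.chain("H")) + len(context.chain("L"))
        assert np.all(sample.chain_type[:n_ab] == 0)
        assert np.all(sample.chain_type[n_ab:] == 1)
        assert sample.n_nodes == sum(len(c) for c in context.chains)
        assert sample.index_map[0] == ("H", 0)

    def test_masked_rows_have_mask_token_and_kept_truth(self, toy_sample):
        rows = toy_sample.mask == 1
        assert np.all(toy_sample.seq_tokens[rows] == MASK_TOKEN)
        assert np.all(toy_sample.truth_tokens <= 19)
        assert np.array_equal(
            toy_sample.coords[~rows], toy_sample.truth_coords[~rows])

    def test_reencoding_is_deterministic(self, toy_complex):
        record, cdr, _ = toy_complex
        context = select_context(record, "H")
        s1 = encode_sample(context, cdr)
        s2 = encode_sample(context, cdr)
        assert np.array_equal(s1.coords, s2.coords)
        assert np.array_equal(s1.edges, s2.edges)
        assert np.array_equal(s1.seq_tokens, s2.seq_tokens)

    def test_design_chain_only_when_no_context(self):
        cx = ComplexRecord("c", [design_chain(12), antigen_at([100.0] * 4)])
        spec = CdrSpec("H", "HCDR3", 4, 7)
        sample = encode_sample(select_context(cx, "H"), spec)
        assert sample.n_nodes == 12
        assert np.all(sample.chain_type == 0)

    def test_sample_roundtrip_through_npz(self, tmp_path, toy_sample):
        path = save_sample(toy_sample, tmp_path / "s.npz")
        back = load_sample(path)
        assert np.array_equal(back.coords, toy_sample.coords)
        assert np.array_equal(back.edges, toy_sample.edges)
        assert back.index_map == toy_sample.index_map
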