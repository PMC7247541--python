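import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimsap.scoring import (
    Enzyme,
    EpilocusMatrix,
    EpilocusState,
    FragmentPanel,
    align_panels,
    build_epilocus_matrix,
    filter_reproducibility,
    filter_size_range,
    panel_types,
    score_condition,
)


def make_panel(presence, enzyme=Enzyme.HPAII, sizes=None):
    presence = np.asarray(presence)
    n, m = presence.shape
    return FragmentPanel(
        enzyme=enzyme,
        sample_ids=[f"S{i}" for i in range(n)],
        locus_ids=[f"L{j}" for j in range(m)],
        presence=presence,
        fragment_sizes=sizes,
    )


class TestScoreCondition:
    def test_truth_table(self):
        assert score_condition(1, 1) == EpilocusState.NONMETH
        assert score_condition(0, 1) == EpilocusState.INTERNAL
        assert score_condition(1, 0) == EpilocusState.EXTERNAL
        assert score_condition(0, 0) == EpilocusState.AMBIG

    def test_exhaustive_and_unique(self):
        seen = {score_condition(h, m) for h in (0, 1) for m in (0, 1)}
        assert seen == set(EpilocusState)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            score_condition(2, 0)
        with pytest.raises(ValueError):
            score_condition(np.array([0, 1]), np.array([0, 0.5]))

    def test_vectorized(self):
        h = np.array([[1, 0], [1, 0]])
        m = np.array([[1, 1], [0, 0]])
        out = score_condition(h, m)
        assert out.tolist() == [
            [EpilocusState.NONMETH, EpilocusState.INTERNAL],
            [EpilocusState.EXTERNAL, EpilocusState.AMBIG],
        ]


class TestSizeFilter:
    def test_boundaries_inclusive(self):
        panel = make_panel(np.ones((2, 4)), sizes=[99, 100, 600, 601])
        out = filter_size_range(panel, 100, 600)
        assert out.locus_ids == ["L1", "L2"]

    def test_identity_when_all_in_range(self):
        panel = make_panel(np.ones((2, 3)), sizes=[150, 300, 450])
        out = filter_size_range(panel, 100, 600)
        assert out.locus_ids == panel.locus_ids

    def test_empty_result_warns(self):
        panel = make_panel(np.ones((2, 2)), sizes=[50, 700])
        with pytest.warns(UserWarning):
            out = filter_size_range(panel, 100, 600)
        assert out.n_loci == 0

    def test_invalid_range(self):
        panel = make_panel(np.ones((2, 2)), sizes=[150, 200])
        with pytest.raises(ValueError):
            filter_size_range(panel, 600, 100)


class TestReproducibility:
    def test_identical_replicates(self):
        p = make_panel(np.eye(4, dtype=int))
        out, rep = filter_reproducibility(p, p)
        assert rep.error_rate == 0.0
        assert rep.n_loci_retained == 4

    def test_single_discordance_strict(self):
        a = np.zeros((3, 3), dtype=int)
        b = a.copy()
        b[1, 2] = 1
        out, rep = filter_reproducibility(make_panel(a), make_panel(b))
        assert out.locus_ids == ["L0", "L1"]

    def test_hand_counted_error_rate(self):
        # 10 samples x 10 loci; 5 discordant calls spread over 3 loci
        a = np.zeros((10, 10), dtype=int)
        b = a.copy()
        b[0, 0] = 1
        b[1, 0] = 1
        b[2, 3] = 1
        b[3, 3] = 1
        b[4, 7] = 1
        out, rep = filter_reproducibility(make_panel(a), make_panel(b))
        assert rep.n_loci_retained == 7
        assert rep.error_rate == pytest.approx(0.05)

    def test_tolerance_superset_of_strict(self, rng):
        a = (rng.random((10, 20)) < 0.5).astype(int)
        b = a ^ (rng.random((10, 20)) < 0.1)
        strict, _ = filter_reproducibility(make_panel(a), make_panel(b.astype(int)))
        tol, _ = filter_reproducibility(
            make_panel(a), make_panel(b.astype(int)),
            mode="tolerance", max_mismatch_fraction=0.15,
        )
        assert set(strict.locus_ids) <= set(tol.locus_ids)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            filter_reproducibility(
                make_panel(np.zeros((2, 3), dtype=int)),
                make_panel(np.zeros((2, 2), dtype=int)),
            )


class TestBuildMatrix:
    def test_single_sample_expansion(self):
        hpa = make_panel([[1, 0, 1, 0]])
        msp = make_panel([[1, 1, 0, 0]], enzyme=Enzyme.MSPI)
        mat = build_epilocus_matrix(hpa, msp)
        row = mat.expanded().iloc[0].tolist()
        assert row == [1, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0]

    def test_all_nonmeth(self):
        hpa = make_panel(np.ones((3, 4), dtype=int))
        msp = make_panel(np.ones((3, 4), dtype=int), enzyme=Enzyme.MSPI)
        df = build_epilocus_matrix(hpa, msp).expanded()
        types = panel_types(df.columns)
        assert (np.asarray(df)[:, types == "n"] == 1).all()
        assert (np.asarray(df)[:, types != "n"] == 0).all()

    def test_counts_match_brute_force(self, rng):
        h = (rng.random((20, 50)) < 0.6).astype(int)
        m = (rng.random((20, 50)) < 0.6).astype(int)
        mat = build_epilocus_matrix(
            make_panel(h), make_panel(m, enzyme=Enzyme.MSPI)
        )
        expected = {s: 0 for s in EpilocusState}
        table = {
            (1, 1): EpilocusState.NONMETH,
            (0, 1): EpilocusState.INTERNAL,
            (1, 0): EpilocusState.EXTERNAL,
            (0, 0): EpilocusState.AMBIG,
        }
        for i in range(20):
            for j in range(50):
                expected[table[(h[i, j], m[i, j])]] += 1
        assert mat.state_counts() == expected

    def test_misaligned_samples_rejected(self):
        hpa = make_panel(np.ones((2, 2), dtype=int))
        msp = make_panel(np.ones((2, 2), dtype=int), enzyme=Enzyme.MSPI)
        msp.sample_ids = ["X0", "X1"]
        with pytest.raises(ValueError):
            build_epilocus_matrix(hpa, msp)

    def test_align_panels_matches_by_id(self):
        hpa = make_panel(np.ones((2, 3), dtype=int))
        msp = make_panel(np.ones((2, 3), dtype=int), enzyme=Enzyme.MSPI)
        msp.locus_ids = ["L2", "L0", "LX"]
        h, m = align_panels(hpa, msp)
        assert h.locus_ids == m.locus_ids == ["L0", "L2"]


class TestExpandedView:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_row_sums_at_most_one(self, seed):
        r = np.random.default_rng(seed)
        states = r.integers(0, 4, size=(5, 7))
        mat = EpilocusMatrix(
            sample_ids=[f"S{i}" for i in range(5)],
            locus_ids=[f"L{j}" for j in range(7)],
            states=states,
        )
        flat = np.asarray(mat.expanded()).reshape(5, 7, 3)
        sums = flat.sum(axis=2)
        assert np.isin(sums, (0, 1)).all()
        # AMBIG expands to exactly (0,0,0)
        assert ((states == 0) == (sums == 0)).all()

    def test_state_strings(self):
        mat = EpilocusMatrix(
            sample_ids=["a"], locus_ids=["x", "y"],
            states=np.array([[1, 0]]),
        )
        assert mat.state_strings().iloc[0].tolist() == ["100", "000"]


class TestPanelIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        panel = make_panel(
            (rng.random((4, 5)) < 0.5).astype(int),
            sizes=[110, 220, 330, 440, 550],
        )
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = FragmentPanel.read_tsv(path, Enzyme.HPAII)
        assert back.sample_ids == panel.sample_ids
        assert back.locus_ids == panel.locus_ids
        assert (back.presence == panel.presence).all()
        assert np.allclose(back.fragment_sizes, panel.fragment_sizes)

    def test_non_binary_value_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tL0\nS0\t2\n")
        with pytest.raises(ValueError):
            FragmentPanel.read_tsv(path, Enzyme.HPAII)
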