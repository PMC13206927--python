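from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ibrtox.ibr import (
    BiomarkerPanel,
    apply_direction,
    build_panel,
    compute_ibr,
    ddct_fold_change,
    infer_directions,
    order_sensitivity,
    panel_from_means,
    read_directions,
    standardize,
    star_area,
    translate_scores,
    write_scores_long,
)
from _oracles import ibr_chain_oracle, shoelace_star_area


class TestDdctFoldChange:
    @pytest.mark.parametrize(
        "tt, rt, tc, rc, expected",
        [
            (25.0, 20.0, 27.0, 22.0, 1.0),   # equal dCt both conditions
            (26.0, 20.0, 25.0, 20.0, 0.5),   # ddCt = +1
            (23.0, 20.0, 25.0, 20.0, 4.0),   # ddCt = -2
        ],
    )
    def test_analytic_values(self, tt, rt, tc, rc, expected):
        assert ddct_fold_change(tt, rt, tc, rc) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ddct_fold_change(float("nan"), 20.0, 25.0, 20.0)


class TestBuildPanel:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["group", "replicate", "biomarker", "value"])

    def test_identical_replicates(self):
        rows = [
            (g, r, b, 3.5)
            for g in ("c", "t")
            for b in ("m1", "m2")
            for r in (1, 2, 3)
        ]
        panel = build_panel(self._table(rows), {"m1": "up", "m2": "down"})
        assert np.allclose(panel.X, 3.5)

    def test_cell_mean(self):
        rows = [("c", r, "m1", v) for r, v in enumerate((1.0, 2.0, 3.0), 1)]
        rows += [("c", 1, "m2", 5.0), ("t", 1, "m1", 0.0), ("t", 1, "m2", 0.0)]
        panel = build_panel(self._table(rows), {"m1": "up", "m2": "up"})
        assert panel.as_frame().loc["c", "m1"] == pytest.approx(2.0)

    def test_missing_cell_names_combination(self):
        rows = [
            ("groupA", 1, "biomarker1", 1.0),
            ("groupA", 1, "biomarker2", 1.0),
            ("groupB", 1, "biomarker1", 1.0),
        ]
        with pytest.raises(ValueError, match=r"groupB.*biomarker2"):
            build_panel(
                self._table(rows), {"biomarker1": "up", "biomarker2": "up"}
            )

    def test_panel_invariant_violations(self):
        with pytest.raises(ValueError, match="2 groups"):
            panel_from_means(
                pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["a", "b"]),
                {"a": "up", "b": "up"},
            )
        with pytest.raises(ValueError, match="direction"):
            panel_from_means(
                pd.DataFrame(
                    [[1.0, 2.0], [3.0, 4.0]], index=["c", "t"], columns=["a", "b"]
                ),
                {"a": "up", "b": "sideways"},
            )


class TestStandardize:
    def _panel(self, X, biomarkers=None):
        X = np.asarray(X, dtype=float)
        biomarkers = biomarkers or [f"b{j}" for j in range(X.shape[1])]
        return BiomarkerPanel(
            groups=[f"g{i}" for i in range(X.shape[0])],
            biomarkers=biomarkers,
            directions={b: "up" for b in biomarkers},
            X=X,
        )

    def test_three_group_closed_form(self):
        # means 0,1,2: sample SD is exactly 1, so Y = (-1, 0, 1)
        Y, m, s = standardize(self._panel([[0.0, 0.0], [1.0, 10.0], [2.0, 20.0]]))
        assert m[0] == pytest.approx(1.0) and s[0] == pytest.approx(1.0)
        assert Y[:, 0] == pytest.approx([-1.0, 0.0, 1.0])

    def test_two_group_closed_form(self):
        # any two distinct values standardize to -/+ sqrt(2)/2 at ddof=1
        Y, _, _ = standardize(self._panel([[3.0, 100.0], [9.0, 7.0]]))
        r = math.sqrt(2) / 2
        assert Y[:, 0] == pytest.approx([-r, r])
        assert Y[:, 1] == pytest.approx([r, -r])

    def test_constant_biomarker_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            Y, _, s = standardize(self._panel([[5.0, 1.0], [5.0, 2.0]]))
        assert s[0] == 0.0 and np.all(Y[:, 0] == 0.0)

    def test_population_mode(self):
        Y, _, s = standardize(
            self._panel([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]), sd_mode="population"
        )
        assert s[0] == pytest.approx(math.sqrt(2.0 / 3.0))
        assert Y[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_column_moments(self):
        rng = np.random.default_rng(3)
        Y, _, _ = standardize(self._panel(rng.uniform(1, 9, size=(5, 4))))
        assert np.allclose(Y.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Y.std(axis=0, ddof=1), 1.0, atol=1e-12)


class TestDirectionAndTranslation:
    def test_direction_identity_and_flip(self):
        Y = np.array([[-1.0, -1.0, 0.0], [0.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        Z = apply_direction(Y, ["up", "down", "down"])
        assert Z[:, 0] == pytest.approx([-1.0, 0.0, 1.0])
        assert Z[:, 1] == pytest.approx([1.0, 0.0, -1.0])
        assert np.all(Z[:, 2] == 0.0)

    def test_unknown_direction_raises(self):
        with pytest.raises(ValueError, match="unknown direction"):
            apply_direction(np.zeros((2, 1)), ["sideways"])

    def test_translate_shifts_by_abs_min(self):
        Z = np.array([[-1.0], [0.0], [1.0]])
        assert translate_scores(Z)[:, 0] == pytest.approx([0.0, 1.0, 2.0])

    def test_translate_all_zero(self):
        assert np.all(translate_scores(np.zeros((3, 2))) == 0.0)

    def test_translate_positive_min_still_adds(self):
        # literal |min| shift: an all-positive column gets shifted up
        Z = np.array([[0.5], [1.5]])
        assert translate_scores(Z)[:, 0] == pytest.approx([1.0, 2.0])

    def test_global_scope(self):
        Z = np.array([[-2.0, 0.5], [1.0, 1.5]])
        S = translate_scores(Z, min_scope="global")
        assert S == pytest.approx(Z + 2.0)


class TestStarArea:
    def test_zero_scores(self):
        assert star_area([0.0, 0.0, 0.0]) == 0.0

    def test_square_of_ones(self):
        assert star_area([1.0, 1.0, 1.0, 1.0]) == pytest.approx(2.0)

    def test_triangle_of_ones(self):
        assert star_area([1.0, 1.0, 1.0]) == pytest.approx(
            3 * math.sin(math.radians(120)) / 2
        )

    @given(
        st.integers(min_value=2, max_value=8).flatmap(
            lambda k: st.lists(
                st.floats(min_value=0.0, max_value=10.0), min_size=k, max_size=k
            )
        )
    )
    def test_matches_shoelace_oracle(self, radii):
        assert star_area(radii) == pytest.approx(
            shoelace_star_area(radii), rel=1e-12, abs=1e-12
        )


class TestComputeIbr:
    def test_identical_groups_zero_index(self):
        panel = panel_from_means(
            pd.DataFrame(
                [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]],
                index=["a", "b", "c"],
                columns=["m1", "m2"],
            ),
            {"m1": "up", "m2": "down"},
        )
        with pytest.warns(UserWarning):
            result = compute_ibr(panel)
        assert all(v == 0.0 for v in result.ibr_index.values())

    def test_min_group_has_zero_radius(self, small_panel):
        result = compute_ibr(small_panel)
        S = result.S.to_numpy()
        assert np.all(S >= -1e-12)
        assert np.allclose(S.min(axis=0), 0.0, atol=1e-12)

    def test_matches_hand_chain_oracle(self, small_panel):
        result = compute_ibr(small_panel)
        want = ibr_chain_oracle(
            small_panel.X.tolist(),
            [small_panel.directions[b] for b in small_panel.biomarkers],
        )
        for got, w in zip(result.ibr_index.values(), want):
            assert got == pytest.approx(w, rel=1e-10)

    def test_star_coordinates_layout(self, small_panel):
        result = compute_ibr(small_panel)
        coords = result.star_coordinates["toxicant"]
        k = small_panel.n_biomarkers
        assert [a for a, _ in coords] == pytest.approx(
            [2 * math.pi * i / k for i in range(k)]
        )
        assert [r for _, r in coords] == pytest.approx(
            list(result.S.loc["toxicant"])
        )

    def test_affine_invariance(self, random_panel_factory):
        panel = random_panel_factory(11)
        base = compute_ibr(panel)
        X2 = panel.X.copy()
        rng = np.random.default_rng(12)
        X2 *= rng.uniform(0.5, 8.0, size=X2.shape[1])  # per-biomarker scale
        X2 += rng.uniform(-5.0, 5.0, size=X2.shape[1])  # per-biomarker offset
        rescaled = BiomarkerPanel(
            groups=panel.groups,
            biomarkers=panel.biomarkers,
            directions=panel.directions,
            X=X2,
        )
        again = compute_ibr(rescaled)
        assert np.allclose(base.Y, again.Y, atol=1e-10)
        assert np.allclose(base.S, again.S, atol=1e-10)
        for g in panel.groups:
            assert again.ibr_index[g] == pytest.approx(
                base.ibr_index[g], rel=1e-10, abs=1e-12
            )


class TestOrderSensitivity:
    def test_k3_is_order_invariant(self, random_panel_factory):
        panel = random_panel_factory(21, n_groups=3, n_bio=3)
        result = compute_ibr(panel)
        dist = order_sensitivity(result)
        assert np.allclose(dist["min"], dist["max"], atol=1e-12)
        assert np.allclose(dist["observed"], dist["median"], atol=1e-12)

    def test_equal_scores_invariant(self):
        panel = panel_from_means(
            pd.DataFrame(
                [[0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]],
                index=["c", "t"],
                columns=list("abcd"),
            ),
            {b: "up" for b in "abcd"},
        )
        dist = order_sensitivity(compute_ibr(panel))
        assert np.allclose(dist["min"], dist["max"], atol=1e-12)

    def test_k4_has_at_most_three_distinct_values(self, random_panel_factory):
        panel = random_panel_factory(31, n_groups=4, n_bio=4)
        result = compute_ibr(panel)
        S = result.S.to_numpy()
        import itertools

        for i in range(S.shape[0]):
            vals = {
                round(star_area(S[i, list(o)]), 9)
                for o in itertools.permutations(range(4))
            }
            assert len(vals) <= 3

    def test_sampled_orderings_deterministic(self, random_panel_factory):
        panel = random_panel_factory(41, n_groups=3, n_bio=7)
        result = compute_ibr(panel)
        d1 = order_sensitivity(result, n_permutations=200, seed=5)
        d2 = order_sensitivity(result, n_permutations=200, seed=5)
        pd.testing.assert_frame_equal(d1, d2)


class TestIOAndInference:
    def test_infer_directions(self):
        means = pd.DataFrame(
            [[1.0, 1.0], [2.0, 0.5], [1.5, 0.8]],
            index=["control", "t1", "t2"],
            columns=["m_up", "m_down"],
        )
        with pytest.warns(UserWarning, match="auto direction"):
            directions = infer_directions(means, "control")
        assert directions == {"m_up": "up", "m_down": "down"}

    def test_read_directions(self, tmp_path):
        p = tmp_path / "dirs.tsv"
        p.write_text("biomarker\tdirection\nAIF\tup\nATP\tDown\n", encoding="utf-8")
        assert read_directions(p) == {"AIF": "up", "ATP": "down"}
        p.write_text("AIF\tsideways\n", encoding="utf-8")
        with pytest.raises(ValueError, match="unknown direction"):
            read_directions(p)

    def test_write_scores_long(self, tmp_path, small_panel):
        result = compute_ibr(small_panel)
        out = tmp_path / "scores.tsv"
        write_scores_long(result, out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["group", "biomarker", "Y", "Z", "S"]
        assert len(df) == small_panel.n_groups * small_panel.n_biomarkers
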