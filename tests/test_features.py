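"""Feature assembly, correlation-based pruning and the replicate split."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from canopyagb.features import (
    SplitSpec,
    assemble,
    feature_columns,
    find_correlation,
    prune_features,
    split_by_repeat,
)
from canopyagb.pipeline import scenario_columns


def _truth(n_plots=6, periods=("P1", "P2")):
    rows = []
    for p in periods:
        for i in range(n_plots):
            rows.append(
                {
                    "plot_id": f"s{i + 1:02d}",
                    "repeat": i // 2 + 1,
                    "treatment": "N1",
                    "period": p,
                    "agb_kg_hm2": 100.0 * (i + 1),
                }
            )
    return pd.DataFrame(rows)


def _textures(truth, names=("R-GDS1-Con", "G-GDS1-Dis")):
    rng = np.random.default_rng(0)
    tex = truth[["plot_id", "period"]].copy()
    for name in names:
        tex[name] = rng.normal(size=len(tex))
    return tex


class TestAssemble:
    def test_row_count_is_plots_times_periods(self):
        truth = _truth()
        table = assemble([_textures(truth)], None, truth)
        assert len(table) == 12

    def test_feature_columns_sorted_and_complete(self):
        truth = _truth()
        heights = truth[["plot_id", "period"]].copy()
        heights["height_cm"] = 30.0
        table = assemble([_textures(truth)], heights, truth)
        assert feature_columns(table) == ["G-GDS1-Dis", "R-GDS1-Con", "height_cm"]

    def test_missing_key_is_reported(self):
        truth = _truth()
        tex = _textures(truth).iloc[:-1]
        with pytest.raises(ValueError, match="missing feature values"):
            assemble([tex], None, truth)

    def test_order_insensitive_to_input_row_order(self):
        truth = _truth()
        tex = _textures(truth)
        a = assemble([tex], None, truth)
        b = assemble([tex.iloc[::-1].reset_index(drop=True)], None, truth)
        pd.testing.assert_frame_equal(a, b)

    def test_scenario_union_contract(self, desk_table):
        cols = feature_columns(desk_table)
        union = scenario_columns(cols, "all+H")
        glcm = scenario_columns(cols, "GLCM-all")
        gabor = scenario_columns(cols, "Gabor-all")
        assert set(union) == set(glcm) | set(gabor) | {"height_cm"}

    def test_single_gds_scenario_has_24_texture_columns(self, desk_table):
        cols = scenario_columns(feature_columns(desk_table), "GDS1")
        assert len(cols) == 24


class TestFindCorrelation:
    def test_identity_removes_nothing(self):
        assert find_correlation(np.eye(5), 0.99) == []

    def test_three_variable_hand_trace(self):
        # r(A,B)=0.995, r(A,C)=0.3, r(B,C)=0.1 -> A has the larger mean |r|
        corr = np.array([[1.0, 0.995, 0.3], [0.995, 1.0, 0.1], [0.3, 0.1, 1.0]])
        assert find_correlation(corr, 0.99) == [0]

    def test_duplicated_column_removes_exactly_one(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert len(find_correlation(corr, 0.99)) == 1

    def test_never_removes_all_variables(self):
        n = 6
        corr = np.full((n, n), 0.999)
        np.fill_diagonal(corr, 1.0)
        removed = find_correlation(corr, 0.99)
        assert len(removed) == n - 1

    def test_no_surviving_pair_exceeds_cutoff(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            base = rng.normal(size=(30, 3))
            X = np.hstack([base, base + 0.05 * rng.normal(size=(30, 3))])
            corr = np.corrcoef(X, rowvar=False)
            removed = find_correlation(corr, 0.9)
            keep = [i for i in range(6) if i not in removed]
            sub = np.abs(corr[np.ix_(keep, keep)])
            np.fill_diagonal(sub, 0.0)
            assert sub.max() <= 0.9

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError):
            find_correlation(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.9)
        with pytest.raises(ValueError):
            find_correlation(np.array([[1.0, 2.0], [2.0, 1.0]]), 0.9)

    def test_matches_caret_reference_implementation(self, tmp_path):
        """Cross-check against R caret::findCorrelation(exact=TRUE)."""
        script = tmp_path / "fc.R"
        out = []
        cases = []
        for trial in range(4):
            rng = np.random.default_rng(trial)
            base = rng.normal(size=(40, 4))
            X = np.hstack(
                [base, base[:, :2] * (1 + 0.001 * rng.normal(size=(40, 2))),
                 rng.normal(size=(40, 2))]
            )
            corr = np.corrcoef(X, rowvar=False)
            path = tmp_path / f"corr{trial}.csv"
            np.savetxt(path, corr, delimiter=",")
            cases.append((path, corr))
        script.write_text(
            "\n".join(
                f'''m <- as.matrix(read.csv("{p}", header=FALSE));
                colnames(m) <- rownames(m) <- paste0("V", 1:ncol(m));
                cat(sort(caret::findCorrelation(m, cutoff=0.9, exact=TRUE))-1, sep=",");
                cat("\\n")'''
                for p, _ in cases
            )
        )
        try:
            res = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=120
            )
        except (FileNotFoundError, subprocess.TimeoutExpired):
            pytest.skip("Rscript unavailable")
        if res.returncode != 0:
            pytest.skip(f"caret unavailable: {res.stderr[:100]}")
        for line, (_, corr) in zip(res.stdout.strip().splitlines(), cases):
            theirs = sorted(int(v) for v in line.split(",")) if line else []
            assert find_correlation(corr, 0.9) == theirs


class TestPruneFeatures:
    def test_duplicate_feature_column_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=30)
        kept = prune_features(df, ["a", "b", "c"], 0.99)
        assert kept == ["b", "c"] or kept == ["a", "c"]
        assert len(kept) == 2


class TestSplitByRepeat:
    def test_default_design_splits_32_16_per_period(self, tiny_scene):
        truth = tiny_scene.truth
        one_period = truth[truth["period"] == "P1"]
        cal, val = split_by_repeat(one_period)
        assert len(cal) == 32
        assert len(val) == 16

    def test_partition_contract(self, tiny_scene):
        cal, val = split_by_repeat(tiny_scene.truth)
        assert len(cal) + len(val) == len(tiny_scene.truth)
        assert not set(map(tuple, cal[["plot_id", "period"]].values)) & set(
            map(tuple, val[["plot_id", "period"]].values)
        )

    def test_missing_calibration_repeats_is_error(self):
        truth = _truth()
        only_rep1 = truth[truth["repeat"] == 1]
        with pytest.raises(ValueError, match="calibration set is empty"):
            split_by_repeat(only_rep1)

    def test_uncovered_label_is_error(self):
        truth = _truth(n_plots=8)  # labels 1..4
        with pytest.raises(ValueError, match="not covered"):
            split_by_repeat(truth, SplitSpec())

    def test_overlapping_spec_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitSpec(calibration_repeats=(1, 2), validation_repeats=(2,))
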