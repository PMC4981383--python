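import json

import numpy as np
import pytest

from mixmc.containers import Lineage, NumericMatrix, Taxonomy
from mixmc.interpret import (
    POSITIVE_COLOR,
    NEGATIVE_COLOR,
    assign_contributions,
    confidence_ellipse,
    export_ellipses,
    export_graphlan,
)
from mixmc.splsda import fit_splsda


def make_matrix(values, otu_ids=None):
    values = np.asarray(values, dtype=float)
    return NumericMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        feature_ids=otu_ids or [f"otu{j}" for j in range(values.shape[1])],
    )


@pytest.fixture
def fitted_toy(rng):
    """Two classes separated on otu0/otu1; otu0 higher in class b."""
    labels = np.array(["a"] * 6 + ["b"] * 6)
    X = rng.normal(size=(12, 5), scale=0.2)
    X[labels == "b", 0] += 3.0
    X[labels == "a", 1] += 3.0
    mat = make_matrix(X)
    model = fit_splsda(mat, labels, n_comp=1, keepX=[2])
    return model, mat, labels


class TestAssignContributions:
    def test_class_with_higher_median_wins(self, fitted_toy):
        model, mat, labels = fitted_toy
        contrib = assign_contributions(model, mat, labels)
        row0 = contrib.frame[contrib.frame["otu_id"] == "otu0"].iloc[0]
        assert row0["assigned_class"] == "b"
        row1 = contrib.frame[contrib.frame["otu_id"] == "otu1"].iloc[0]
        assert row1["assigned_class"] == "a"

    def test_medians_match_direct_groupby(self, fitted_toy):
        model, mat, labels = fitted_toy
        contrib = assign_contributions(model, mat, labels)
        frame = mat.to_frame()
        for _, row in contrib.frame.iterrows():
            for cls in ("a", "b"):
                expected = frame.loc[labels == cls, row["otu_id"]].median()
                assert row[f"median_{cls}"] == pytest.approx(expected)

    def test_equal_medians_flagged_as_tie(self):
        # otu0: medians tie (2 vs 2) but means differ, so it keeps a
        # nonzero loading; otu1 separates the classes
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        vals = np.array(
            [[0.0, 5.0], [2.0, 6.0], [10.0, 7.0],
             [0.0, 0.0], [2.0, 1.0], [4.0, 2.0]]
        )
        mat = make_matrix(vals)
        model = fit_splsda(mat, labels, n_comp=1, keepX=[2])
        contrib = assign_contributions(model, mat, labels)
        tied = contrib.frame[contrib.frame["otu_id"] == "otu0"].iloc[0]
        assert tied["tie"]
        assert set(tied["tied_classes"].split("|")) == {"a", "b"}

    def test_rows_ordered_by_decreasing_importance(self, rng):
        labels = np.array(["a"] * 8 + ["b"] * 8)
        X = rng.normal(size=(16, 10))
        X[labels == "a", :3] += [3.0, 2.0, 1.0]
        mat = make_matrix(X)
        model = fit_splsda(mat, labels, n_comp=1, keepX=[5])
        contrib = assign_contributions(model, mat, labels)
        mags = contrib.frame["loading"].abs().to_numpy()
        assert np.all(np.diff(mags) <= 1e-12)
        assert contrib.frame["rank_in_component"].tolist() == list(range(1, 6))

    def test_row_count_equals_keepx_per_component(self, rng):
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        X = rng.normal(size=(30, 12))
        for k in range(3):
            X[labels == f"{'abc'[k]}", k] += 2
        mat = make_matrix(X)
        model = fit_splsda(mat, labels, n_comp=2, keepX=[4, 7])
        contrib = assign_contributions(model, mat, labels)
        assert len(contrib.for_component(1)) == 4
        assert len(contrib.for_component(2)) == 7

    def test_sample_permutation_leaves_output_unchanged(self, fitted_toy, rng):
        model, mat, labels = fitted_toy
        base = assign_contributions(model, mat, labels)
        perm = rng.permutation(mat.n_samples)
        mat_p = NumericMatrix(
            values=mat.values[perm],
            sample_ids=[mat.sample_ids[i] for i in perm],
            feature_ids=list(mat.feature_ids),
        )
        again = assign_contributions(model, mat_p, labels[perm])
        for col in ("otu_id", "assigned_class", "loading"):
            assert base.frame[col].tolist() == again.frame[col].tolist()

    def test_id_mismatch_rejected(self, fitted_toy):
        model, mat, labels = fitted_toy
        wrong = make_matrix(mat.values, otu_ids=[f"x{j}" for j in range(5)])
        with pytest.raises(ValueError, match="match"):
            assign_contributions(model, wrong, labels)

    def test_taxonomy_attached_at_requested_rank(self, fitted_toy):
        model, mat, labels = fitted_toy
        tax = Taxonomy({
            f"otu{j}": Lineage({"kingdom": "Bacteria", "family": f"Fam{j}"})
            for j in range(5)
        })
        contrib = assign_contributions(model, mat, labels, taxonomy=tax)
        sel = contrib.frame.iloc[0]
        assert sel["taxonomy"] == f"Fam{sel['otu_id'][-1]}"


class TestGraphlanExport:
    def _taxonomy(self, n=5):
        return Taxonomy({
            f"otu{j}": Lineage({
                "kingdom": "Bacteria", "phylum": "Firmicutes",
                "family": f"Fam{j}",
            })
            for j in range(n)
        })

    def test_loading_sign_sets_marker_color(self, fitted_toy, tmp_path):
        model, mat, labels = fitted_toy
        contrib = assign_contributions(model, mat, labels)
        out = tmp_path / "annot.txt"
        n = export_graphlan(contrib, self._taxonomy(), out)
        assert n == 2
        text = out.read_text()
        for _, row in contrib.frame.iterrows():
            expected = POSITIVE_COLOR if row["loading"] > 0 else NEGATIVE_COLOR
            line = [
                l for l in text.splitlines()
                if row["otu_id"] in l and "clade_marker_color" in l
            ]
            assert line and line[0].endswith(expected)

    def test_empty_table_writes_header_only(self, fitted_toy, tmp_path):
        model, mat, labels = fitted_toy
        contrib = assign_contributions(model, mat, labels)
        contrib.frame = contrib.frame.iloc[0:0]
        out = tmp_path / "annot.txt"
        n = export_graphlan(contrib, self._taxonomy(), out)
        assert n == 0
        lines = out.read_text().strip().splitlines()
        assert all("\tclade_marker" not in l for l in lines)

    def test_marker_sizes_monotone_in_medians(self, rng, tmp_path):
        labels = np.array(["a"] * 8 + ["b"] * 8)
        X = np.abs(rng.normal(size=(16, 5))) + 0.1
        X[labels == "a"] *= [5, 4, 3, 2, 1]
        mat = make_matrix(X)
        model = fit_splsda(mat, labels, n_comp=1, keepX=[4])
        contrib = assign_contributions(model, mat, labels)
        out = tmp_path / "annot.txt"
        export_graphlan(contrib, self._taxonomy(), out, tmp_path / "tree.txt")
        sizes = {}
        for line in out.read_text().splitlines():
            if "clade_marker_size" in line:
                clade, _, val = line.split("\t")
                sizes[clade.split(".")[-1]] = float(val)
        meds = {
            row["otu_id"]: row[f"median_{row['assigned_class'].split('|')[0]}"]
            for _, row in contrib.frame.iterrows()
        }
        otus = sorted(meds, key=meds.get)
        ordered = [sizes[o] for o in otus]
        assert all(a <= b + 1e-9 for a, b in zip(ordered, ordered[1:]))

    def test_missing_lineage_skipped_with_warning(self, fitted_toy, tmp_path, caplog):
        import logging

        model, mat, labels = fitted_toy
        contrib = assign_contributions(model, mat, labels)
        partial = Taxonomy({"otu0": Lineage({"kingdom": "Bacteria"})})
        with caplog.at_level(logging.WARNING, logger="mixmc.interpret"):
            n = export_graphlan(contrib, partial, tmp_path / "a.txt")
        assert n == 1
        assert any("no lineage" in r.message for r in caplog.records)


class TestConfidenceEllipse:
    def test_isotropic_class_gives_near_circular_ellipse(self, rng):
        scores = rng.normal(size=(500, 2))
        ell = confidence_ellipse(scores, ["a"] * 500)[0]
        ratio = ell.semi_axes[0] / ell.semi_axes[1]
        assert ratio == pytest.approx(1.0, abs=0.2)

    def test_axes_grow_with_level(self, rng):
        scores = rng.normal(size=(50, 2))
        labels = ["a"] * 50
        prev = 0.0
        for level in (0.5, 0.8, 0.95, 0.99):
            ell = confidence_ellipse(scores, labels, level=level)[0]
            assert ell.semi_axes[0] > prev
            prev = ell.semi_axes[0]

    def test_monte_carlo_coverage_matches_level(self, rng):
        """~95% of draws from the generating Gaussian fall inside the
        population 95% ellipse (large-sample fit)."""
        mean = np.array([1.0, -2.0])
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        fit_draws = rng.multivariate_normal(mean, cov, size=4000)
        ell = confidence_ellipse(fit_draws, ["a"] * 4000, level=0.95)[0]
        test_draws = rng.multivariate_normal(mean, cov, size=10000)
        inside = _inside_ellipse(test_draws, ell)
        assert inside.mean() == pytest.approx(0.95, abs=0.02)

    def test_degenerate_covariance_flagged(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        ell = confidence_ellipse(pts, ["a"] * 4)[0]
        assert ell.degenerate

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="< 3"):
            confidence_ellipse(rng.normal(size=(2, 2)), ["a", "a"])

    def test_json_export_round_trips(self, rng, tmp_path):
        scores = rng.normal(size=(30, 2))
        labels = ["a"] * 15 + ["b"] * 15
        ells = confidence_ellipse(scores, labels)
        path = tmp_path / "e.json"
        export_ellipses(ells, path)
        back = json.loads(path.read_text())
        assert [e["class"] for e in back] == ["a", "b"]
        assert back[0]["level"] == 0.95


def _inside_ellipse(points, ell):
    theta = np.radians(ell.angle_degrees)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rel = (points - np.asarray(ell.center)) @ R
    a, b = ell.semi_axes
    return (rel[:, 0] / a) ** 2 + (rel[:, 1] / b) ** 2 <= 1.0
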