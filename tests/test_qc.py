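import numpy as np
import pytest

from screenkit.formats import GctMatrix
from screenkit.qc import (
    DEFAULT_CORRELATION_THRESHOLD,
    QcReport,
    ReplicateMap,
    apply_removals,
    distribution_qc,
    pca_batch_report,
    replicate_correlation_qc,
    run_qc,
)

from .conftest import make_gct


def _matrix(columns: dict[str, np.ndarray]) -> GctMatrix:
    names = list(columns)
    values = np.column_stack([columns[c] for c in names])
    return GctMatrix(
        row_ids=[f"sh{i}" for i in range(values.shape[0])],
        row_descriptions=[""] * values.shape[0],
        column_ids=names,
        values=values,
    )


class TestCorrelationQc:
    def test_identical_replicates_pass(self, rng):
        v = rng.normal(size=50)
        m = _matrix({"A_r1": v, "A_r2": v.copy()})
        reps = ReplicateMap({"A_r1": "A", "A_r2": "A"})
        report = replicate_correlation_qc(m, reps, threshold=1.0)
        assert not report.failed_replicates

    def test_default_threshold_is_historical_constant(self):
        assert DEFAULT_CORRELATION_THRESHOLD == 0.6795

    def test_auto_threshold_matches_percentile_oracle(self, rng):
        # 3 lines x 2 reps; shared latent gives within-line rho ~0.9
        n = 400
        cols, reps = {}, {}
        for ln in "ABC":
            latent = rng.normal(size=n)
            for r in (1, 2):
                cols[f"{ln}_r{r}"] = latent + rng.normal(scale=1 / 3, size=n)
                reps[f"{ln}_r{r}"] = ln
        m = _matrix(cols)
        report = replicate_correlation_qc(m, ReplicateMap(reps), threshold="auto")
        names = list(cols)
        inter = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if reps[names[i]] != reps[names[j]]:
                    inter.append(np.corrcoef(cols[names[i]], cols[names[j]])[0, 1])
        assert report.correlation_threshold == pytest.approx(np.percentile(inter, 75))

    def test_degenerate_replicate_fails(self, rng):
        m = _matrix({"A_r1": np.zeros(20), "A_r2": rng.normal(size=20)})
        report = replicate_correlation_qc(m, ReplicateMap({"A_r1": "A", "A_r2": "A"}), 0.5)
        assert "degenerate" in report.failed_replicates["A_r1"]

    def test_raising_threshold_never_unfails(self, rng):
        cols = {f"A_r{k}": rng.normal(size=60) for k in range(4)}
        m = _matrix(cols)
        reps = ReplicateMap({c: "A" for c in cols})
        failed_low = set(replicate_correlation_qc(m, reps, 0.2).failed_replicates)
        failed_high = set(replicate_correlation_qc(m, reps, 0.9).failed_replicates)
        assert failed_low <= failed_high

    def test_verdicts_invariant_to_column_order(self, rng):
        cols = {f"L{j}_r{k}": rng.normal(size=40) for j in range(2) for k in range(3)}
        reps = ReplicateMap({c: c.split("_")[0] for c in cols})
        m1 = _matrix(cols)
        m2 = _matrix(dict(reversed(list(cols.items()))))
        r1 = replicate_correlation_qc(m1, reps, 0.5)
        r2 = replicate_correlation_qc(m2, reps, 0.5)
        assert set(r1.failed_replicates) == set(r2.failed_replicates)


class TestDistributionQc:
    def test_identical_columns_all_pass(self):
        m = make_gct(np.tile(np.arange(10.0)[:, None], (1, 4)))
        assert not distribution_qc(m).failed_replicates

    def test_outlier_fails_by_mean_minus_sd(self):
        # 9 columns scoring 5 and one scoring 0: cutoff = 4.5 - 1.5 = 3.0
        values = np.full((20, 10), 5.0)
        values[:, 9] = 0.0
        m = make_gct(values)
        report = distribution_qc(m)
        scores = np.array(list(report.distribution_scores.values()))
        assert report.distribution_cutoff == pytest.approx(
            scores.mean() - scores.std()
        )
        assert list(report.failed_replicates) == [m.column_ids[9]]

    def test_normal_scores_fail_rate_matches_tail(self, rng):
        from scipy.stats import norm

        # constant columns: each column's 75th percentile IS its N(0,1) draw
        draws = rng.normal(size=1000)
        m = make_gct(np.tile(draws, (3, 1)))
        report = distribution_qc(m)
        frac = len(report.failed_replicates) / 1000
        assert frac == pytest.approx(norm.cdf(-1), abs=0.04)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            distribution_qc(make_gct(np.zeros((5, 1))))


class TestApplyRemovals:
    def _quad(self, rng, fail=()):
        cols = {}
        reps = {}
        for ln in ("A", "B"):
            latent = rng.normal(size=50)
            for k in range(4):
                name = f"{ln}_r{k}"
                cols[name] = latent + rng.normal(scale=0.1, size=50)
                reps[name] = ln
        m = _matrix(cols)
        report = QcReport()
        for name in fail:
            report.fail(name, "correlation")
        return m, report, ReplicateMap(reps)

    def test_no_failures_identity(self, rng):
        m, report, reps = self._quad(rng)
        out = apply_removals(m, report, reps)
        assert out.column_ids == m.column_ids
        np.testing.assert_array_equal(out.values, m.values)

    def test_line_with_two_passing_fully_removed(self, rng):
        m, report, reps = self._quad(rng, fail=("A_r0", "A_r1"))
        out = apply_removals(m, report, reps, min_passing=3)
        assert [c for c in out.column_ids if c.startswith("A")] == []
        assert len([c for c in out.column_ids if c.startswith("B")]) == 4

    def test_single_failure_leaves_three(self, rng):
        m, report, reps = self._quad(rng, fail=("A_r0",))
        out = apply_removals(m, report, reps, min_passing=3)
        assert sorted(c for c in out.column_ids if c.startswith("A")) == [
            "A_r1", "A_r2", "A_r3",
        ]

    def test_absent_manual_removal_warns_not_raises(self, rng, caplog):
        m, report, reps = self._quad(rng)
        out = apply_removals(m, report, reps, manual_removals=[("NOPE", "engineered")])
        assert out.column_ids == m.column_ids

    def test_second_application_is_noop(self, rng):
        m, report, reps = self._quad(rng, fail=("A_r0",))
        once = apply_removals(m, report, reps)
        twice = apply_removals(once, report, reps)
        assert once.column_ids == twice.column_ids


class TestRunQc:
    def test_failed_cell_lines_superset_rule(self, rng):
        cols, reps = {}, {}
        latent = rng.normal(size=100)
        for k in range(4):
            cols[f"A_r{k}"] = latent + rng.normal(scale=0.05, size=100)
            reps[f"A_r{k}"] = "A"
        # line B: mutually uncorrelated replicates, all should fail
        for k in range(4):
            cols[f"B_r{k}"] = rng.normal(size=100)
            reps[f"B_r{k}"] = "B"
        report = run_qc(_matrix(cols), ReplicateMap(reps), threshold=0.6795)
        assert "B" in report.failed_cell_lines
        assert "A" not in report.failed_cell_lines


class TestPcaReport:
    def test_identical_columns_identical_coordinates(self):
        m = make_gct(np.tile(np.arange(6.0)[:, None], (1, 3)))
        out = pca_batch_report(m)
        assert np.allclose(out[["PC1", "PC2"]].to_numpy().std(axis=0), 0)

    def test_planted_clusters_separate_on_pc1(self, rng):
        base = rng.normal(size=(100, 6)) * 0.1
        base[:50, 3:] += 5.0  # half the shRNAs shifted in columns 3-5
        m = make_gct(base)
        out = pca_batch_report(m, {"batch": {c: ("x" if j < 3 else "y")
                                             for j, c in enumerate(m.column_ids)}})
        pc1 = out["PC1"].to_numpy()
        assert (pc1[:3] > 0).all() != (pc1[3:] > 0).all()  # clusters split by sign
        assert set(out["batch"]) == {"x", "y"}

    def test_small_category_still_reported(self, rng):
        m = make_gct(rng.normal(size=(10, 4)))
        out = pca_batch_report(m, {"screener": {m.column_ids[0]: "solo"}})
        assert out.loc[m.column_ids[0], "screener"] == "solo"

    def test_nonfinite_rejected(self, rng):
        v = rng.normal(size=(5, 3))
        v[2, 1] = np.nan
        with pytest.raises(ValueError):
            pca_batch_report(make_gct(v))
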