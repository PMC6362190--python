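import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix, make_hr_matrix
from metasieve.detect import (
    bh_qvalues,
    call_candidates,
    log2_transform,
    one_tailed_p,
    sample_zscores,
    summarize_candidates,
)


class TestLog2Transform:
    @pytest.mark.parametrize("hr,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_values_with_unit_pseudocount(self, hr, expected):
        df = pd.DataFrame({"s": [hr]})
        assert log2_transform(df, 1.0).iloc[0, 0] == pytest.approx(expected)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_transform(pd.DataFrame({"s": [1.0]}), 0.0)

    def test_monotone_in_hr(self):
        df = pd.DataFrame({"s": np.linspace(0, 50, 30)})
        out = log2_transform(df, 1.0)["s"].to_numpy()
        assert (np.diff(out) > 0).all()


class TestSampleZscores:
    def matrix(self, case, controls):
        data = {"case": [case]}
        data.update({f"c{i}": [v] for i, v in enumerate(controls)})
        return pd.DataFrame(data, index=["t"])

    def test_hand_computed_z(self):
        m = self.matrix(8.0, [2.0, 4.0, 6.0])  # mean 4, sample sd 2
        z, testable = sample_zscores(m, "case", ["c0", "c1", "c2"])
        assert z["t"] == pytest.approx(2.0)
        assert bool(testable["t"])

    def test_case_at_control_mean_gives_zero(self):
        m = self.matrix(4.0, [2.0, 4.0, 6.0])
        z, _ = sample_zscores(m, "case", ["c0", "c1", "c2"])
        assert z["t"] == pytest.approx(0.0)

    def test_degenerate_controls_flagged_untestable(self):
        m = self.matrix(9.0, [3.0, 3.0, 3.0])
        z, testable = sample_zscores(m, "case", ["c0", "c1", "c2"])
        assert not bool(testable["t"]) and np.isnan(z["t"])

    def test_too_few_controls_rejected(self):
        m = self.matrix(1.0, [1.0, 2.0])
        with pytest.raises(ValueError, match="3 control"):
            sample_zscores(m, "case", ["c0", "c1"])

    def test_case_among_controls_rejected(self):
        m = self.matrix(1.0, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="case"):
            sample_zscores(m, "case", ["case", "c0", "c1"])


class TestOneTailedP:
    @pytest.mark.parametrize(
        "z,expected,tol",
        [(0.0, 0.5, 1e-12), (2.0, 0.02275, 1e-4), (-3.0, 0.99865, 1e-4)],
    )
    def test_upper_tail_values(self, z, expected, tol):
        assert one_tailed_p(z) == pytest.approx(expected, abs=tol)


def bh_stepup_oracle(p):
    """Brute-force BH: q_i = min over p_(j) >= p_(i) of m * p_(j) / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for k in range(m - 1, -1, -1):
        i = order[k]
        running_min = min(running_min, m * p[i] / (k + 1))
        q[i] = min(running_min, 1.0)
    return q


class TestBHQvalues:
    def test_hand_worked_example(self):
        q = bh_qvalues([0.01, 0.04, 0.03, 0.05])
        assert np.allclose(q, [0.04, 0.05, 0.05, 0.05])

    def test_single_p(self):
        assert bh_qvalues([1.0]) == pytest.approx([1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.1, 1.2])
        with pytest.raises(ValueError):
            bh_qvalues([-0.1])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    def test_matches_stepup_oracle(self, p):
        q = bh_qvalues(p)
        assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)
        # q >= p and sorted q non-decreasing
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_ties_share_a_q(self):
        q = bh_qvalues([0.02, 0.02, 0.5])
        assert q[0] == q[1]


def detection_fixture(seed=0, n_taxa=30):
    """Random HR matrix: 3 case, 6 control samples."""
    rng = np.random.default_rng(seed)
    samples = [f"MS-{i}" for i in range(3)] + [f"C-{i}" for i in range(6)]
    hr = {
        f"t{j}": {s: float(rng.lognormal(0, 1)) for s in samples}
        for j in range(n_taxa)
    }
    groups = {s: ("MS" if s.startswith("MS") else "control") for s in samples}
    runs = {s: 1 for s in samples}
    return make_hr_matrix(hr, groups, runs)


class TestCallCandidates:
    def test_candidate_definition_holds_row_by_row(self):
        table = call_candidates(detection_fixture())
        scored = table.dropna(subset=["q"])
        expected = (scored["q"] < 0.05) & (scored["hr"] > 1.0)
        assert (scored["is_candidate"] == expected).all()

    def test_strict_thresholds(self):
        table = call_candidates(detection_fixture())
        # no row with q exactly at threshold or hr exactly at threshold is a candidate
        at_q = table[table["q"] == 0.05]
        at_hr = table[table["hr"] == 1.0]
        assert not at_q["is_candidate"].any()
        assert not at_hr["is_candidate"].any()

    def test_relaxing_thresholds_never_removes_candidates(self):
        hr = detection_fixture(seed=5)
        strict = call_candidates(hr, q_threshold=0.05, hr_threshold=1.0)
        loose = call_candidates(hr, q_threshold=0.2, hr_threshold=0.5)
        strict_set = set(map(tuple, strict.loc[strict["is_candidate"],
                                               ["sample_id", "taxon_id"]].to_numpy()))
        loose_set = set(map(tuple, loose.loc[loose["is_candidate"],
                                             ["sample_id", "taxon_id"]].to_numpy()))
        assert strict_set <= loose_set

    def test_degenerate_q_threshold_catches_all_testable_high_hr(self):
        hr = detection_fixture(seed=8)
        table = call_candidates(hr, q_threshold=2.0)  # above any possible q
        scored = table.dropna(subset=["q"])
        assert (scored["is_candidate"] == (scored["hr"] > 1.0)).all()

    def test_per_sample_family_adjusts_within_each_sample(self):
        hr = detection_fixture(seed=2)
        table = call_candidates(hr, family="per-sample")
        for _, sub in table.dropna(subset=["q"]).groupby("sample_id"):
            assert np.allclose(
                sub["q"].to_numpy(), bh_stepup_oracle(sub["p"].to_numpy()), atol=1e-12
            )

    def test_pooled_family_adjusts_jointly(self):
        hr = detection_fixture(seed=2)
        table = call_candidates(hr, family="pooled").dropna(subset=["q"])
        assert np.allclose(
            table["q"].to_numpy(), bh_stepup_oracle(table["p"].to_numpy()), atol=1e-12
        )


class TestSummarizeCandidates:
    def fixture(self):
        # hand-built candidate table + counts for two taxa
        table = pd.DataFrame(
            {
                "sample_id": ["MS-1", "MS-2", "MS-3"] * 2,
                "taxon_id": ["tA"] * 3 + ["tB"] * 3,
                "hr": [5.0, 4.0, 0.1, 2.0, 0.2, 0.3],
                "q": [0.01, 0.02, 0.9, 0.04, 0.5, 0.6],
                "is_candidate": [True, True, False, True, False, False],
            }
        )
        counts = {
            "tA": {"MS-1": 60, "MS-2": 50, "MS-3": 0, "C-1": 7, "C-2": 3},
            "tB": {"MS-1": 99, "MS-2": 0, "MS-3": 0, "C-1": 1, "C-2": 0},
        }
        groups = {"MS-1": "MS", "MS-2": "MS", "MS-3": "MS",
                  "C-1": "control", "C-2": "control"}
        runs = {s: 1 for s in groups}
        hq = {s: 10 ** 6 for s in groups}
        return table, make_count_matrix(counts, hq, groups, runs)

    def test_read_filter_boundary(self):
        table, cm = self.fixture()
        out = summarize_candidates(table, cm, read_min=100).set_index("taxon_id")
        assert out.loc["tA", "case_mapped_pairs"] == 110
        assert bool(out.loc["tA", "passes_read_filter"])  # 110 >= 100
        assert out.loc["tB", "case_mapped_pairs"] == 99
        assert not bool(out.loc["tB", "passes_read_filter"])

    def test_control_totals_and_specimens_increased(self):
        table, cm = self.fixture()
        out = summarize_candidates(table, cm, read_min=100).set_index("taxon_id")
        assert out.loc["tA", "control_mapped_pairs"] == 10
        assert out.loc["tA", "n_specimens_increased"] == 2  # q < 0.05 in MS-1, MS-2
        assert out.loc["tB", "n_specimens_increased"] == 1

    def test_specimens_increased_counts_q_hits(self):
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "taxon_id": ["t"] * 8,
                "hr": [2.0] * 8,
                "q": [0.01, 0.2, 0.3, 0.02, 0.9, 0.5, 0.04, 0.7],
                "is_candidate": [True] + [False] * 7,
            }
        )
        counts = {"t": {f"s{i}": 1 for i in range(8)}}
        groups = {f"s{i}": "MS" for i in range(8)}
        cm = make_count_matrix(counts, {f"s{i}": 10 ** 6 for i in range(8)},
                               groups, {f"s{i}": 1 for i in range(8)})
        out = summarize_candidates(table, cm)
        assert out.loc[0, "n_specimens_increased"] == 3  # s0, s3, s6
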