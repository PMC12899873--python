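import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dccn import data_io
from dccn.data_io import (
    IntakeMatrix,
    apply_exclusions,
    cumulative_average,
    read_cohort,
    read_network,
    write_cohort,
    write_network,
    write_scores,
    read_scores,
)
from dccn.errors import DataError
from dccn.network import CoConsumptionNetwork, EdgeCandidate

from conftest import make_cohort, make_intake


class TestExclusions:
    def test_fbg_at_threshold_is_prevalent_diabetes(self):
        cohort = make_cohort(20)
        cohort.iloc[0, cohort.columns.get_loc("fbg_baseline")] = 126.0
        kept, log = apply_exclusions(cohort, make_intake(cohort))
        pid = cohort.index[0]
        assert pid not in kept.index
        assert log.reasons[pid] == "prevalent_diabetes"

    def test_clean_participant_retained(self):
        cohort = make_cohort(20)
        kept, log = apply_exclusions(cohort, make_intake(cohort))
        # median-energy, complete-covariate, FBG-90 rows survive
        assert cohort.index[5] in kept.index

    def test_energy_trim_matches_sort_oracle(self):
        # 1000 distinct energies: exactly the 5 top and 5 bottom removed
        cohort = make_cohort(1000)
        intake = make_intake(cohort)
        rng = np.random.default_rng(7)
        energies = rng.permutation(np.linspace(800, 3200, 1000))
        intake.energy[1] = pd.Series(energies, index=cohort.index)
        kept, log = apply_exclusions(cohort, intake)
        removed = {p for p, r in log.reasons.items() if r == "energy_outlier"}
        order = np.argsort(energies)
        oracle = set(cohort.index[order[:5]]) | set(cohort.index[order[-5:]])
        assert removed == oracle
        assert len(kept) == 990

    def test_reason_order_meds_before_energy(self):
        cohort = make_cohort(200)
        intake = make_intake(cohort)
        intake.energy[1].iloc[0] = 1e9  # also an energy outlier
        cohort.iloc[0, cohort.columns.get_loc("on_antidiabetic_meds")] = True
        _, log = apply_exclusions(cohort, intake)
        assert log.reasons[cohort.index[0]] == "prevalent_diabetes"

    def test_missing_covariate_excluded_last(self):
        cohort = make_cohort(100)
        cohort.iloc[3, cohort.columns.get_loc("bmi")] = np.nan
        kept, log = apply_exclusions(cohort, make_intake(cohort))
        assert log.reasons[cohort.index[3]] == "missing_covariate"

    def test_idempotent_with_recorded_bounds(self):
        cohort = make_cohort(500)
        intake = make_intake(cohort)
        kept1, log1 = apply_exclusions(cohort, intake)
        kept2, log2 = apply_exclusions(kept1, intake,
                                       energy_bounds=log1.energy_bounds)
        assert list(kept2.index) == list(kept1.index)
        assert not log2.reasons

    def test_all_excluded_is_error(self):
        cohort = make_cohort(5)
        cohort["on_antidiabetic_meds"] = True
        with pytest.raises(DataError):
            apply_exclusions(cohort, make_intake(cohort))


class TestCumulativeAverage:
    def _matrix(self, values_by_visit, pid="P0001"):
        idx = pd.Index([pid], name="participant_id")
        frames = {
            v: pd.DataFrame({"rice": [x]}, index=idx)
            for v, x in values_by_visit.items()
        }
        energy = {v: pd.Series([1500.0 + x], index=idx)
                  for v, x in values_by_visit.items()}
        return IntakeMatrix(frames, energy)

    def _cohort(self, dx=None, pid="P0001"):
        c = make_cohort(1)
        c.index = pd.Index([pid], name="participant_id")
        if dx is not None:
            c["incident_t2d"] = True
            c["diagnosis_visit"] = float(dx)
        return c

    @pytest.mark.parametrize(
        "visits,dx,design,expected",
        [
            ({1: 1.0, 2: 2.0, 3: 3.0}, None, "multi_visit", 2.0),
            ({1: 1.0, 2: 2.0}, 1.5, "baseline_plus_one", 1.0),
            ({1: 1.0, 2: 2.0, 3: 4.0}, 3, "multi_visit", 1.5),
            ({1: 1.0, 2: 2.0}, None, "baseline_plus_one", 1.5),
        ],
    )
    def test_averaging_rules(self, visits, dx, design, expected):
        cum = cumulative_average(self._matrix(visits), self._cohort(dx), design)
        assert cum.intake.iloc[0, 0] == pytest.approx(expected)

    def test_value_within_visit_range(self):
        cum = cumulative_average(self._matrix({1: 0.5, 2: 4.0}), self._cohort())
        assert 0.5 <= cum.intake.iloc[0, 0] <= 4.0

    def test_ignores_visits_at_or_after_diagnosis(self):
        # permuting post-diagnosis values cannot change the result
        a = cumulative_average(self._matrix({1: 1.0, 2: 2.0, 3: 99.0}),
                               self._cohort(3))
        b = cumulative_average(self._matrix({1: 1.0, 2: 2.0, 3: -0.0}),
                               self._cohort(3))
        assert a.intake.iloc[0, 0] == b.intake.iloc[0, 0] == 1.5

    def test_no_eligible_visit_is_error(self):
        with pytest.raises(DataError):
            cumulative_average(self._matrix({1: 1.0}), self._cohort(1))

    def test_unknown_design_is_error(self):
        with pytest.raises(DataError):
            cumulative_average(self._matrix({1: 1.0}), self._cohort(), "bootstrap")


class TestRoundTrips:
    def _network(self, n_nodes=45):
        nodes = [f"food{i:02d}" for i in range(n_nodes)]
        edges = [
            EdgeCandidate("food01", "food02", 0.34567890123456, 100, 100),
            EdgeCandidate("food03", "food01", -0.21, 100, 100),
            EdgeCandidate("food05", "food09", 0.4999999999, 100, 100),
        ]
        return CoConsumptionNetwork(nodes, edges, group="diabetic")

    def test_edge_csv_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.csv"
        write_network(net, path)
        g = read_network(path)
        orig = net.to_networkx()
        assert set(g.nodes) == set(orig.nodes)
        assert set(map(frozenset, g.edges)) == set(map(frozenset, orig.edges))
        for a, b, d in orig.edges(data=True):
            assert g.edges[a, b]["weight"] == pytest.approx(d["weight"], rel=1e-12)

    def test_edge_csv_column_contract(self, tmp_path):
        path = tmp_path / "net.csv"
        write_network(self._network(), path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[0] == "food_a,food_b,weight,sign,n_iterations_significant"

    def test_graphml_export_has_all_nodes(self, tmp_path):
        path = tmp_path / "net.graphml"
        write_network(self._network(45), path, fmt="graphml")
        g = nx.read_graphml(path)  # generic reader
        assert g.number_of_nodes() == 45

    def test_scores_round_trip(self, tmp_path):
        idx = pd.Index(["a", "b", "c"], name="participant_id")
        table = pd.DataFrame(
            {"diabetes_score": [1.25, 0.0, 3.111111111111],
             "non_diabetes_score": [0.5, 0.0, 1.0],
             "d_ccn": [0.75, 0.0, 2.111111111111],
             "quartile": ["Q1", "Q2", "Q4"]},
            index=idx,
        )
        path = tmp_path / "scores.csv"
        write_scores(table, path)
        back = read_scores(path)
        pd.testing.assert_frame_equal(back, table)

    def test_cohort_round_trip(self, tmp_path):
        cohort = make_cohort(30)
        intake = make_intake(cohort)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, intake, path)
        cohort2, intake2 = read_cohort(path)
        pd.testing.assert_frame_equal(cohort2, cohort, check_dtype=False)
        pd.testing.assert_frame_equal(intake2.frames[1], intake.frames[1])

    def test_read_cohort_rejects_unknown_column(self, tmp_path):
        cohort = make_cohort(5)
        intake = make_intake(cohort)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, intake, path)
        df = pd.read_csv(path)
        df["mystery"] = 1
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match="mystery"):
            read_cohort(path)

    def test_read_cohort_rejects_negative_intake(self, tmp_path):
        cohort = make_cohort(5)
        intake = make_intake(cohort)
        intake.frames[1].iloc[2, 0] = 1.0
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, intake, path)
        df = pd.read_csv(path)
        df.loc[2, "food_rice"] = -0.5
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match="food_rice"):
            read_cohort(path)

    def test_read_cohort_rejects_duplicate_rows(self, tmp_path):
        cohort = make_cohort(5)
        intake = make_intake(cohort)
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, intake, path)
        df = pd.read_csv(path)
        pd.concat([df, df.iloc[[0]]]).to_csv(path, index=False)
        with pytest.raises(DataError, match="duplicate"):
            read_cohort(path)


def test_intake_matrix_rejects_negative_values():
    idx = pd.Index(["a"], name="participant_id")
    with pytest.raises(DataError, match="negative"):
        IntakeMatrix({1: pd.DataFrame({"rice": [-1.0]}, index=idx)},
                     {1: pd.Series([1500.0], index=idx)})
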