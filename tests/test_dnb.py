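import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tippingnet.dnb import (
    LogRatioMatrix,
    TransitionPoint,
    CISeries,
    DominantGroup,
    compute_ci,
    kmedoids,
    log_ratio_matrix,
    transition_point,
    validate_clinical_order,
)
from tippingnet.io import ClinicalTable
from tippingnet.patient import PatientProfile


def profiles_from(tumor_rows, adjacent_rows, genes):
    out = []
    for i, (t, a) in enumerate(zip(tumor_rows, adjacent_rows)):
        out.append(
            PatientProfile(
                patient_id=f"P{i}",
                tumor_expr=dict(zip(genes, t)),
                adjacent_expr=dict(zip(genes, a)),
            )
        )
    return out


class TestLogRatioMatrix:
    def test_pseudo_count_arithmetic(self):
        profiles = profiles_from(
            [[7.0], [3.0], [0.0]], [[3.0], [3.0], [0.0]], ["G1"]
        )
        matrix = log_ratio_matrix(profiles, {"G1"})
        values = matrix.values.loc["G1"]
        assert values["P0"] == pytest.approx(1.0)  # log2(8/4)
        assert values["P1"] == 0.0  # equal tissues
        assert values["P2"] == 0.0  # both zero

    def test_too_few_patients(self):
        profiles = profiles_from([[1.0]], [[1.0]], ["G1"])
        with pytest.raises(ValueError):
            log_ratio_matrix(profiles, {"G1"})

    def test_unmeasured_gene_is_zero(self):
        profiles = profiles_from([[1.0]] * 3, [[1.0]] * 3, ["G1"])
        matrix = log_ratio_matrix(profiles, {"G1", "G9"})
        assert (matrix.values.loc["G9"] == 0).all()


class TestComputeCI:
    def test_worked_example(self, worked_matrix):
        ci, sd_in, pcc_in, pcc_out, flags = compute_ci(
            worked_matrix, {"G1", "G2"}, {"G3"}
        )
        assert sd_in == pytest.approx(1.93649, abs=1e-5)
        assert pcc_in == pytest.approx(1.0, abs=1e-9)
        assert pcc_out == pytest.approx(0.44721, abs=1e-5)
        assert ci == pytest.approx(8.6603, abs=1e-3)
        assert flags == []

    def test_constant_group_gives_zero(self):
        values = pd.DataFrame(
            [[1.0] * 4, [2.0] * 4, [1.0, 2.0, 3.0, 4.0]],
            index=["G1", "G2", "G3"], columns=list("abcd"),
        )
        ci, sd_in, *_ = compute_ci(LogRatioMatrix(values), {"G1", "G2"}, {"G3"})
        assert sd_in == 0.0 and ci == 0.0

    def test_uncorrelated_background_engages_floor(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0], [5.0] * 4],
            index=["G1", "G2", "G3"], columns=list("abcd"),
        )
        ci, *_, flags = compute_ci(LogRatioMatrix(values), {"G1", "G2"}, {"G3"})
        assert "outer-correlation-floor" in flags
        assert np.isfinite(ci)

    def test_small_group_rejected(self, worked_matrix):
        with pytest.raises(ValueError):
            compute_ci(worked_matrix, {"G1"}, {"G3"})

    def test_empty_background_rejected(self, worked_matrix):
        with pytest.raises(ValueError):
            compute_ci(worked_matrix, {"G1", "G2", "G3"})

    def test_scale_equivariance(self, worked_matrix):
        ci1, sd1, pi1, po1, _ = compute_ci(worked_matrix, {"G1", "G2"}, {"G3"})
        scaled = LogRatioMatrix(worked_matrix.values * 3.0)
        ci3, sd3, pi3, po3, _ = compute_ci(scaled, {"G1", "G2"}, {"G3"})
        assert sd3 == pytest.approx(3 * sd1)
        assert ci3 == pytest.approx(3 * ci1)
        assert pi3 == pytest.approx(pi1) and po3 == pytest.approx(po1)

    def test_patient_permutation_invariance(self, worked_matrix):
        ci1, *_ = compute_ci(worked_matrix, {"G1", "G2"}, {"G3"})
        permuted = LogRatioMatrix(worked_matrix.values[["p3", "p1", "p4", "p2"]])
        ci2, *_ = compute_ci(permuted, {"G1", "G2"}, {"G3"})
        assert ci2 == pytest.approx(ci1)


class TestKMedoids:
    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(5)
        z1, z2 = rng.standard_normal(30), rng.standard_normal(30)
        rows = [z1 + 0.2 * rng.standard_normal(30) for _ in range(6)]
        rows += [z2 + 0.2 * rng.standard_normal(30) for _ in range(6)]
        block = np.array(rows)
        r = np.corrcoef(block)
        dist = 1.0 - np.abs(r)
        np.fill_diagonal(dist, 0.0)
        labels = kmedoids(dist, 2, np.random.default_rng(17))
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_bad_k(self):
        with pytest.raises(ValueError):
            kmedoids(np.zeros((3, 3)), 5, np.random.default_rng(0))


class TestTransitionPoint:
    def _series(self, ci_values):
        groups = [
            DominantGroup(step=i + 1, members={"A", "B"}, ci=c,
                          sd_in=1, pcc_in=1, pcc_out=1)
            for i, c in enumerate(ci_values)
        ]
        return CISeries(
            patient_id="P1",
            driver_sequence=[f"D{i+1}" for i in range(len(ci_values))],
            groups=groups,
        )

    def test_argmax(self):
        tp = transition_point(self._series([1.0, 2.5, 9.1, 3.0]))
        assert tp.step == 3 and tp.driver == "D3"

    def test_earliest_max_on_tie(self):
        assert transition_point(self._series([2.0, 5.0, 5.0])).step == 2

    def test_length_one(self):
        assert transition_point(self._series([0.5])).step == 1

    def test_all_zero_flagged(self):
        tp = transition_point(self._series([0.0, 0.0]))
        assert "no-signal" in tp.flags


class TestClinicalValidation:
    def _results(self, entries):
        """entries: pid -> (transition gene, driver order)."""
        return {
            pid: (
                TransitionPoint(
                    patient_id=pid,
                    step=order.index(gene) + 1,
                    driver=gene,
                    dnb_genes=set(),
                    ci=1.0,
                ),
                order,
            )
            for pid, (gene, order) in entries.items()
        }

    def test_early_gene_before_late_gene_is_consistent(self):
        # early-stage transition gene S precedes late-stage gene E in the
        # late patient's order
        order = ["S", "M", "E"]
        results = self._results({"early": ("S", order), "late": ("E", order)})
        clinical = ClinicalTable(
            stage={"early": "2", "late": "4"},
            subtype={"early": "CMS1", "late": "CMS1"},
        )
        report = validate_clinical_order(results, clinical)
        assert report.consistent == 1 and report.inconsistent == 0
        assert report.fraction_consistent == 1.0

    def test_gene_absent_is_not_evaluable(self):
        results = self._results(
            {"early": ("X", ["X", "Y"]), "late": ("E", ["S", "E"])}
        )
        clinical = ClinicalTable(
            stage={"early": "1", "late": "3"},
            subtype={"early": "CMS2", "late": "CMS2"},
        )
        report = validate_clinical_order(results, clinical)
        assert report.not_evaluable == 1
        assert report.fraction_consistent is None

    def test_inverted_genes_are_inconsistent(self):
        order = ["E", "S"]
        results = self._results({"early": ("S", order), "late": ("E", order)})
        clinical = ClinicalTable(
            stage={"early": "1", "late": "4"},
            subtype={"early": "CMS3", "late": "CMS3"},
        )
        report = validate_clinical_order(results, clinical)
        assert report.inconsistent == 1
        assert report.fraction_consistent == 0.0

    def test_shared_transition_gene_counts_consistent(self):
        order = ["S", "E"]
        results = self._results({"early": ("E", order), "late": ("E", order)})
        clinical = ClinicalTable(
            stage={"early": "2", "late": "4"},
            subtype={"early": "CMS1", "late": "CMS1"},
        )
        report = validate_clinical_order(results, clinical)
        assert report.consistent == 1
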