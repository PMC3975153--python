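"""Reference CSMFs, difference reports, status cross-tabs, broad aggregation."""

import numpy as np
import pandas as pd
import pytest

import intersamm as im
from intersamm.classification import MORBID_NON_SAMM, SAMM, UNCOMPLICATED
from intersamm.evaluation import (
    CauseMapError,
    JoinError,
    MORBID,
    read_references,
)
from intersamm.model_registry import SchemaError


def ref(case_id, status, causes=()):
    return im.ReferenceClassification(case_id, status, tuple(causes))


def est(case_id, status, indeterminate=False):
    return im.CaseClassification(
        case_id=case_id, status=status, assigned_causes=[],
        uncertainty_fraction=0.0, indeterminate=indeterminate,
    )


IDENTITY_AB = im.CauseMap.identity(["A", "B"])


class TestReferenceCSMF:
    def test_two_causes_split_evenly(self):
        s = im.reference_csmf([ref("1", SAMM, ["A", "B"])], IDENTITY_AB,
                              ["A", "B"])
        assert s.csmf == {"A": 0.5, "B": 0.5}

    def test_three_case_hand_fractions(self):
        refs = [
            ref("1", SAMM, ["A"]),
            ref("2", SAMM, ["A", "B"]),
            ref("3", UNCOMPLICATED),
        ]
        s = im.reference_csmf(refs, IDENTITY_AB, ["A", "B"])
        assert s.csmf["A"] == pytest.approx(0.5)
        assert s.csmf["B"] == pytest.approx(1 / 6)
        assert s.uncomplicated_fraction == pytest.approx(1 / 3)
        assert s.uncertainty_fraction == 0.0  # clinician certainty is lost

    def test_other_sink_collects_foreign_causes(self):
        cmap = im.CauseMap({"weird syndrome": "other", "A": "A"})
        s = im.reference_csmf([ref("1", SAMM, ["weird syndrome", "A"])],
                              cmap, ["A"])
        assert s.other_fraction == pytest.approx(0.5)
        assert s.csmf["A"] == pytest.approx(0.5)

    def test_unmapped_label_lists_labels(self):
        with pytest.raises(CauseMapError, match="mystery"):
            im.reference_csmf([ref("1", SAMM, ["mystery"])], IDENTITY_AB,
                              ["A", "B"])

    def test_mass_conservation(self):
        rng = np.random.default_rng(12)
        refs = []
        for i in range(50):
            r = rng.random()
            if r < 0.3:
                refs.append(ref(f"c{i}", UNCOMPLICATED))
            elif r < 0.4:
                refs.append(ref(f"c{i}", MORBID))  # no recorded cause
            else:
                k = int(rng.integers(1, 4))
                refs.append(ref(f"c{i}", SAMM,
                                list(rng.choice(["A", "B", "C"], size=k,
                                                replace=False))))
        s = im.reference_csmf(refs, im.CauseMap.identity(["A", "B", "C"]),
                              ["A", "B", "C"])
        assert s.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_reference_csv_round_trip(self, tmp_path):
        path = tmp_path / "refs.csv"
        path.write_text(
            "case_id,status,causes\n"
            "1,samm,A;B\n"
            "2,uncomplicated,\n"
            "3,morbid,C\n"
        )
        refs = read_references(path)
        assert refs[0].causes == ("A", "B")
        assert refs[1].causes == ()
        assert refs[2].status == MORBID


class TestCompareCSMF:
    def summary(self, csmf):
        return im.PopulationSummary(
            n_cases=10, status_fractions={}, csmf=dict(csmf),
            uncomplicated_fraction=0.0, indeterminate_fraction=0.0,
            uncertainty_fraction=0.0, scope="x",
        )

    def test_identical_summaries_all_zero(self):
        a = self.summary({"A": 0.1, "B": 0.2})
        cmp = im.compare_csmf(a, a)
        assert cmp.mean == cmp.min == cmp.max == 0.0

    def test_single_cause_arithmetic(self):
        cmp = im.compare_csmf(self.summary({"A": 0.10}),
                              self.summary({"A": 0.07}))
        assert cmp.mean == cmp.min == cmp.max == pytest.approx(0.03)

    def test_ten_cause_spreadsheet_oracle(self):
        rng = np.random.default_rng(6)
        a = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0, 0.1, 10))}
        b = {f"c{i}": float(v) for i, v in enumerate(rng.uniform(0, 0.1, 10))}
        cmp = im.compare_csmf(self.summary(a), self.summary(b))
        diffs = np.abs([a[k] - b[k] for k in a])
        assert cmp.mean == pytest.approx(diffs.mean())
        assert cmp.min == pytest.approx(diffs.min())
        assert cmp.max == pytest.approx(diffs.max())

    def test_symmetry(self):
        a = self.summary({"A": 0.1, "B": 0.2})
        b = self.summary({"A": 0.3, "B": 0.05})
        assert im.compare_csmf(a, b).mean == im.compare_csmf(b, a).mean

    def test_registry_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            im.compare_csmf(self.summary({"A": 0.1}), self.summary({"B": 0.1}))


class TestStatusCrosstab:
    def test_perfect_three_level_agreement_is_identity(self):
        ests, refs = [], []
        for i, status in enumerate(
                [UNCOMPLICATED, UNCOMPLICATED, MORBID_NON_SAMM, SAMM]):
            ests.append(est(f"c{i}", status))
            refs.append(ref(f"c{i}", status))
        t = im.status_crosstab(ests, refs, ref_levels=3)
        assert t.loc[UNCOMPLICATED, UNCOMPLICATED] == 100.0
        assert t.loc[MORBID_NON_SAMM, MORBID_NON_SAMM] == 100.0
        assert t.loc[SAMM, SAMM] == 100.0
        assert t.loc[SAMM, UNCOMPLICATED] == 0.0

    def test_all_uncomplicated_estimate_fills_first_row(self):
        ests = [est(f"c{i}", UNCOMPLICATED) for i in range(4)]
        refs = [ref("c0", UNCOMPLICATED), ref("c1", MORBID_NON_SAMM),
                ref("c2", SAMM), ref("c3", SAMM)]
        t = im.status_crosstab(ests, refs, ref_levels=3)
        assert (t.loc[UNCOMPLICATED] == 100.0).all()

    def test_two_level_collapse_and_hand_tally(self):
        ests = [est("1", UNCOMPLICATED), est("2", MORBID_NON_SAMM),
                est("3", SAMM), est("4", SAMM), est("5", UNCOMPLICATED)]
        refs = [ref("1", UNCOMPLICATED), ref("2", MORBID), ref("3", SAMM),
                ref("4", MORBID_NON_SAMM), ref("5", MORBID)]
        t = im.status_crosstab(ests, refs, ref_levels=2)
        # morbid column: cases 2,3,4,5 -> rows non-samm 1, samm 2, unc 1
        assert t.loc[MORBID_NON_SAMM, MORBID] == pytest.approx(25.0)
        assert t.loc[SAMM, MORBID] == pytest.approx(50.0)
        assert t.loc[UNCOMPLICATED, MORBID] == pytest.approx(25.0)

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(44)
        statuses = [UNCOMPLICATED, MORBID_NON_SAMM, SAMM]
        ests = [est(f"c{i}", statuses[rng.integers(3)]) for i in range(30)]
        refs = [ref(f"c{i}", statuses[rng.integers(3)]) for i in range(30)]
        t = im.status_crosstab(ests, refs, ref_levels=3)
        totals = t.sum(axis=0)
        for col in t.columns:
            assert totals[col] == pytest.approx(100.0) or totals[col] == 0.0

    def test_unmatched_ids_error_with_count(self):
        with pytest.raises(JoinError, match="2 case ids"):
            im.status_crosstab([est("1", SAMM), est("2", SAMM)],
                               [ref("1", SAMM), ref("3", SAMM)])


class TestAggregateCauses:
    def summary(self, csmf):
        return im.PopulationSummary(
            n_cases=100, status_fractions={}, csmf=dict(csmf),
            uncomplicated_fraction=0.0, indeterminate_fraction=0.0,
            uncertainty_fraction=0.0, scope="x",
        )

    def test_haemorrhage_merges_aph_and_pph(self, matrix72):
        csmf = {c: 0.0 for c in matrix72.causes.codes}
        csmf["antepartum_haemorrhage"] = 0.002
        csmf["postpartum_haemorrhage"] = 0.043
        broad = im.aggregate_causes(self.summary(csmf), im.DEFAULT_BROAD_SCHEME)
        assert broad.csmf["Haemorrhage"] == pytest.approx(0.045)

    def test_identity_scheme_is_a_no_op(self):
        csmf = {"A": 0.1, "B": 0.2}
        scheme = im.AggregationScheme({"A": "A", "B": "B"})
        out = im.aggregate_causes(self.summary(csmf), scheme)
        assert out.csmf == csmf

    def test_broad_fractions_conserve_substantive_mass(self, matrix72):
        rng = np.random.default_rng(31)
        csmf = {c: float(v) for c, v in
                zip(matrix72.causes.codes, rng.uniform(0, 0.08, 10))}
        broad = im.aggregate_causes(self.summary(csmf), im.DEFAULT_BROAD_SCHEME)
        assert sum(broad.csmf.values()) == pytest.approx(sum(csmf.values()))

    def test_each_cause_maps_to_exactly_one_category(self, matrix72):
        assert set(im.DEFAULT_BROAD_SCHEME.mapping) == set(matrix72.causes.codes)

    def test_uncovered_cause_rejected(self):
        with pytest.raises(SchemaError):
            im.aggregate_causes(self.summary({"unknown_cause": 0.1}),
                                im.DEFAULT_BROAD_SCHEME)
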