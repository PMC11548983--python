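"""Mamdani inference, centroid defuzzification and ranking."""

import numpy as np
import pytest

import fuzzyhaem as fh
from fuzzyhaem.engine import OutputPartition, defuzzify_mean_of_maxima
from fuzzyhaem.errors import InferenceError
from fuzzyhaem.labels import DiseaseLabel, LabParameter
from fuzzyhaem.membership import FuzzifiedValue
from fuzzyhaem.rules import PRESENT, RuleBase


def _fv(param, **degrees):
    return FuzzifiedValue(param, 0.0, degrees)


class TestRuleActivation:
    def test_min_over_clauses(self):
        rule = fh.parse_rule("IF MCV IS LOW AND RDW IS HIGH THEN D3 IS PRESENT")
        fuzz = {
            LabParameter.MCV: _fv(LabParameter.MCV, LOW=0.8),
            LabParameter.RDW: _fv(LabParameter.RDW, HIGH=0.6),
        }
        assert fh.rule_activation(rule, fuzz) == pytest.approx(0.6)

    def test_zero_clause_annihilates(self):
        rule = fh.parse_rule("IF MCV IS LOW AND RDW IS HIGH THEN D3 IS PRESENT")
        fuzz = {
            LabParameter.MCV: _fv(LabParameter.MCV, LOW=0.0),
            LabParameter.RDW: _fv(LabParameter.RDW, HIGH=1.0),
        }
        assert fh.rule_activation(rule, fuzz) == 0.0

    def test_weight_scales_activation(self):
        rule = fh.parse_rule("IF HB IS HIGH THEN D15 IS PRESENT WEIGHT 0.9")
        fuzz = {LabParameter.HB: _fv(LabParameter.HB, HIGH=1.0)}
        assert fh.rule_activation(rule, fuzz) == pytest.approx(0.9)

    def test_unfuzzified_parameter_raises(self):
        rule = fh.parse_rule("IF PCV IS HIGH THEN D16 IS PRESENT")
        with pytest.raises(InferenceError, match="PCV"):
            fh.rule_activation(rule, {})


class TestAggregateActivation:
    def _base(self):
        return fh.parse_rulebase(
            "IF MCV IS LOW THEN D3 IS PRESENT\n"
            "IF RDW IS HIGH THEN D3 IS PRESENT\n"
        )

    def test_max_over_present_rules(self):
        fuzz = {
            LabParameter.MCV: _fv(LabParameter.MCV, LOW=0.3),
            LabParameter.RDW: _fv(LabParameter.RDW, HIGH=0.7),
        }
        present, absent = fh.aggregate_activation(self._base(), fuzz, DiseaseLabel.D3)
        assert present == pytest.approx(0.7)
        assert absent == pytest.approx(0.3)

    def test_full_present_gives_zero_absent(self):
        fuzz = {
            LabParameter.MCV: _fv(LabParameter.MCV, LOW=1.0),
            LabParameter.RDW: _fv(LabParameter.RDW, HIGH=0.2),
        }
        present, absent = fh.aggregate_activation(self._base(), fuzz, DiseaseLabel.D3)
        assert (present, absent) == (1.0, 0.0)

    def test_no_rules_fire_gives_full_absent(self):
        fuzz = {
            LabParameter.MCV: _fv(LabParameter.MCV, LOW=0.0),
            LabParameter.RDW: _fv(LabParameter.RDW, HIGH=0.0),
        }
        present, absent = fh.aggregate_activation(self._base(), fuzz, DiseaseLabel.D3)
        assert (present, absent) == (0.0, 1.0)


class TestDefuzzifyCentroid:
    def test_full_present_hits_ceiling(self):
        # centroid of the symmetric PRESENT triangle (0.68, 0.84, 1.0)
        assert fh.defuzzify_centroid(1.0, 0.0) == pytest.approx(0.84, abs=1e-9)

    def test_balanced_case_is_midpoint(self):
        assert fh.defuzzify_centroid(0.5, 0.5) == pytest.approx(0.50, abs=1e-9)

    def test_full_absent_hits_floor(self):
        assert fh.defuzzify_centroid(0.0, 1.0) == pytest.approx(0.16, abs=1e-9)

    def test_empty_output_set_falls_back_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert fh.defuzzify_centroid(0.0, 0.0) == 0.0
        assert any("empty" in r.message for r in caplog.records)

    def test_agrees_with_riemann_oracle_at_10x_resolution(self):
        """Independent midpoint-Riemann centroid at 10x grid density."""
        out = OutputPartition()

        def oracle(present, absent, cells):
            # membership via interpolation over the breakpoint polylines --
            # a different route than the implementation's piecewise evaluator
            xs = (np.arange(cells) + 0.5) / cells
            tri_a = np.interp(xs, [out.absent.a, out.absent.b, out.absent.d], [0, 1, 0])
            tri_p = np.interp(xs, [out.present.a, out.present.b, out.present.d], [0, 1, 0])
            mu = np.maximum(np.minimum(tri_a, absent), np.minimum(tri_p, present))
            return float((mu * xs).sum() / mu.sum())

        grid = np.linspace(0.05, 1.0, 14)
        for p in grid:
            for a in grid:
                ours = fh.defuzzify_centroid(float(p), float(a), out)
                ref = oracle(float(p), float(a), 10 * (out.grid_points - 1))
                assert ours == pytest.approx(ref, abs=1e-6)

    def test_strictly_increasing_in_present_activation(self):
        ps = np.linspace(0.01, 0.99, 50)
        scores = [fh.defuzzify_centroid(float(p), float(1 - p)) for p in ps]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_mean_of_maxima_closed_forms(self):
        assert defuzzify_mean_of_maxima(1.0, 0.0) == pytest.approx(0.84, abs=1e-3)
        assert defuzzify_mean_of_maxima(0.0, 1.0) == pytest.approx(0.16, abs=1e-3)

    def test_grid_floor_is_enforced(self):
        with pytest.raises(ValueError):
            OutputPartition(grid_points=500)


class TestDiagnoseWorkedCases:
    def test_normal_panel_scores_083(self, config, rulebase, worked_cases):
        record = worked_cases[0].labeled.record  # G2/A5, 89.6/13.6/12.0/39.5
        scores = fh.diagnose(record, config, rulebase)
        assert round(scores[DiseaseLabel.D0], 2) == 0.83

    def test_megaloblastic_panel_hits_ceiling(self, config, rulebase, worked_cases):
        case = next(c for c in worked_cases if c.labeled.record.mcv == 115.8)
        scores = fh.diagnose(case.labeled.record, config, rulebase)
        assert round(scores[DiseaseLabel.D8], 2) == 0.84
        assert round(scores[DiseaseLabel.D9], 2) == 0.84

    def test_all_normal_plateau_centers(self, config, rulebase, adult_female):
        parts = {
            p: config.partition_for(p, adult_female).function("NORMAL")
            for p in LabParameter
        }
        mid = {p: (mf.b + mf.c) / 2 for p, mf in parts.items()}
        record = fh.PatientRecord(
            "mid", fh.Gender.G2, fh.AgeGroup.A5,
            mid[LabParameter.MCV], mid[LabParameter.RDW],
            mid[LabParameter.HB], mid[LabParameter.PCV],
        )
        scores = fh.diagnose(record, config, rulebase)
        assert scores[DiseaseLabel.D0] == pytest.approx(0.84, abs=1e-9)
        for d in DiseaseLabel:
            if d is not DiseaseLabel.D0:
                assert scores[d] == pytest.approx(0.16, abs=1e-9)

    def test_scores_bounded_by_output_centroids(self, config, rulebase, worked_cases):
        for case in worked_cases:
            scores = fh.diagnose(case.labeled.record, config, rulebase)
            for s in scores.scores.values():
                assert 0.16 - 1e-9 <= s <= 0.84 + 1e-9

    def test_determinism_is_bit_identical(self, config, rulebase, worked_cases):
        record = worked_cases[2].labeled.record
        a = fh.diagnose(record, config, rulebase)
        b = fh.diagnose(record, config, rulebase)
        assert a.scores == b.scores


def test_crisp_limit_activates_single_combination(config, rulebase):
    """With zero-width transitions the engine reduces to crisp table lookup."""
    from fuzzyhaem.membership import FuzzyPartition, MembershipFunction

    crisp_partitions = {}
    for key, part in config.partitions.items():
        terms = []
        bands = [part.transition_band(i) for i in range(len(part.terms) - 1)]
        mids = [(lo + hi) / 2 for lo, hi in bands]
        lo_u, hi_u = part.universe
        edges = [lo_u] + mids + [hi_u]
        for i, (lab, _) in enumerate(part.terms):
            a = edges[i]
            d = edges[i + 1]
            terms.append((lab, MembershipFunction(a, a, d, d)))
        crisp_partitions[key] = FuzzyPartition(part.parameter, tuple(terms), part.universe)
    crisp_config = fh.ReferenceConfig(crisp_partitions, version="crisp")

    # microcytic anisocytic anemia panel, away from any crisp boundary
    record = fh.PatientRecord("c", fh.Gender.G2, fh.AgeGroup.A5, 70.0, 18.3, 9.5, 31.8)
    scores = fh.diagnose(record, crisp_config, rulebase)
    active = {d for d, s in scores.items() if s > 0.5}
    assert active == {DiseaseLabel.D3, DiseaseLabel.D4, DiseaseLabel.D5, DiseaseLabel.D17}
    for d in active:
        assert scores[d] == pytest.approx(0.84, abs=1e-9)


class TestRankDiagnoses:
    def _scores(self, **kw):
        base = {d: 0.16 for d in DiseaseLabel}
        base.update({DiseaseLabel(k): v for k, v in kw.items()})
        return fh.DiseaseScoreVector(base)

    def test_ties_break_by_ascending_index(self):
        scores = self._scores(D3=0.84, D4=0.84, D5=0.84, D17=0.84)
        ranked = fh.rank_diagnoses(scores, n=8, threshold=0.25)
        assert ranked.labels() == (
            DiseaseLabel.D3, DiseaseLabel.D4, DiseaseLabel.D5, DiseaseLabel.D17
        )

    def test_top1_is_argmax(self):
        scores = self._scores(D0=0.5, D8=0.7)
        ranked = fh.rank_diagnoses(scores, n=1, threshold=0.0)
        assert ranked.labels() == (DiseaseLabel.D8,)

    def test_all_below_threshold_is_empty(self):
        ranked = fh.rank_diagnoses(self._scores(), n=8, threshold=0.25)
        assert ranked.labels() == ()

    def test_descending_scores(self, config, rulebase, worked_cases):
        for case in worked_cases:
            ranked = fh.rank_diagnoses(fh.diagnose(case.labeled.record, config, rulebase))
            ss = [s for _, s in ranked.entries]
            assert ss == sorted(ss, reverse=True)
            assert len(ranked.entries) <= 8
            assert all(s >= 0.25 for s in ss)
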