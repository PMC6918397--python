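import numpy as np
import pandas as pd
import pytest

from conftest import auc_pair_enumeration

from cannamark.calling import GenotypeMatrix
from cannamark.scoring import (
    ScoreSpec,
    auc,
    consensus_profile,
    evaluate,
    indel_score_spec,
    locus_points,
    optimize_weights,
    sample_score,
    score_samples,
)


def _matrix(columns: dict, labels: list[str], kinds: dict | None = None):
    cells = pd.DataFrame(columns, index=[f"s{i}" for i in range(len(labels))])
    loci = pd.DataFrame(
        [
            (key.split(":")[0], int(key.split(":")[1]), (kinds or {}).get(key, "snp"))
            for key in cells.columns
        ],
        columns=["gene", "position", "kind"],
        index=cells.columns,
    )
    return GenotypeMatrix(cells, pd.Series(labels, index=cells.index), loci)


def _indel_matrix(patterns: list[tuple[bool, bool]], labels: list[str]):
    return _matrix(
        {
            "G:153:del": ["del" if d else "ref" for d, _ in patterns],
            "G:755:ins": ["ins" if i else "ref" for _, i in patterns],
        },
        labels,
        kinds={"G:153:del": "deletion", "G:755:ins": "insertion"},
    )


class TestConsensus:
    def test_clean_separation(self):
        m = _matrix({"G:1:snp": ["T", "T", "C", "C"]}, ["drug", "drug", "fiber", "fiber"])
        prof = consensus_profile(m, ["G:1:snp"])
        assert prof.loc["G:1:snp", "drug_allele"] == "T"
        assert prof.loc["G:1:snp", "fiber_allele"] == "C"

    def test_mode_with_minority_het(self):
        m = _matrix(
            {"G:1:snp": ["T", "T", "R", "C", "C", "C"]},
            ["drug"] * 3 + ["fiber"] * 3,
        )
        prof = consensus_profile(m, ["G:1:snp"])
        assert prof.loc["G:1:snp", "drug_allele"] == "T"

    def test_tie_broken_by_allele_order_with_warning(self):
        m = _matrix(
            {"G:1:snp": ["T", "T", "C", "C", "A", "A"]},
            ["drug"] * 4 + ["fiber"] * 2,
        )
        with pytest.warns(UserWarning, match="tie"):
            prof = consensus_profile(m, ["G:1:snp"])
        assert prof.loc["G:1:snp", "drug_allele"] == "C"  # C before T

    def test_missing_locus_is_error(self):
        m = _matrix({"G:1:snp": ["T", "C"]}, ["drug", "fiber"])
        with pytest.raises(KeyError):
            consensus_profile(m, ["G:9:snp"])


class TestPoints:
    @pytest.mark.parametrize(
        "cell,expected", [("T", 1), ("C", -1), ("R", 0), ("G", 0), ("ref", 0)]
    )
    def test_three_way_rule(self, cell, expected):
        assert locus_points(cell, "T", "C") == expected

    def test_non_discriminating_profile_scores_zero(self):
        assert locus_points("T", "T", "T") == 0


class TestIndelScore:
    def test_published_score_values(self):
        # both indels -> 0.1; neither -> 0; insertion only -> -1; deletion only -> 1.1
        m = _indel_matrix(
            [(True, True), (False, False), (False, True), (True, False)],
            ["drug", "fiber", "fiber", "drug"],
        )
        spec = indel_score_spec(m)
        scores = score_samples(m, spec, pd.DataFrame())
        assert list(np.round(scores, 10)) == [0.1, 0.0, -1.0, 1.1]

    def test_attainable_set_is_exactly_four_values(self):
        m = _indel_matrix(
            [(a, b) for a in (True, False) for b in (True, False)],
            ["drug", "drug", "fiber", "fiber"],
        )
        spec = indel_score_spec(m)
        scores = set(np.round(score_samples(m, spec, pd.DataFrame()), 10))
        assert scores == {-1.0, 0.0, 0.1, 1.1}

    def test_sample_score_missing_cell_warns_and_scores_zero(self):
        m = _matrix({"G:1:snp": ["T", "C"]}, ["drug", "fiber"])
        prof = consensus_profile(m, ["G:1:snp"])
        spec = ScoreSpec(loci=["G:1:snp", "G:9:snp"], weights=[1.0, 1.0])
        row = m.cells.iloc[0]
        with pytest.warns(UserWarning, match="missing genotype"):
            s = sample_score(row, spec, prof, m.loci["kind"])
        assert s == 1.0


class TestAuc:
    def test_perfect_separation(self):
        assert auc([2, 2, 0, 0], ["drug", "drug", "fiber", "fiber"]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([1, 1, 1, 1], ["drug", "drug", "fiber", "fiber"]) == 0.5

    def test_documented_small_case(self):
        # pairs: (2>1)=1, (2>0)=1, (1=1)=0.5, (1>0)=1 -> 3.5/4
        assert auc([2, 1, 1, 0], ["drug", "drug", "fiber", "fiber"]) == 0.875

    def test_one_class_empty_is_error(self):
        with pytest.raises(ValueError):
            auc([1, 2], ["drug", "drug"])

    def test_matches_pair_enumeration_oracle_on_random_panels(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = rng.integers(4, 21)
            labels = np.array(["drug", "fiber"] * n)[:n]
            if len(set(labels)) < 2:
                continue
            scores = rng.integers(-3, 4, n).astype(float)  # integer scores force ties
            assert auc(scores, labels) == pytest.approx(
                auc_pair_enumeration(scores, labels)
            )


class TestOptimize:
    def test_single_perfect_snp_reaches_auc_one(self):
        m = _matrix({"G:1:snp": ["T", "T", "C", "C"]}, ["drug", "drug", "fiber", "fiber"])
        prof = consensus_profile(m, ["G:1:snp"])
        spec = optimize_weights(m, prof, k=1)
        assert spec.auc == 1.0 and spec.weights[0] > 0

    def test_uninformative_loci_stay_near_chance(self):
        rng = np.random.default_rng(4)
        labels = ["drug"] * 20 + ["fiber"] * 20
        cols = {
            f"G:{i}:snp": list(rng.choice(["T", "C"], size=40)) for i in range(1, 5)
        }
        m = _matrix(cols, labels)
        prof = consensus_profile(m, list(cols))
        spec = optimize_weights(m, prof, k=2)
        # greedy optimization overfits a little on 40 samples but cannot
        # manufacture real signal
        assert spec.auc < 0.85

    def test_two_indel_loci_admit_one_negative_weight(self, default_panel):
        m = default_panel.matrix
        indel_keys = [
            k for k in m.cells.columns
            if m.loci.loc[k, "kind"] in ("deletion", "insertion")
        ]
        m2 = m.subset_loci(indel_keys)
        prof = pd.DataFrame(columns=["drug_allele", "fiber_allele"])
        spec = optimize_weights(m2, prof, k=2)
        assert sum(1 for w in spec.weights if w < 0) <= 1
        single = optimize_weights(m2, prof, k=1)
        assert spec.auc >= single.auc

    def test_auc_never_decreases_as_k_grows(self, default_panel, default_scan):
        m = default_panel.matrix
        sig = default_scan[default_scan["significant"]]
        snp_keys = [k for k in sig.index if sig.loc[k, "kind"] == "snp"]
        prof = consensus_profile(m, snp_keys)
        aucs = [optimize_weights(m, prof, k=k).auc for k in (1, 2, 3)]
        assert aucs == sorted(aucs)
        assert aucs[0] == 1.0  # a single planted marker already separates

    def test_k_beyond_candidates_is_error(self):
        m = _matrix({"G:1:snp": ["T", "C"]}, ["drug", "fiber"])
        prof = consensus_profile(m, ["G:1:snp"])
        with pytest.raises(ValueError):
            optimize_weights(m, prof, k=5)


class TestEvaluate:
    def test_indel_score_on_default_panel_has_full_sensitivity(self, default_panel):
        m = default_panel.matrix
        spec = indel_score_spec(m)
        result = evaluate(spec, m, pd.DataFrame(), B=200, seed=11)
        assert result.sensitivity == 1.0
        assert result.auc == 1.0

    def test_all_ref_fiber_panel_has_full_specificity(self):
        m = _indel_matrix(
            [(True, True), (True, True), (False, False), (False, False)],
            ["drug", "drug", "fiber", "fiber"],
        )
        result = evaluate(indel_score_spec(m), m, pd.DataFrame(), B=100, seed=1)
        assert result.specificity == 1.0

    def test_degenerate_ci_when_metric_constant(self):
        m = _indel_matrix(
            [(True, True)] * 3 + [(False, False)] * 3,
            ["drug"] * 3 + ["fiber"] * 3,
        )
        result = evaluate(indel_score_spec(m), m, pd.DataFrame(), B=100, seed=1)
        for low, high in result.ci.values():
            assert low == high == 1.0

    def test_cis_contain_point_estimates(self, default_panel):
        m = default_panel.matrix
        result = evaluate(indel_score_spec(m), m, pd.DataFrame(), B=200, seed=2)
        for name, point in (
            ("auc", result.auc),
            ("sensitivity", result.sensitivity),
            ("specificity", result.specificity),
        ):
            low, high = result.ci[name]
            assert low <= point <= high

    def test_invalid_bootstrap_count(self, default_panel):
        m = default_panel.matrix
        with pytest.raises(ValueError):
            evaluate(indel_score_spec(m), m, pd.DataFrame(), B=0, seed=1)


def test_score_spec_json_round_trip(tmp_path):
    spec = ScoreSpec(loci=["G:1:snp"], weights=[1.1], threshold=0.0, auc=1.0)
    path = tmp_path / "spec.json"
    spec.to_json(path)
    back = ScoreSpec.from_json(path)
    assert back == spec
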