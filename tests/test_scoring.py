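import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import phyloscreen as ps
from phyloscreen.errors import InsufficientDataError, NormalizationError
from phyloscreen.scoring import ActivityScorer, ThresholdSpec

from _oracles import brute_category_thresholds, brute_calls, brute_cells


def _records(responses, category="CYTOTOX", assay="C1"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(responses))],
            "phylum": "Porifera",
            "genus": "Porifera_g1",
            "bioregion": "1",
            "category": category,
            "assay_id": assay,
            "response": responses,
        }
    )


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, control, expected",
        [(50, 100, 50.0), (100, 100, 100.0), (30, 60, 50.0), (0, 10, 0.0)],
    )
    def test_percent_of_control(self, raw, control, expected):
        assert ps.normalize_to_control(raw, control) == expected

    @pytest.mark.parametrize("control", [0.0, -5.0])
    def test_nonpositive_control_rejected(self, control):
        with pytest.raises(NormalizationError):
            ps.normalize_to_control(50.0, control)

    def test_vectorized_with_offender_position(self):
        with pytest.raises(NormalizationError, match=r"\[2\]"):
            ps.normalize_to_control([1.0, 2.0, 3.0], [10.0, 10.0, 0.0])


class TestComputeThreshold:
    def test_worked_example(self):
        """[100, 100, 100, 60] -> mean 90, sample SD 20, threshold 70."""
        spec = ps.compute_threshold(_records([100.0, 100.0, 100.0, 60.0]), "CYTOTOX")
        assert spec.mean == pytest.approx(90.0)
        assert spec.sd == pytest.approx(20.0)
        assert spec.threshold == pytest.approx(70.0)
        assert spec.n_values == 4

    def test_zero_variance_warns_threshold_equals_mean(self):
        with pytest.warns(UserWarning, match="zero response variance"):
            spec = ps.compute_threshold(_records([100.0, 100.0]), "CYTOTOX")
        assert spec.threshold == spec.mean == 100.0

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ps.compute_threshold(_records([100.0]), "CYTOTOX")
        with pytest.raises(InsufficientDataError):
            ps.compute_threshold(_records([]), "CYTOTOX")

    def test_per_assay_pooling_returns_one_spec_per_assay(self, random_records):
        specs = ps.compute_threshold(random_records, "CYTOTOX", "per_assay")
        assert set(specs) == {"C1", "C2", "C3"}
        for assay, spec in specs.items():
            vals = random_records.query(
                "category == 'CYTOTOX' and assay_id == @assay"
            )["response"]
            assert spec.mean == pytest.approx(vals.mean())
            assert spec.sd == pytest.approx(vals.std(ddof=1))


class TestCallActivity:
    def test_inclusive_at_equality(self):
        records = _records([70.0, 95.0])
        thr = ThresholdSpec("CYTOTOX", None, 90.0, 20.0, 70.0, 4, "pooled")
        calls = ps.call_activity(records, thr)
        active = dict(zip(calls.sample_id, calls.active))
        assert active == {"s0": True, "s1": False}

    @pytest.mark.parametrize(
        "rule, expected",
        [("any", True), ("all", False), ("mean", False)],
    )
    def test_repeated_measure_rules(self, rule, expected):
        # one sample, assay responses {65, 95}, threshold 70
        records = pd.DataFrame(
            {
                "sample_id": "s0",
                "phylum": "Porifera",
                "genus": "Porifera_g1",
                "bioregion": "1",
                "category": "CYTOTOX",
                "assay_id": ["C1", "C2"],
                "response": [65.0, 95.0],
            }
        )
        thr = ThresholdSpec("CYTOTOX", None, 90.0, 20.0, 70.0, 4, "pooled")
        calls = ps.call_activity(records, thr, rule=rule)
        assert bool(calls.active.iloc[0]) is expected

    def test_missing_threshold_is_loud(self):
        records = _records([50.0], category="CNS")
        thr = ThresholdSpec("CYTOTOX", None, 90.0, 20.0, 70.0, 4, "pooled")
        with pytest.raises(KeyError, match="CNS"):
            ps.call_activity(records, thr)

    def test_partial_samples_counted(self):
        records = pd.DataFrame(
            {
                "sample_id": ["s0", "s0", "s1"],
                "phylum": "Porifera",
                "genus": "g",
                "bioregion": "1",
                "category": "CYTOTOX",
                "assay_id": ["C1", "C2", "C1"],  # s1 misses C2
                "response": [65.0, 95.0, 80.0],
            }
        )
        thr = ThresholdSpec("CYTOTOX", None, 90.0, 20.0, 70.0, 4, "pooled")
        calls = ps.call_activity(records, thr)
        assert calls.attrs["n_partial_samples"] == 1


class TestSummarizeCells:
    def test_simple_percentage(self):
        records = _records([60.0, 95.0, 96.0, 97.0])
        thr = ThresholdSpec("CYTOTOX", None, 90.0, 20.0, 70.0, 4, "pooled")
        cells = ps.summarize_cells(ps.call_activity(records, thr))
        assert len(cells) == 1
        row = cells.iloc[0]
        assert (row.n_tested, row.n_active, row.pct_active) == (4, 1, 25.0)

    def test_conservation_totals(self, random_records):
        calls = ps.call_activity(
            random_records, ps.compute_thresholds(random_records)
        )
        cells = ps.summarize_cells(calls, "phylum")
        assert cells.n_active.sum() == calls.active.sum()
        assert cells.n_tested.sum() == len(
            random_records[["sample_id", "category"]].drop_duplicates()
        )
        assert ((cells.n_active >= 0) & (cells.n_active <= cells.n_tested)).all()
        assert cells.n_tested.gt(0).all()  # empty cells are absent, not zero


@pytest.mark.parametrize("pooling", ["pooled", "per_assay"])
@pytest.mark.parametrize("rule", ["any", "all", "mean"])
def test_scoring_matches_brute_force_oracle(random_records, pooling, rule):
    """Thresholds, per-assay flags, calls and cell tallies all agree
    exactly with an independent per-record brute-force implementation."""
    recs = random_records.to_dict("records")
    oracle_thr = brute_category_thresholds(recs, pooling)
    oracle_calls = brute_calls(recs, oracle_thr, rule, pooling)

    thresholds = ps.compute_thresholds(random_records, pooling)
    for row in thresholds.itertuples(index=False):
        key = row.category if pooling == "pooled" else (row.category, row.assay_id)
        mean, sd, thr = oracle_thr[key]
        assert row.mean == pytest.approx(mean, rel=1e-12)
        assert row.sd == pytest.approx(sd, rel=1e-12)
        assert row.threshold == pytest.approx(thr, rel=1e-12)

    calls, flags = ps.call_activity(
        random_records, thresholds, rule, return_flags=True
    )
    for row in calls.itertuples(index=False):
        assert row.active == oracle_calls[(row.sample_id, row.category)]["active"]
    for row in flags.itertuples(index=False):
        oc = oracle_calls[(row.sample_id, row.category)]
        assert row.assay_active == oc["per_assay"][row.assay_id]

    for level in ("phylum", "genus"):
        cells = ps.summarize_cells(calls, level)
        oracle = brute_cells(oracle_calls, level)
        assert len(cells) == len(oracle)
        for row in cells.itertuples(index=False):
            n, k, pct = oracle[(row.taxon, row.bioregion, row.category)]
            assert (row.n_tested, row.n_active) == (n, k)
            assert row.pct_active == pytest.approx(pct, rel=1e-12)


class TestInvariants:
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance_of_calls(self, scale, random_records):
        """Multiplying raw and control by a common factor leaves every
        call unchanged (percent-of-control is dimensionless)."""
        raw = random_records["response"].to_numpy() * 2.0  # pretend controls = 200
        base = random_records.assign(
            response=ps.normalize_to_control(raw, np.full(len(raw), 200.0))
        )
        scaled = random_records.assign(
            response=ps.normalize_to_control(
                raw * scale, np.full(len(raw), 200.0 * scale)
            )
        )
        calls_a = ps.call_activity(base, ps.compute_thresholds(base))
        calls_b = ps.call_activity(scaled, ps.compute_thresholds(scaled))
        assert (calls_a.active == calls_b.active).all()

    def test_monotone_fixed_thresholds(self, random_records):
        """With thresholds held fixed, lowering responses can only make
        samples more active."""
        thr = ps.compute_thresholds(random_records)
        before = ps.call_activity(random_records, thr)
        lowered = random_records.assign(
            response=random_records["response"] * 0.7
        )
        after = ps.call_activity(lowered, thr)
        merged = before.merge(
            after, on=["sample_id", "category"], suffixes=("_pre", "_post")
        )
        assert not (merged.active_pre & ~merged.active_post).any()

    def test_monotone_recomputed_thresholds_for_perturbed_sample(self):
        """Recomputing thresholds after lowering one response never flips
        that sample inactive: x - mean(x) + sd(x) is increasing in x."""
        rng = np.random.default_rng(7)
        values = np.round(rng.normal(95, 15, 40), 2)
        for idx in (0, 5, 17):
            base = _records(list(values))
            calls0 = ps.call_activity(base, ps.compute_thresholds(base))
            was_active = bool(
                calls0.set_index("sample_id").loc[f"s{idx}", "active"]
            )
            perturbed = values.copy()
            perturbed[idx] -= 30.0
            df = _records(list(perturbed))
            calls1 = ps.call_activity(df, ps.compute_thresholds(df))
            now_active = bool(
                calls1.set_index("sample_id").loc[f"s{idx}", "active"]
            )
            assert not (was_active and not now_active)

    def test_gaussian_tail_fraction_matches_threshold_rule(self):
        """Mean - 1 SD cuts off ~15.9% of a Gaussian response sample."""
        rng = np.random.default_rng(123)
        n = 200_000
        responses = rng.normal(100.0, 12.0, n)
        df = _records(list(responses))
        spec = ps.compute_threshold(df, "CYTOTOX")
        frac = float((responses <= spec.threshold).mean())
        expected = norm.cdf(-1.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestActivityScorer:
    def test_fit_transform_matches_functions(self, random_records):
        scorer = ActivityScorer()
        calls_est = scorer.fit_transform(random_records)
        calls_fn = ps.call_activity(
            random_records, ps.compute_thresholds(random_records)
        )
        pd.testing.assert_frame_equal(calls_est, calls_fn)

    def test_transform_requires_fit(self, random_records):
        with pytest.raises(RuntimeError, match="fitted"):
            ActivityScorer().transform(random_records)

    def test_get_set_params_round_trip(self):
        scorer = ActivityScorer(pooling="per_assay", rule="all")
        params = scorer.get_params()
        assert params == {"pooling": "per_assay", "rule": "all"}
        scorer.set_params(rule="mean")
        assert scorer.rule == "mean"
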