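import warnings

import numpy as np
import pandas as pd
import pytest

from addr.cohort import (
    CohortConfig,
    CohortTable,
    CoxResult,
    TrialOverlap,
    chronic_exposure,
    fit_cox,
    flag_significance,
    generate_synthetic_cohort,
    load_cohort,
    load_trials,
    tabulate_trials,
)
from addr.evidence import aggregate_rates, Judgment
from addr.pool import CandidatePool


def visits_table(patterns):
    """patterns: {participant: [drug-string per visit]}"""
    rows = []
    for pid, drugs_per_visit in patterns.items():
        for k, drugs in enumerate(drugs_per_visit):
            rows.append(
                {
                    "participant": pid,
                    "visit_age": 70.0 + k,
                    "drugs": drugs,
                    "declined": False,
                }
            )
    return pd.DataFrame(rows)


def participants_table(pids):
    return pd.DataFrame(
        {
            "participant": pids,
            "entry_age": 70.0,
            "exit_age": 75.0,
            "event": False,
            "age": 70.0,
            "sex": "female",
            "education": 16.0,
            "marital": "married",
            "living": "alone",
        }
    )


class TestChronicExposure:
    def test_nonconsecutive_mentions_not_exposed(self):
        cohort = CohortTable(
            participants=participants_table(["p1"]),
            visits=visits_table({"p1": ["dx", "", "dx"]}),
        )
        assert not chronic_exposure(cohort, "dx").loc["p1"]

    def test_consecutive_mentions_exposed(self):
        cohort = CohortTable(
            participants=participants_table(["p1"]),
            visits=visits_table({"p1": ["", "dx", "dx"]}),
        )
        assert chronic_exposure(cohort, "dx").loc["p1"]

    def test_matches_consecutive_pair_scan(self, rng):
        pids = [f"p{i}" for i in range(30)]
        patterns = {
            pid: [("dx" if rng.random() < 0.4 else "") for _ in range(5)]
            for pid in pids
        }
        cohort = CohortTable(
            participants=participants_table(pids),
            visits=visits_table(patterns),
        )
        flags = chronic_exposure(cohort, "dx")
        for pid in pids:
            present = [d == "dx" for d in patterns[pid]]
            want = any(a and b for a, b in zip(present, present[1:]))
            assert flags.loc[pid] == want


class TestGenerator:
    def test_deterministic(self):
        cfg = CohortConfig(n_participants=50, drug_effects={"dx": -0.3}, seed=9)
        a = generate_synthetic_cohort(cfg)
        b = generate_synthetic_cohort(cfg)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_full_censoring_yields_no_events_and_na_fit(self):
        cfg = CohortConfig(
            n_participants=80, drug_effects={"dx": 0.0}, censoring_rate=1.0, seed=2
        )
        with pytest.warns(UserWarning, match="no events"):
            cohort = generate_synthetic_cohort(cfg)
        assert cohort.n_events == 0
        assert fit_cox(cohort, "dx").status == "not-estimable"

    def test_entry_never_after_exit_and_two_visits_minimum(self):
        cfg = CohortConfig(n_participants=100, drug_effects={"dx": 0.0}, seed=4)
        cohort = generate_synthetic_cohort(cfg)
        p = cohort.participants
        assert (p["entry_age"] <= p["exit_age"]).all()
        counts = cohort.visits.groupby("participant").size()
        assert (counts >= 2).all()

    def test_round_trip(self, tmp_path):
        cfg = CohortConfig(n_participants=30, drug_effects={"dx": 0.0}, seed=5)
        cohort = generate_synthetic_cohort(cfg)
        cohort.write(tmp_path / "cohort.tsv")
        again = load_cohort(tmp_path / "cohort.tsv")
        assert again.n_participants == cohort.n_participants
        assert again.n_events == cohort.n_events
        assert chronic_exposure(again, "dx").equals(chronic_exposure(cohort, "dx"))


class TestFitCox:
    def test_absent_drug_not_estimable_rendered_na(self):
        cfg = CohortConfig(n_participants=60, drug_effects={"dx": 0.0}, seed=1)
        cohort = generate_synthetic_cohort(cfg)
        res = fit_cox(cohort, "never_prescribed")
        assert res.status == "not-estimable"
        assert res.reason == "drug-absent"
        assert res.render_hr() == "NA"

    def test_protective_effect_recovered_in_sign(self):
        cfg = CohortConfig(n_participants=2000, drug_effects={"dx": -0.5}, seed=3)
        cohort = generate_synthetic_cohort(cfg)
        res = fit_cox(cohort, "dx")
        assert res.status == "ok"
        assert res.hazard_ratio < 1.0
        assert res.p_value < 0.05

    def test_agrees_with_independent_phreg_oracle(self):
        import statsmodels.api as sm

        cfg = CohortConfig(n_participants=800, drug_effects={"dx": -0.4}, seed=8)
        cohort = generate_synthetic_cohort(cfg)
        res = fit_cox(cohort, "dx", covariates=("age", "sex"))
        p = cohort.participants
        exposed = chronic_exposure(cohort, "dx").loc[p["participant"]].to_numpy()
        exog = pd.DataFrame(
            {
                "exposed": exposed.astype(float),
                "age_c": p["age"].to_numpy() - 70.0,
                "sex_female": (p["sex"] == "female").astype(float).to_numpy(),
            }
        )
        model = sm.PHReg(
            p["exit_age"].to_numpy(),
            exog,
            status=p["event"].astype(int).to_numpy(),
            entry=p["entry_age"].to_numpy(),
            ties="efron",
        )
        fit = model.fit()
        assert res.beta == pytest.approx(fit.params[0], abs=1e-3)

    def test_truncation_uses_only_entry_exit_event(self):
        # shifting visit ages (exposure pattern intact) leaves the fit alone
        cfg = CohortConfig(n_participants=400, drug_effects={"dx": -0.3}, seed=6)
        cohort = generate_synthetic_cohort(cfg)
        res1 = fit_cox(cohort, "dx")
        shifted = CohortTable(
            participants=cohort.participants.copy(),
            visits=cohort.visits.assign(visit_age=cohort.visits["visit_age"] - 0.1),
        )
        res2 = fit_cox(shifted, "dx")
        assert res1.beta == pytest.approx(res2.beta, abs=1e-12)

    def test_ok_result_requires_positive_hr(self):
        with pytest.raises(ValueError):
            CoxResult("d", "ok", beta=0.0, hazard_ratio=-1.0, p_value=0.5)


class TestSignificanceFlags:
    @pytest.mark.parametrize(
        "p,want",
        [(0.27, (False, True)), (0.0001, (True, True)), (0.95, (False, False))],
    )
    def test_dual_thresholds(self, p, want):
        res = CoxResult("d", "ok", beta=0.0, hazard_ratio=1.0, p_value=p)
        assert flag_significance(res) == want

    def test_requires_ok_status(self):
        with pytest.raises(ValueError):
            flag_significance(CoxResult("d", "not-estimable"))


class TestTrialOverlap:
    def test_count_defaults_to_ids(self):
        o = TrialOverlap("d", ("NCT1", "NCT2"))
        assert o.trial_count == 2

    def test_count_may_exceed_listed_ids_but_not_undercut(self):
        assert TrialOverlap("d", ("NCT1",), trial_count=97).trial_count == 97
        with pytest.raises(ValueError):
            TrialOverlap("d", ("NCT1", "NCT2"), trial_count=1)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "trials.tsv"
        path.write_text(
            "drug_id\ttrial_count\ttrial_ids\n"
            "a\t2\tNCT1;NCT2\n"
            "b\t0\t\n"
        )
        overlaps = load_trials(path)
        assert overlaps[0].trial_ids == ("NCT1", "NCT2")
        assert overlaps[1].trial_count == 0


class TestTabulateTrials:
    def _profiles(self, spec):
        return [
            aggregate_rates(d, [Judgment(1)] * p + [Judgment(0)] * u + [Judgment(-1)] * n)
            for d, (p, u, n) in spec.items()
        ]

    def test_all_zero_trials_recovers_nothing(self):
        pool = CandidatePool(members={"a": {"m": 1}, "b": {"m": 2}})
        overlaps = [TrialOverlap("a", ()), TrialOverlap("b", ())]
        profiles = self._profiles({"a": (3, 1, 0), "b": (0, 5, 0)})
        tab = tabulate_trials(pool, overlaps, profiles)
        assert tab == {
            "trial_tested": 0,
            "criterion1_recovered": 0,
            "criterion2_recovered": 0,
        }

    def test_matches_filter_and_count_oracle(self, rng):
        from addr.evidence import (
            POTENTIALLY_THERAPEUTIC,
            apply_criterion1,
            apply_criterion2,
        )

        drugs = [f"d{i}" for i in range(20)]
        pool = CandidatePool(members={d: {"m": 1} for d in drugs})
        spec = {
            d: (int(rng.integers(0, 3)), int(rng.integers(0, 5)), int(rng.integers(0, 3)))
            for d in drugs
        }
        profiles = self._profiles(spec)
        counts = {d: int(rng.integers(0, 3)) for d in drugs}
        overlaps = [
            TrialOverlap(d, tuple(f"NCT{i}" for i in range(c))) for d, c in counts.items()
        ]
        tab = tabulate_trials(pool, overlaps, profiles)
        prof_by = {p.drug_id: p for p in profiles}
        tested = [d for d in drugs if counts[d] >= 1]
        want_c1 = sum(
            1
            for d in tested
            if apply_criterion1(prof_by[d]) == POTENTIALLY_THERAPEUTIC
        )
        want_c2 = sum(
            1
            for d in tested
            if apply_criterion2(prof_by[d]) == POTENTIALLY_THERAPEUTIC
        )
        assert tab["trial_tested"] == len(tested)
        assert tab["criterion1_recovered"] == want_c1
        assert tab["criterion2_recovered"] == want_c2
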