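import numpy as np
import pytest
from dataclasses import replace

from meganorm import (SyntheticCohortSpec, dichotomize_scores, generate_cohort,
                      read_cohort, run_pipeline, write_cohort)
from meganorm.synthetic import (CohortIOError, CohortSpecError, SubjectRecord,
                                SymptomDef, null_spec)


def _recordings(cohort):
    for s in cohort:
        yield from s.recordings


def test_generation_is_deterministic(table):
    spec = replace(null_spec(seed=9), n_subjects_norm=6, n_subjects_clin=4,
                   total_count_mean=20_000.0)
    a = generate_cohort(spec, table)
    b = generate_cohort(spec, table)
    for sa, sb in zip(a, b):
        assert sa.subject_id == sb.subject_id
        assert sa.symptom_scores == sb.symptom_scores
        assert sa.age == sb.age
        for ra, rb in zip(sa.recordings, sb.recordings):
            assert ra.counts == rb.counts


def test_count_total_sums_partition_regions(table, small_null_cohort):
    _, cohort = small_null_cohort
    part = set(table.partition_ids)
    for rec in _recordings(cohort):
        assert rec.count_total == sum(
            c for r, c in rec.counts.items() if r in part)
        assert all(c >= 0 for c in rec.counts.values())


def test_every_subject_has_baseline_rest_and_empty_room(small_null_cohort):
    _, cohort = small_null_cohort
    for s in cohort:
        assert s.recording("baseline", "rest") is not None
        assert s.recording("baseline", "empty_room") is not None


def test_no_dark_counts_means_silent_empty_room(table):
    spec = replace(null_spec(seed=1), n_subjects_norm=4, n_subjects_clin=0,
                   session_quality_sd=0.0, total_count_mean=10_000.0)
    assert spec.dark_fraction == 0.0
    for s in generate_cohort(spec, table):
        for rec in s.recordings:
            if rec.condition == "empty_room":
                assert rec.count_total == 0
                assert all(c == 0 for c in rec.counts.values())


def test_followup_fraction_controls_retest_subset(table):
    spec = replace(null_spec(seed=2), n_subjects_norm=10, n_subjects_clin=0,
                   followup_fraction=0.5, total_count_mean=10_000.0)
    cohort = generate_cohort(spec, table)
    n_follow = sum(s.recording("followup", "rest") is not None for s in cohort)
    assert n_follow == 5


def test_invalid_spec_rejected():
    with pytest.raises(CohortSpecError):
        SyntheticCohortSpec(dark_fraction=1.0).validate()
    with pytest.raises(CohortSpecError):
        SyntheticCohortSpec(retest_rho=1.5).validate()
    with pytest.raises(CohortSpecError):
        SyntheticCohortSpec(cohort_effect={"L_thalamus": 0.0}).validate()
    with pytest.raises(CohortSpecError):
        SyntheticCohortSpec(symptom_defs=[
            SymptomDef("x", 1.2, {}, 10)]).validate()


@pytest.mark.parametrize("score,cutoff,expected", [
    (15, 15, "positive"),  # boundary: score >= cutoff screens positive
    (62, 63, "negative"),
    (70, 63, "positive"),
])
def test_dichotomize_boundary_convention(score, cutoff, expected):
    subj = SubjectRecord("s", "clin", 30.0, {"sym": score}, [])
    assert dichotomize_scores(subj, {"sym": cutoff}) == {"sym": expected}


def test_dichotomize_missing_score_is_explicit():
    subj = SubjectRecord("s", "clin", 30.0, {"insomnia": 20}, [])
    out = dichotomize_scores(subj, {"insomnia": 15, "depression": 63})
    assert out == {"insomnia": "positive", "depression": "missing"}


def test_survey_prevalence_matches_spec(table):
    spec = replace(null_spec(seed=3), n_subjects_norm=0, n_subjects_clin=600,
                   total_count_mean=5_000.0)
    cohort = generate_cohort(spec, table)
    for sym in spec.symptom_defs:
        pos = np.mean([dichotomize_scores(s, {sym.name: sym.cutoff})[sym.name]
                       == "positive" for s in cohort])
        # binomial s.e. ~ 0.02 at n=600
        assert abs(pos - sym.prevalence) < 0.07


def test_planted_symptom_effect_is_detectable(table):
    """Effect 1.5 on L_thalamus for one symptom separates the screened
    groups' z-scores at p < 0.01 (two-sample t on the affected region)."""
    from scipy import stats
    spec = replace(
        null_spec(seed=4), n_subjects_norm=200, n_subjects_clin=200,
        followup_fraction=0.0,
        symptom_defs=[SymptomDef("insomnia", 0.5,
                                 {"L_thalamus": 1.5}, cutoff=15)])
    cohort = generate_cohort(spec, table)
    res = run_pipeline(cohort, table)
    z = []
    status = []
    for s in cohort:
        if s.cohort != "clin":
            continue
        z.append(res.zscores[(s.subject_id, "baseline", "rest")].z["L_thalamus"])
        status.append(dichotomize_scores(s, {"insomnia": 15})["insomnia"])
    z = np.array(z)
    status = np.array(status)
    t, p = stats.ttest_ind(z[status == "positive"], z[status == "negative"])
    assert p < 0.01
    assert t > 0


def test_null_cohorts_are_exchangeable(table):
    """Under the all-effects-1 spec, relabelling subjects does not shift the
    per-region between-cohort separation: the observed max |t| over regions
    is a typical draw from the permutation distribution."""
    from scipy import stats
    spec = replace(null_spec(seed=6), n_subjects_norm=30, n_subjects_clin=30,
                   followup_fraction=0.0, total_count_mean=60_000.0)
    cohort = generate_cohort(spec, table)
    res = run_pipeline(cohort, table)
    ids = table.ids_of_class("cortical", "subcortical")
    X, sids = res.z_matrix(ids)
    y = np.array([res.cohort_of[s] for s in sids]) == "clin"

    def max_abs_t(labels):
        a, b = X[labels], X[~labels]
        t = stats.ttest_ind(a, b).statistic
        return np.abs(t).max()

    observed = max_abs_t(y)
    rng = np.random.default_rng(0)
    perm = np.array([max_abs_t(rng.permutation(y)) for _ in range(60)])
    rank = (perm >= observed).mean()
    assert 0.02 < rank  # observed statistic is not an outlier vs permutations


def test_cohort_round_trip(table, tmp_path, small_null_cohort):
    _, cohort = small_null_cohort
    sub = cohort[:5] + cohort[-3:]
    write_cohort(sub, tmp_path)
    back = read_cohort(tmp_path)
    assert len(back) == len(sub)
    for a, b in zip(sub, back):
        assert (a.subject_id, a.cohort) == (b.subject_id, b.cohort)
        assert a.symptom_scores == b.symptom_scores
        assert a.age == pytest.approx(b.age)
        assert len(a.recordings) == len(b.recordings)
        for ra, rb in zip(a.recordings, b.recordings):
            assert ra.counts == rb.counts
            assert ra.count_total == rb.count_total


def test_empty_cohort_round_trip(tmp_path):
    write_cohort([], tmp_path)
    assert read_cohort(tmp_path) == []


def test_negative_count_rejected_with_line_number(tmp_path, table,
                                                  small_null_cohort):
    _, cohort = small_null_cohort
    write_cohort(cohort[:2], tmp_path)
    counts_path = tmp_path / "counts.tsv"
    lines = counts_path.read_text().splitlines()
    lines[3] = lines[3].rsplit("\t", 1)[0] + "\t-5"
    counts_path.write_text("\n".join(lines) + "\n")
    with pytest.raises(CohortIOError, match="line 4"):
        read_cohort(tmp_path)
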