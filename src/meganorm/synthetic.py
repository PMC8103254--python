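"""Synthetic cohorts of per-region validated-current counts.

Generates subject and empty-room recordings with the statistical structure the
downstream analysis assumes: multinomial counts over the partition regions
with volume-proportional baseline probabilities modulated by log-normal
latent activity, planted multiplicative group and symptom effects, a shared
session-quality factor linking a subject recording to its same-day empty-room
recording, an additive dark-count layer whose regional pattern is shared
between the two (the mechanism behind the positive subject<->empty-room
density correlations), thinned deep-tract counts, and integer symptom survey
scores tied to the same latents that carry the symptom's brain effect.

Everything is reproducible from one root seed; independent named substreams
(latents, totals, multinomials, surveys, anatomy) keep draws stable when one
stage changes.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .regions import RegionTable, default_region_table

COHORTS = ("norm", "clin")
SESSIONS = ("baseline", "followup")
CONDITIONS = ("rest", "task", "empty_room")

#: symptom-survey cut-offs: score >= cut-off screens positive
DEFAULT_CUTOFFS = {"insomnia": 15, "somatization": 63, "depression": 63,
                   "anxiety": 63}


class CohortSpecError(ValueError):
    """Raised for invalid generator parameters."""


class CohortIOError(ValueError):
    """Raised when cohort files are malformed."""


@dataclass(frozen=True)
class SymptomDef:
    """One symptom: its prevalence in the clinical cohort, the regions whose
    activity it multiplies, and the survey cut-off used to screen positive."""

    name: str
    prevalence: float
    effects: dict[str, float]  # region_id -> multiplicative effect
    cutoff: int
    score_spread: float = 6.0  # survey points per latent s.d. beyond threshold


def default_symptom_defs() -> list[SymptomDef]:
    """Four symptoms of the chronic-TBI screening battery.

    Prevalences approximate the clinical cohort's screen-positive rates
    (roughly 0.3-0.5); affected regions and effect directions follow the
    regions that dominate the published symptom classifiers (e.g. depressed
    thalamic activity with insomnia-linked hippocampus/insula reductions).
    """
    return [
        SymptomDef("insomnia", 0.47,
                   {"L_hippocampus": 0.70, "L_insula": 0.70}, cutoff=15),
        SymptomDef("somatization", 0.43, {"L_amygdala": 1.40}, cutoff=63),
        SymptomDef("depression", 0.31,
                   {"R_thalamus": 1.50, "R_lateraloccipital": 0.70}, cutoff=63),
        SymptomDef("anxiety", 0.46,
                   {"L_rostralanteriorcingulate": 1.40, "R_insula": 1.40},
                   cutoff=63),
    ]


def default_cohort_effect() -> dict[str, float]:
    """Regions distinguishing the clinical cohort (bilateral thalamic
    reduction, cerebellar/fusiform elevation)."""
    return {"L_thalamus": 0.70, "R_thalamus": 0.70, "R_cerebellum": 1.40,
            "L_fusiform": 1.40, "R_hippocampus": 0.70}


@dataclass
class SyntheticCohortSpec:
    """Generative parameters for a two-cohort study.

    Defaults emulate the study conditions: 619 normative and 63 clinical
    subjects, ~41% returning for follow-up, on the order of 5e5 validated
    currents per recording, a modest dark-count share, and a long-term latent
    stability of 0.45.
    """

    n_subjects_norm: int = 619
    n_subjects_clin: int = 63
    followup_fraction: float = 0.41
    total_count_mean: float = 500_000.0
    total_count_cv: float = 0.30
    region_activity_base: dict[str, float] = field(default_factory=dict)
    symptom_defs: list[SymptomDef] = field(default_factory=default_symptom_defs)
    cohort_effect: dict[str, float] = field(default_factory=default_cohort_effect)
    dark_fraction: float = 0.05
    session_quality_sd: float = 0.20
    retest_rho: float = 0.45
    subject_sd: float = 0.25          # between-subject log-activity s.d.
    recording_sd: float = 0.05        # per-recording log-activity jitter
    dark_pattern_sd: float = 0.30     # per-session dark-count regional pattern
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects_norm < 0 or self.n_subjects_clin < 0:
            raise CohortSpecError("cohort sizes must be non-negative")
        if not 0.0 <= self.followup_fraction <= 1.0:
            raise CohortSpecError("followup_fraction must be in [0, 1]")
        if not self.total_count_mean > 0:
            raise CohortSpecError("total_count_mean must be positive")
        if self.total_count_cv < 0:
            raise CohortSpecError("total_count_cv must be >= 0")
        if not 0.0 <= self.dark_fraction < 1.0:
            raise CohortSpecError("dark_fraction must be in [0, 1)")
        if self.session_quality_sd < 0:
            raise CohortSpecError("session_quality_sd must be >= 0")
        if not 0.0 <= self.retest_rho <= 1.0:
            raise CohortSpecError("retest_rho must be in [0, 1]")
        for d in (self.subject_sd, self.recording_sd, self.dark_pattern_sd):
            if d < 0:
                raise CohortSpecError("latent s.d. parameters must be >= 0")
        for rid, mult in {**self.region_activity_base,
                          **self.cohort_effect}.items():
            if not mult > 0:
                raise CohortSpecError(f"multiplier for {rid!r} must be > 0")
        for sym in self.symptom_defs:
            if not 0.0 < sym.prevalence < 1.0:
                raise CohortSpecError(
                    f"prevalence for {sym.name!r} must be in (0, 1)")
            for rid, mult in sym.effects.items():
                if not mult > 0:
                    raise CohortSpecError(
                        f"effect for {sym.name!r}/{rid!r} must be > 0")


def null_spec(**overrides) -> SyntheticCohortSpec:
    """All effects 1 and no dark counts: the two cohorts are exchangeable.

    With a dark layer present the per-cohort empty-room correction estimates
    its correlations with different sampling error in the two cohorts, which
    by itself separates them; the exchangeable null therefore switches the
    dark layer off entirely.
    """
    base = SyntheticCohortSpec(
        symptom_defs=[replace(s, effects={}) for s in default_symptom_defs()],
        cohort_effect={},
        dark_fraction=0.0,
    )
    return replace(base, **overrides)


@dataclass
class RecordingCounts:
    """One recording's per-region validated-current counts.

    ``count_total`` is the sum over the partition regions (cortical + wm_rim
    + subcortical); deep-tract counts overlap those regions and are tallied
    independently.
    """

    subject_id: str
    cohort: str
    session: str
    condition: str
    counts: dict[str, int]
    count_total: int

    def count(self, region_id: str) -> int:
        """Count for a region; absent means a (meaningful) zero."""
        return self.counts.get(region_id, 0)


@dataclass
class SubjectRecord:
    subject_id: str
    cohort: str
    age: float
    symptom_scores: dict[str, int]
    recordings: list[RecordingCounts]

    def recording(self, session: str, condition: str) -> Optional[RecordingCounts]:
        for rec in self.recordings:
            if rec.session == session and rec.condition == condition:
                return rec
        return None


# ---------------------------------------------------------------------------
# generation

def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("latents", "totals", "multinomials", "surveys", "anatomy")
    return {name: np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(names)}


def _lognormal_mean(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Draw a log-normal variate with the given mean and coefficient of
    variation (degenerate at ``mean`` when cv = 0)."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * sigma2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def tract_overlaps(table: RegionTable, seed: int) -> dict[str, list[str]]:
    """Deterministic map tract -> white-matter rims it overlaps.

    Each deep tract threads 4-8 rims of its own hemisphere (midline tracts
    draw from both).  The map is anatomy, fixed once per (table, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(4,)))
    rims = [table[rid] for rid in table.ids_of_class("wm_rim")]
    out: dict[str, list[str]] = {}
    for tract in (table[rid] for rid in table.ids_of_class("deep_tract")):
        if tract.hemisphere == "midline":
            pool = [r.region_id for r in rims]
        else:
            pool = [r.region_id for r in rims if r.hemisphere == tract.hemisphere]
        k = int(rng.integers(4, 9))
        chosen = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        out[tract.region_id] = [pool[i] for i in sorted(chosen)]
    return out


def generate_cohort(spec: SyntheticCohortSpec,
                    table: Optional[RegionTable] = None) -> list[SubjectRecord]:
    """Generate the full two-cohort study for a spec.

    Every subject has a baseline rest, task and same-day empty-room recording;
    the follow-up subset additionally has a follow-up rest and empty-room
    recording.  Follow-up latent activity correlates with baseline at
    ``retest_rho``.  Fully reproducible for a fixed seed.
    """
    spec.validate()
    if table is None:
        table = default_region_table(seed=spec.seed)
    rngs = _streams(spec.seed)

    part_ids = table.partition_ids
    part_vols = np.array([table[r].volume_mm3 for r in part_ids])
    base_log = np.log(np.array(
        [spec.region_activity_base.get(r, 1.0) for r in part_ids]))
    cohort_log = np.log(np.array(
        [spec.cohort_effect.get(r, 1.0) for r in part_ids]))
    overlaps = tract_overlaps(table, spec.seed)
    tract_ids = table.ids_of_class("deep_tract")
    thin_p = {}
    for tid in tract_ids:
        rim_vol = sum(table[r].volume_mm3 for r in overlaps[tid])
        thin_p[tid] = min(0.9, table[tid].volume_mm3 / rim_vol)

    sym_thresholds = {s.name: float(-_NORMAL.ppf(s.prevalence))
                      for s in spec.symptom_defs}

    subjects: list[SubjectRecord] = []
    plan = ([("norm", f"N{i + 1:04d}") for i in range(spec.n_subjects_norm)]
            + [("clin", f"C{i + 1:04d}") for i in range(spec.n_subjects_clin)])
    n_follow = {"norm": int(round(spec.followup_fraction * spec.n_subjects_norm)),
                "clin": int(round(spec.followup_fraction * spec.n_subjects_clin))}
    seen = {"norm": 0, "clin": 0}

    for cohort, sid in plan:
        seen[cohort] += 1
        has_followup = seen[cohort] <= n_follow[cohort]
        lo, hi = (18.0, 87.0) if cohort == "norm" else (21.0, 60.0)
        age = float(rngs["latents"].uniform(lo, hi))

        # symptom latents: clinical cohort only carries survey scores
        effect_log = base_log.copy()
        if cohort == "clin":
            effect_log = effect_log + cohort_log
        scores: dict[str, int] = {}
        for sym in spec.symptom_defs:
            u = float(rngs["surveys"].standard_normal())
            if cohort != "clin":
                continue
            thr = sym_thresholds[sym.name]
            positive = u >= thr
            if positive:
                for rid, mult in sym.effects.items():
                    if rid in table and table[rid].reg_class != "deep_tract":
                        effect_log[part_ids.index(rid)] += np.log(mult)
            # integer survey score: >= cutoff iff latent exceeds threshold
            delta = sym.score_spread * (u - thr)
            if positive:
                score = sym.cutoff + int(np.floor(delta))
            else:
                score = sym.cutoff - 1 + int(np.ceil(delta))
            scores[sym.name] = int(np.clip(score, 0, 4 * sym.cutoff))

        eps_base = rngs["latents"].normal(0.0, spec.subject_sd, size=len(part_ids))
        nu = rngs["latents"].normal(0.0, spec.subject_sd, size=len(part_ids))
        eps_follow = (spec.retest_rho * eps_base
                      + np.sqrt(1.0 - spec.retest_rho ** 2) * nu)

        recordings: list[RecordingCounts] = []
        session_plan = [("baseline", ("rest", "task"), eps_base)]
        if has_followup:
            session_plan.append(("followup", ("rest",), eps_follow))
        for session, conditions, eps in session_plan:
            q = np.exp(rngs["totals"].normal(0.0, spec.session_quality_sd)) \
                if spec.session_quality_sd > 0 else 1.0
            dark_pat = rngs["latents"].normal(0.0, spec.dark_pattern_sd,
                                              size=len(part_ids))
            w_dark = part_vols * np.exp(dark_pat)
            p_dark = w_dark / w_dark.sum()

            for condition in conditions:
                jit = rngs["latents"].normal(0.0, spec.recording_sd,
                                             size=len(part_ids))
                w_true = part_vols * np.exp(effect_log + eps + jit)
                p_true = w_true / w_true.sum()
                n_total = int(round(_lognormal_mean(
                    rngs["totals"], spec.total_count_mean,
                    spec.total_count_cv) * q))
                n_dark = int(rngs["multinomials"].binomial(
                    n_total, spec.dark_fraction)) if spec.dark_fraction else 0
                cnt = rngs["multinomials"].multinomial(n_total - n_dark, p_true)
                if n_dark:
                    cnt = cnt + rngs["multinomials"].multinomial(n_dark, p_dark)
                counts = {r: int(c) for r, c in zip(part_ids, cnt)}
                idx = {r: i for i, r in enumerate(part_ids)}
                for tid in tract_ids:
                    pool = int(sum(cnt[idx[r]] for r in overlaps[tid]))
                    counts[tid] = int(rngs["multinomials"].binomial(
                        pool, thin_p[tid]))
                recordings.append(RecordingCounts(
                    sid, cohort, session, condition, counts, int(cnt.sum())))

            # same-day empty room shares q and the dark pattern
            if spec.dark_fraction > 0:
                e_total = int(round(_lognormal_mean(
                    rngs["totals"], spec.dark_fraction * spec.total_count_mean,
                    spec.total_count_cv) * q))
            else:
                e_total = 0
            ecnt = rngs["multinomials"].multinomial(e_total, p_dark)
            ecounts = {r: int(c) for r, c in zip(part_ids, ecnt)}
            for tid in tract_ids:
                idx = {r: i for i, r in enumerate(part_ids)}
                pool = int(sum(ecnt[idx[r]] for r in overlaps[tid]))
                ecounts[tid] = int(rngs["multinomials"].binomial(
                    pool, thin_p[tid]))
            recordings.append(RecordingCounts(
                sid, cohort, session, "empty_room", ecounts, int(ecnt.sum())))

        subjects.append(SubjectRecord(sid, cohort, age, scores, recordings))
    return subjects


class _Normal:
    # thin wrapper so scipy is imported lazily at module import time
    def ppf(self, p: float) -> float:
        from scipy.stats import norm
        return float(norm.ppf(p))


_NORMAL = _Normal()


# ---------------------------------------------------------------------------
# survey dichotomisation

def dichotomize_scores(subject: SubjectRecord,
                       cutoffs: dict[str, int] = DEFAULT_CUTOFFS,
                       ) -> dict[str, str]:
    """Screen each named symptom: positive iff score >= cut-off.

    A symptom without a recorded score maps to ``"missing"`` rather than
    being silently dropped.
    """
    out = {}
    for name, cutoff in cutoffs.items():
        score = subject.symptom_scores.get(name)
        if score is None:
            out[name] = "missing"
        else:
            out[name] = "positive" if score >= cutoff else "negative"
    return out


# ---------------------------------------------------------------------------
# cohort I/O (lossless TSV round trip)

_COUNTS_FILE = "counts.tsv"
_SUBJECTS_FILE = "subjects.tsv"
_RECORDINGS_FILE = "recordings.tsv"


def _atomic_write(frame: pd.DataFrame, path: str) -> None:
    dirname = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tsv")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            frame.to_csv(fh, sep="\t", index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_cohort(cohort: list[SubjectRecord], directory: str | os.PathLike) -> None:
    """Write a cohort as three TSVs: subjects, recordings, long-form counts."""
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    sym_names = sorted({n for s in cohort for n in s.symptom_scores})
    subj_rows = []
    rec_rows = []
    cnt_rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "cohort": s.cohort, "age": s.age}
        for n in sym_names:
            row[n] = s.symptom_scores.get(n, "")
        subj_rows.append(row)
        for rec in s.recordings:
            rec_rows.append({"subject_id": s.subject_id, "cohort": rec.cohort,
                             "session": rec.session, "condition": rec.condition,
                             "count_total": rec.count_total})
            for rid, c in rec.counts.items():
                cnt_rows.append({"subject_id": s.subject_id,
                                 "cohort": rec.cohort, "session": rec.session,
                                 "condition": rec.condition,
                                 "region_id": rid, "count": c})
    _atomic_write(pd.DataFrame(
        subj_rows, columns=["subject_id", "cohort", "age"] + sym_names),
        os.path.join(directory, _SUBJECTS_FILE))
    _atomic_write(pd.DataFrame(
        rec_rows, columns=["subject_id", "cohort", "session", "condition",
                           "count_total"]),
        os.path.join(directory, _RECORDINGS_FILE))
    _atomic_write(pd.DataFrame(
        cnt_rows, columns=["subject_id", "cohort", "session", "condition",
                           "region_id", "count"]),
        os.path.join(directory, _COUNTS_FILE))


def read_cohort(directory: str | os.PathLike) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort` (lossless round trip)."""
    directory = os.fspath(directory)
    subj = pd.read_csv(os.path.join(directory, _SUBJECTS_FILE), sep="\t",
                       dtype={"subject_id": str})
    recs = pd.read_csv(os.path.join(directory, _RECORDINGS_FILE), sep="\t",
                       dtype={"subject_id": str})
    counts = pd.read_csv(os.path.join(directory, _COUNTS_FILE), sep="\t",
                         dtype={"subject_id": str, "region_id": str})
    bad = counts.index[counts["count"] < 0]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise CohortIOError(
            f"{_COUNTS_FILE} line {bad[0] + 2}: negative count "
            f"{counts.loc[bad[0], 'count']}")

    sym_names = [c for c in subj.columns
                 if c not in ("subject_id", "cohort", "age")]
    grouped = {k: g for k, g in counts.groupby(
        ["subject_id", "session", "condition"], sort=False)}
    out: list[SubjectRecord] = []
    for _, srow in subj.iterrows():
        sid = srow["subject_id"]
        scores = {}
        for n in sym_names:
            v = srow[n]
            if pd.notna(v) and v != "":
                scores[n] = int(v)
        recordings = []
        sub_recs = recs[recs["subject_id"] == sid]
        for _, rrow in sub_recs.iterrows():
            key = (sid, rrow["session"], rrow["condition"])
            g = grouped.get(key)
            cmap = ({str(r): int(c) for r, c in
                     zip(g["region_id"], g["count"])} if g is not None else {})
            recordings.append(RecordingCounts(
                sid, rrow["cohort"], rrow["session"], rrow["condition"],
                cmap, int(rrow["count_total"])))
        out.append(SubjectRecord(sid, srow["cohort"], float(srow["age"]),
                                 scores, recordings))
    return out
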