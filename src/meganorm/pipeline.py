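"""End-to-end orchestration: counts -> densities -> correction -> atlas ->
z-scores, plus convenient z-matrix extraction for the classifiers.

Default ordering: densities are dark-count corrected first (with the
subject<->empty-room correlation model fitted per cohort), the normative
atlas is then built on the corrected normative baseline densities, and all
recordings are z-scored against that atlas.  Both the correction and its
placement before atlas construction can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .density import (DensityVector, NormativeAtlas, ZScoreVector,
                      build_atlas, compute_density, zscore)
from .empty_room import EmptyRoomModel, correct_density, fit_empty_room_model
from .regions import RegionTable
from .synthetic import SubjectRecord

Key = tuple[str, str, str]  # (subject_id, session, condition)


@dataclass
class PipelineResult:
    table: RegionTable
    atlas: NormativeAtlas
    empty_models: dict[str, EmptyRoomModel]  # cohort -> model (may be empty)
    densities: dict[Key, DensityVector]  # corrected if correction applied
    raw_densities: dict[Key, DensityVector]
    zscores: dict[Key, ZScoreVector]
    cohort_of: dict[str, str]  # subject_id -> cohort

    def z_matrix(self, region_ids: Sequence[str],
                 cohort: Optional[str] = None, session: str = "baseline",
                 condition: str = "rest",
                 subject_ids: Optional[Sequence[str]] = None,
                 ) -> tuple[np.ndarray, list[str]]:
        """Subjects x regions z matrix for one (cohort, session, condition).

        Returns the matrix and the subject ids (row order).  ``subject_ids``
        restricts and orders the rows explicitly.
        """
        if subject_ids is None:
            subject_ids = [sid for (sid, ses, cond) in self.zscores
                           if ses == session and cond == condition
                           and (cohort is None or self.cohort_of[sid] == cohort)]
        rows = []
        for sid in subject_ids:
            zv = self.zscores[(sid, session, condition)]
            rows.append(zv.as_array(region_ids))
        return np.array(rows), list(subject_ids)


def compute_all_densities(cohort: Sequence[SubjectRecord], table: RegionTable,
                          ) -> dict[Key, DensityVector]:
    out: dict[Key, DensityVector] = {}
    for s in cohort:
        for rec in s.recordings:
            key = (s.subject_id, rec.session, rec.condition)
            if rec.condition == "empty_room" and rec.count_total == 0:
                # an ideal (dark-count-free) empty room: zero density, so the
                # correction reduces to the identity
                out[key] = DensityVector(
                    s.subject_id, rec.session, rec.condition,
                    {r.region_id: 0.0 for r in table.regions})
            else:
                out[key] = compute_density(rec, table)
    return out


def fit_cohort_empty_models(cohort: Sequence[SubjectRecord],
                            densities: dict[Key, DensityVector],
                            session: str = "baseline",
                            condition: str = "rest",
                            per_cohort: bool = True,
                            ) -> dict[str, EmptyRoomModel]:
    """Fit the subject<->empty-room correlation model.

    By default the correlation is estimated within each cohort separately
    (the clinical cohort gets its own model rather than borrowing the
    normative one); with ``per_cohort=False`` one pooled model is shared.
    """
    groups: dict[str, list[tuple[DensityVector, DensityVector]]] = {}
    for s in cohort:
        key_subj = (s.subject_id, session, condition)
        key_empty = (s.subject_id, session, "empty_room")
        if key_subj in densities and key_empty in densities:
            name = s.cohort if per_cohort else "all"
            groups.setdefault(name, []).append(
                (densities[key_subj], densities[key_empty]))
    models = {}
    for name, pairs in groups.items():
        subj_dvs = [p[0] for p in pairs]
        empty_dvs = [p[1] for p in pairs]
        models[name] = fit_empty_room_model(subj_dvs, empty_dvs)
    if not per_cohort:
        models = {c: models["all"] for c in {s.cohort for s in cohort}}
    return models


def run_pipeline(cohort: Sequence[SubjectRecord], table: RegionTable,
                 apply_correction: bool = True,
                 correction_before_atlas: bool = True,
                 per_cohort_correction: bool = True,
                 reference_cohort: str = "norm",
                 ) -> PipelineResult:
    """Run densities -> (correction) -> atlas -> z-scores for a cohort.

    The atlas reference set is the ``reference_cohort`` baseline rest
    recordings.  With ``correction_before_atlas=False`` the atlas is built
    on raw densities and the correction (if enabled) applies only to the
    individual vectors that are then z-scored.
    """
    raw = compute_all_densities(cohort, table)
    cohort_of = {s.subject_id: s.cohort for s in cohort}
    empty_models: dict[str, EmptyRoomModel] = {}
    densities = raw
    if apply_correction:
        empty_models = fit_cohort_empty_models(
            cohort, raw, per_cohort=per_cohort_correction)
        densities = {}
        for key, dv in raw.items():
            sid, session, condition = key
            if condition == "empty_room":
                densities[key] = dv
                continue
            empty_key = (sid, session, "empty_room")
            model = empty_models.get(cohort_of[sid])
            if model is None or empty_key not in raw:
                densities[key] = dv
            else:
                densities[key] = correct_density(dv, raw[empty_key], model)

    atlas_source = densities if (apply_correction and correction_before_atlas) \
        else raw
    reference = [atlas_source[(sid, "baseline", "rest")]
                 for sid, c in cohort_of.items() if c == reference_cohort
                 if (sid, "baseline", "rest") in atlas_source]
    atlas = build_atlas(reference)

    zscored = {}
    for key, dv in densities.items():
        if key[2] == "empty_room":
            continue
        zscored[key] = zscore(dv, atlas)
    return PipelineResult(table, atlas, empty_models, densities, raw,
                          zscored, cohort_of)
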