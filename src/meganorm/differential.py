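"""Per-subject cortex vs adjacent white-matter-rim activity differentials.

For each cortical parcel and its paired white-matter rim the observed counts
are compared with the counts expected if activity were proportional to
volume, using the 2-cell Pearson goodness-of-fit statistic (1 df, no
continuity correction — counts are in the thousands, so the correction is
immaterial).  Tail probabilities are computed in log space so that p-values
down to 1e-300 and beyond are representable; a stringent threshold
(default 1e-8) controls false positives over the tens of thousands of
subject x pair tests a cohort produces.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

from .regions import RegionTable
from .synthetic import RecordingCounts, SubjectRecord

DEFAULT_THRESHOLD_P = 1e-8
MIN_TESTABLE_COUNT = 10  # pairs with fewer total counts are not tested


@dataclass
class PairDifferentialResult:
    subject_id: str
    ctx_region: str
    wm_region: str
    c_ctx: int
    c_wm: int
    e_ctx: float
    e_wm: float
    chi2: float
    log10_p: float
    p: float
    direction: str  # "cortex_higher" | "wm_higher" | "none"
    significant: bool
    testable: bool = True


def pair_chi2(c_ctx: int, c_wm: int, v_ctx: float, v_wm: float,
              threshold_p: float = DEFAULT_THRESHOLD_P,
              subject_id: str = "", ctx_region: str = "", wm_region: str = "",
              ) -> PairDifferentialResult:
    """Test one cortex/rim pair against volume-proportional expected counts.

    Expected counts split the observed total by volume fraction; the
    direction compares the per-volume rates c/v.  Pairs with total count
    below ``MIN_TESTABLE_COUNT`` (including zero) are flagged untestable.
    """
    if c_ctx < 0 or c_wm < 0:
        raise ValueError("counts must be non-negative")
    if not (v_ctx > 0 and v_wm > 0):
        raise ValueError("volumes must be positive")
    total = c_ctx + c_wm
    e_ctx = total * v_ctx / (v_ctx + v_wm)
    e_wm = total * v_wm / (v_ctx + v_wm)
    if total < MIN_TESTABLE_COUNT:
        return PairDifferentialResult(
            subject_id, ctx_region, wm_region, c_ctx, c_wm, e_ctx, e_wm,
            math.nan, math.nan, math.nan, "none", False, testable=False)
    chi2 = (c_ctx - e_ctx) ** 2 / e_ctx + (c_wm - e_wm) ** 2 / e_wm
    # 1-df tail via the normal identity sf(x) = 2*Phi(-sqrt(x)); log_ndtr
    # stays finite where chi2.logsf underflows (chi2 in the tens of thousands)
    log_p = float(math.log(2.0) + log_ndtr(-math.sqrt(chi2)))
    log10_p = log_p / math.log(10.0)
    p = math.exp(log_p) if log_p > -700 else 0.0
    rate_ctx = c_ctx / v_ctx
    rate_wm = c_wm / v_wm
    if chi2 == 0 or rate_ctx == rate_wm:
        direction = "none"
    elif rate_ctx > rate_wm:
        direction = "cortex_higher"
    else:
        direction = "wm_higher"
    significant = bool(log10_p < math.log10(threshold_p))
    return PairDifferentialResult(
        subject_id, ctx_region, wm_region, c_ctx, c_wm, e_ctx, e_wm,
        float(chi2), log10_p, p, direction, significant)


@dataclass
class DifferentialSummary:
    n_pairs_total: int
    n_untestable: int
    n_cortex_higher: int
    n_wm_higher: int

    @property
    def frac_cortex_higher(self) -> float:
        return self.n_cortex_higher / self.n_pairs_total if self.n_pairs_total else 0.0

    @property
    def frac_wm_higher(self) -> float:
        return self.n_wm_higher / self.n_pairs_total if self.n_pairs_total else 0.0


def cohort_differential_summary(
        cohort: Sequence[SubjectRecord], table: RegionTable,
        threshold_p: float = DEFAULT_THRESHOLD_P,
        session: str = "baseline", condition: str = "rest",
        return_results: bool = False,
        ) -> "DifferentialSummary | tuple[DifferentialSummary, list[PairDifferentialResult]]":
    """Tally significant cortex/rim differentials over a cohort.

    One test per subject per cortex/rim pair on the chosen recording (raw
    counts; the statistic needs integers).
    """
    pairs = table.cortex_rim_pairs()
    results: list[PairDifferentialResult] = []
    n_total = 0
    n_unt = n_ctx = n_wm = 0
    for subject in cohort:
        rec = subject.recording(session, condition)
        if rec is None:
            continue
        for ctx_id, rim_id in pairs:
            n_total += 1
            res = pair_chi2(rec.count(ctx_id), rec.count(rim_id),
                            table[ctx_id].volume_mm3, table[rim_id].volume_mm3,
                            threshold_p, subject.subject_id, ctx_id, rim_id)
            if not res.testable:
                n_unt += 1
            elif res.significant:
                if res.direction == "cortex_higher":
                    n_ctx += 1
                elif res.direction == "wm_higher":
                    n_wm += 1
            if return_results:
                results.append(res)
    summary = DifferentialSummary(n_total, n_unt, n_ctx, n_wm)
    return (summary, results) if return_results else summary


def write_differential_results(results: Iterable[PairDifferentialResult],
                               path: str | os.PathLike) -> None:
    frame = pd.DataFrame([{
        "subject_id": r.subject_id, "ctx_region": r.ctx_region,
        "wm_region": r.wm_region, "c_ctx": r.c_ctx, "c_wm": r.c_wm,
        "chi2": r.chi2, "log10_p": r.log10_p, "direction": r.direction,
        "significant": r.significant,
    } for r in results])
    dirname = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tsv")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            frame.to_csv(fh, sep="\t", index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
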