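"""Test-retest reliability of regional z-scores.

Short-term reliability compares rest vs task recordings from the same
sitting; long-term reliability compares baseline vs follow-up rest
recordings.  Both are summarised per region by the Pearson correlation
across paired subjects and the mean difference (second minus first, in
z-score units); the mean difference can be used to adjust a follow-up
measure for comparison with baseline.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ReliabilityError(ValueError):
    pass


@dataclass
class ReliabilityReport:
    """Per-region test-retest summary.

    ``pearson_r`` is NaN for a region with zero variance in either session
    (correlation undefined there).
    """

    term: str  # "short" or "long"
    region_ids: list[str]
    pearson_r: dict[str, float]
    mean_diff: dict[str, float]  # second minus first, z units
    n_pairs: int
    p_diff: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": self.region_ids,
            "term": self.term,
            "pearson_r": [self.pearson_r[r] for r in self.region_ids],
            "mean_diff": [self.mean_diff[r] for r in self.region_ids],
            "n_pairs": self.n_pairs,
            "p_diff": [self.p_diff[r] if self.p_diff else np.nan
                       for r in self.region_ids],
        })

    def write(self, path: str | os.PathLike) -> None:
        dirname = os.path.dirname(os.fspath(path)) or "."
        fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tsv")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                self.to_frame().to_csv(fh, sep="\t", index=False)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def test_retest(z_first: np.ndarray, z_second: np.ndarray,
                region_ids: list[str], term: str = "long",
                ) -> ReliabilityReport:
    """Per-region Pearson r and mean difference across paired subjects.

    Rows of ``z_first`` and ``z_second`` must be paired by subject.
    """
    z_first = np.asarray(z_first, dtype=float)
    z_second = np.asarray(z_second, dtype=float)
    if z_first.shape != z_second.shape:
        raise ReliabilityError(
            f"unpaired matrices: {z_first.shape} vs {z_second.shape}")
    n = z_first.shape[0]
    if n < 3:
        raise ReliabilityError(f"need >= 3 paired subjects, got {n}")
    if z_first.shape[1] != len(region_ids):
        raise ReliabilityError("region_ids does not match matrix width")

    a = z_first - z_first.mean(axis=0)
    b = z_second - z_second.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).mean(axis=0) / (sa * sb)
    r[(sa == 0) | (sb == 0)] = np.nan  # undefined, flagged
    diff = (z_second - z_first).mean(axis=0)
    return ReliabilityReport(
        term=term,
        region_ids=list(region_ids),
        pearson_r=dict(zip(region_ids, r.tolist())),
        mean_diff=dict(zip(region_ids, diff.tolist())),
        n_pairs=n,
    )


def reliability_difference_significance(report: ReliabilityReport,
                                        z_first: np.ndarray,
                                        z_second: np.ndarray,
                                        ) -> ReliabilityReport:
    """Paired two-sided t-test per region for mean difference != 0.

    Returns the report with ``p_diff`` filled in; a region whose paired
    differences are all identical (zero-variance difference) gets p = 1.0
    when the difference is zero and NaN otherwise (t undefined).
    """
    z_first = np.asarray(z_first, dtype=float)
    z_second = np.asarray(z_second, dtype=float)
    d = z_second - z_first
    sd = d.std(axis=0, ddof=1)
    p = np.empty(d.shape[1])
    ok = sd > 0
    if ok.any():
        res = stats.ttest_rel(z_second[:, ok], z_first[:, ok])
        p[ok] = res.pvalue
    deg = ~ok
    p[deg & (np.abs(d.mean(axis=0)) < 1e-300)] = 1.0
    p[deg & (np.abs(d.mean(axis=0)) >= 1e-300)] = np.nan
    report.p_diff = dict(zip(report.region_ids, p.tolist()))
    return report
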