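"""Regional current density and the normative z-score atlas.

A recording's count for region *r* is normalised to a density

    rho_r = (count_r / count_total) / (vol_r / vol_total)

so that rho_r = 1 everywhere when currents are uniformly distributed over the
brain.  Dividing by the total count removes variation due to data quality and
record length; dividing by the volume fraction makes regions comparable.
Deep white-matter tracts, although excluded from the volume partition, are
normalised with the same whole-brain totals.

A normative atlas holds the per-region mean and standard deviation of density
over a reference cohort; any recording is then expressed as z-scores

    z_r = (rho_r - mean_r) / sd_r .

Because a density cannot be negative, each region's z has a floor
(0 - mean_r)/sd_r, attained exactly when the count is zero.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regions import RegionTable
from .synthetic import RecordingCounts


class DensityError(ValueError):
    pass


class AtlasError(ValueError):
    pass


@dataclass
class DensityVector:
    subject_id: str
    session: str
    condition: str
    rho: dict[str, float]

    def as_array(self, region_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.rho[r] for r in region_ids])


@dataclass
class ZScoreVector:
    subject_id: str
    session: str
    condition: str
    z: dict[str, float]

    def as_array(self, region_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.z[r] for r in region_ids])


@dataclass
class NormativeAtlas:
    """Per-region normative mean/sd of density, with the z floor."""

    mean_rho: dict[str, float]
    sd_rho: dict[str, float]
    n_reference: int
    floor_z: dict[str, float]

    @property
    def region_ids(self) -> list[str]:
        return list(self.mean_rho)

    def write(self, path: str | os.PathLike) -> None:
        frame = pd.DataFrame({
            "region_id": list(self.mean_rho),
            "mean_rho": [self.mean_rho[r] for r in self.mean_rho],
            "sd_rho": [self.sd_rho[r] for r in self.mean_rho],
            "n_reference": self.n_reference,
            "floor_z": [self.floor_z[r] for r in self.mean_rho],
        })
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

    @classmethod
    def load(cls, path: str | os.PathLike) -> "NormativeAtlas":
        frame = pd.read_csv(path, sep="\t", dtype={"region_id": str})
        return cls(
            mean_rho=dict(zip(frame["region_id"], frame["mean_rho"])),
            sd_rho=dict(zip(frame["region_id"], frame["sd_rho"])),
            n_reference=int(frame["n_reference"].iloc[0]) if len(frame) else 0,
            floor_z=dict(zip(frame["region_id"], frame["floor_z"])),
        )


def compute_density(rec: RecordingCounts, table: RegionTable) -> DensityVector:
    """Normalise a recording's counts to regional densities.

    Regions absent from the counts map are treated as count 0 (a validated
    count of zero is meaningful, not missing).  A zero total leaves the
    density undefined and is an error.
    """
    if rec.count_total <= 0:
        raise DensityError(
            f"recording {rec.subject_id}/{rec.session}/{rec.condition}: "
            f"count_total is {rec.count_total}; density undefined")
    vt = table.vol_total_mm3
    ct = rec.count_total
    rho = {}
    for r in table.regions:
        rho[r.region_id] = (rec.count(r.region_id) / ct) / (r.volume_mm3 / vt)
    return DensityVector(rec.subject_id, rec.session, rec.condition, rho)


def build_atlas(densities: Sequence[DensityVector],
                ddof: int = 1) -> NormativeAtlas:
    """Per-region mean and sample s.d. (n-1 denominator) over a reference set.

    A region with zero variance across the reference makes the atlas unusable
    there and is an error.
    """
    if len(densities) < 3:
        raise AtlasError(f"need >= 3 reference densities, got {len(densities)}")
    region_ids = list(densities[0].rho)
    for dv in densities[1:]:
        if set(dv.rho) != set(region_ids):
            raise AtlasError(
                f"reference density for {dv.subject_id!r} covers different "
                f"regions")
    mat = np.array([[dv.rho[r] for r in region_ids] for dv in densities])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise AtlasError(
            f"zero variance across reference for region "
            f"{region_ids[zero[0]]!r}; atlas unusable there")
    floor = (0.0 - mean) / sd
    return NormativeAtlas(
        mean_rho=dict(zip(region_ids, mean.tolist())),
        sd_rho=dict(zip(region_ids, sd.tolist())),
        n_reference=len(densities),
        floor_z=dict(zip(region_ids, floor.tolist())),
    )


def zscore(dv: DensityVector, atlas: NormativeAtlas) -> ZScoreVector:
    """Express a density vector as normative z-scores."""
    z = {}
    for r, rho in dv.rho.items():
        if r not in atlas.mean_rho:
            raise AtlasError(f"region {r!r} not covered by the atlas")
        z[r] = (rho - atlas.mean_rho[r]) / atlas.sd_rho[r]
    return ZScoreVector(dv.subject_id, dv.session, dv.condition, z)


def zscore_matrix(zvecs: Sequence[ZScoreVector],
                  region_ids: Sequence[str]) -> np.ndarray:
    """Stack z-score vectors into a subjects x regions matrix."""
    return np.array([zv.as_array(region_ids) for zv in zvecs])
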