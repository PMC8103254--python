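"""Empty-room dark-count correction.

An ideal extraction method would return zero activity from an empty-room
recording; in practice there is a dark count, and regional densities from
empty-room recordings correlate with the densities measured from the subject
present on the same day.  The correction subtracts the empty-room density
weighted by that correlation:

    rho_corrected_r = rho_r - corr_r * rho_empty_r

where corr_r is the across-subject Pearson correlation between subject and
same-day empty-room densities for region r.  When the two densities have
equal variance this coincides with the least-squares residual, so corrected
densities are uncorrelated with the empty-room densities in expectation.
Corrected densities may be negative; the z floor applies only pre-correction.
"""

from __future__ import annotations

import os
import tempfile
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .density import DensityVector


class EmptyRoomError(ValueError):
    pass


@dataclass
class EmptyRoomModel:
    """Per-region subject<->empty-room density correlation."""

    corr: dict[str, float]
    n_pairs: int

    def write(self, path: str | os.PathLike) -> None:
        frame = pd.DataFrame({
            "region_id": list(self.corr),
            "corr": list(self.corr.values()),
            "n_pairs": self.n_pairs,
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
    def load(cls, path: str | os.PathLike) -> "EmptyRoomModel":
        frame = pd.read_csv(path, sep="\t", dtype={"region_id": str})
        return cls(corr=dict(zip(frame["region_id"], frame["corr"])),
                   n_pairs=int(frame["n_pairs"].iloc[0]) if len(frame) else 0)


def fit_empty_room_model(subject_densities: Sequence[DensityVector],
                         empty_densities: Sequence[DensityVector],
                         ) -> EmptyRoomModel:
    """Per-region Pearson correlation across same-day subject/empty pairs.

    Inputs must be paired element-wise by subject and session.  A region with
    zero variance in either vector gets corr 0 (no correction applied there)
    with a warning.
    """
    if len(subject_densities) != len(empty_densities):
        raise EmptyRoomError(
            f"unpaired inputs: {len(subject_densities)} subject vs "
            f"{len(empty_densities)} empty-room densities")
    n = len(subject_densities)
    if n < 3:
        raise EmptyRoomError(f"need >= 3 pairs, got {n}")
    for sdv, edv in zip(subject_densities, empty_densities):
        if (sdv.subject_id, sdv.session) != (edv.subject_id, edv.session):
            raise EmptyRoomError(
                f"pair mismatch: {sdv.subject_id}/{sdv.session} vs "
                f"{edv.subject_id}/{edv.session}")
    region_ids = list(subject_densities[0].rho)
    S = np.array([[dv.rho[r] for r in region_ids] for dv in subject_densities])
    E = np.array([[dv.rho[r] for r in region_ids] for dv in empty_densities])
    Sc = S - S.mean(axis=0)
    Ec = E - E.mean(axis=0)
    s_sd = Sc.std(axis=0)
    e_sd = Ec.std(axis=0)
    corr = np.zeros(len(region_ids))
    ok = (s_sd > 0) & (e_sd > 0)
    corr[ok] = (Sc[:, ok] * Ec[:, ok]).mean(axis=0) / (s_sd[ok] * e_sd[ok])
    if not ok.all():
        degenerate = [region_ids[i] for i in np.flatnonzero(~ok)]
        warnings.warn(
            f"zero variance for {len(degenerate)} region(s) "
            f"(e.g. {degenerate[0]!r}); correlation set to 0 there",
            stacklevel=2)
    return EmptyRoomModel(corr=dict(zip(region_ids, corr.tolist())), n_pairs=n)


def correct_density(dv: DensityVector, empty_dv: DensityVector,
                    model: EmptyRoomModel) -> DensityVector:
    """Apply the dark-count correction to one recording's densities.

    ``empty_dv`` must be the same-day empty-room recording of the same
    subject.  Negative corrected densities are permitted.
    """
    if empty_dv is None:
        raise EmptyRoomError(
            f"{dv.subject_id}/{dv.session}: no same-day empty-room recording")
    if (dv.subject_id, dv.session) != (empty_dv.subject_id, empty_dv.session):
        raise EmptyRoomError(
            f"correction pair mismatch: {dv.subject_id}/{dv.session} vs "
            f"{empty_dv.subject_id}/{empty_dv.session}")
    rho = {r: v - model.corr.get(r, 0.0) * empty_dv.rho[r]
           for r, v in dv.rho.items()}
    return DensityVector(dv.subject_id, dv.session, dv.condition, rho)
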