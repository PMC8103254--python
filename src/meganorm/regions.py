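"""Region table: the parcellation every other module keys on.

The default parcellation mirrors the automated segmentation used for
MEG-derived regional current counts: 68 cortical parcels (Desikan-Killiany,
34 per hemisphere), 68 adjacent white-matter rims (thickness <= 5 mm, one per
cortical parcel), 17 subcortical structures, and 18 deep white-matter tracts.
The cortical + rim + subcortical regions partition the brain volume; the deep
tracts overlap white matter and are excluded from the partition sum, although
their densities are still normalised by whole-brain totals.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

REG_CLASSES = ("cortical", "wm_rim", "subcortical", "deep_tract")
HEMISPHERES = ("L", "R", "midline")

#: region classes whose volumes tile the whole brain
PARTITION_CLASSES = ("cortical", "wm_rim", "subcortical")

# Desikan-Killiany cortical parcel names (34 per hemisphere).
DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

# Subcortical structures: 8 bilateral pairs plus the brain-stem (17 total).
SUBCORTICAL_BILATERAL = [
    "thalamus", "caudate", "putamen", "pallidum",
    "hippocampus", "amygdala", "accumbens", "cerebellum",
]

# Deep white-matter tracts (Tracula naming): 2 midline + 8 bilateral pairs.
TRACT_MIDLINE = ["fmajor", "fminor"]
TRACT_BILATERAL = ["atr", "cab", "ccg", "cst", "ilf", "slfp", "slft", "unc"]


class RegionTableError(ValueError):
    """Raised when a region table violates a structural invariant."""


@dataclass(frozen=True)
class Region:
    region_id: str
    name: str
    reg_class: str
    hemisphere: str
    volume_mm3: float
    paired_region_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.reg_class not in REG_CLASSES:
            raise RegionTableError(
                f"region {self.region_id!r}: unknown reg_class {self.reg_class!r}")
        if self.hemisphere not in HEMISPHERES:
            raise RegionTableError(
                f"region {self.region_id!r}: unknown hemisphere {self.hemisphere!r}")
        if not (self.volume_mm3 > 0):
            raise RegionTableError(
                f"region {self.region_id!r}: non-positive volume {self.volume_mm3!r}")
        paired_expected = self.reg_class in ("cortical", "wm_rim")
        if paired_expected and not self.paired_region_id:
            raise RegionTableError(
                f"region {self.region_id!r}: {self.reg_class} region lacks "
                f"paired_region_id")
        if not paired_expected and self.paired_region_id:
            raise RegionTableError(
                f"region {self.region_id!r}: {self.reg_class} region must not "
                f"carry a pairing")


@dataclass
class RegionTable:
    """Ordered, validated collection of regions.

    ``vol_total_mm3`` is the whole-brain volume, by construction the sum of
    the cortical + wm_rim + subcortical volumes.  If an explicit total is
    supplied (e.g. read back from a file) it must agree with that sum to
    1e-9 relative, otherwise the table is rejected.
    """

    regions: list[Region]
    vol_total_mm3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        seen: set[str] = set()
        for rid in ids:
            if rid in seen:
                raise RegionTableError(f"duplicate region_id {rid!r}")
            seen.add(rid)
        self._index = {r.region_id: r for r in self.regions}

        partition_sum = sum(
            r.volume_mm3 for r in self.regions if r.reg_class in PARTITION_CLASSES)
        if self.vol_total_mm3 is None:
            self.vol_total_mm3 = partition_sum
        elif abs(partition_sum - self.vol_total_mm3) > 1e-9 * self.vol_total_mm3:
            raise RegionTableError(
                f"partition violation: cortical+wm_rim+subcortical volumes sum to "
                f"{partition_sum!r} but vol_total_mm3 is {self.vol_total_mm3!r}")

        # pairing must be a symmetric bijection cortical <-> wm_rim
        for r in self.regions:
            if r.paired_region_id is None:
                continue
            partner = self._index.get(r.paired_region_id)
            if partner is None:
                raise RegionTableError(
                    f"region {r.region_id!r}: paired region "
                    f"{r.paired_region_id!r} not in table")
            want = "wm_rim" if r.reg_class == "cortical" else "cortical"
            if partner.reg_class != want:
                raise RegionTableError(
                    f"region {r.region_id!r}: partner {partner.region_id!r} has "
                    f"class {partner.reg_class!r}, expected {want!r}")
            if partner.paired_region_id != r.region_id:
                raise RegionTableError(
                    f"asymmetric pairing {r.region_id!r} -> "
                    f"{r.paired_region_id!r} -> {partner.paired_region_id!r}")

    # -- access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._index

    def __getitem__(self, region_id: str) -> Region:
        return self._index[region_id]

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def ids_of_class(self, *reg_classes: str) -> list[str]:
        return [r.region_id for r in self.regions if r.reg_class in reg_classes]

    @property
    def partition_ids(self) -> list[str]:
        return self.ids_of_class(*PARTITION_CLASSES)

    @property
    def volumes(self) -> dict[str, float]:
        return {r.region_id: r.volume_mm3 for r in self.regions}

    def cortex_rim_pairs(self) -> list[tuple[str, str]]:
        """(cortical_id, rim_id) for every cortical parcel, in table order."""
        return [(r.region_id, r.paired_region_id) for r in self.regions
                if r.reg_class == "cortical"]

    # -- I/O ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "name": [r.name for r in self.regions],
                "reg_class": [r.reg_class for r in self.regions],
                "hemisphere": [r.hemisphere for r in self.regions],
                "volume_mm3": [r.volume_mm3 for r in self.regions],
                "paired_region_id": [r.paired_region_id or "" for r in self.regions],
            }
        )

    def write(self, path: str | os.PathLike) -> None:
        """Write as TSV (atomic: temp file + rename).

        The whole-brain total is kept in a ``# vol_total_mm3`` comment line so
        a round trip preserves the partition check.
        """
        frame = self.to_frame()
        dirname = os.path.dirname(os.fspath(path)) or "."
        fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tsv")
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                fh.write(f"# vol_total_mm3 = {self.vol_total_mm3!r}\n")
                frame.to_csv(fh, sep="\t", index=False)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def load_region_table(path: str | os.PathLike) -> RegionTable:
    """Load and validate a TSV region table.

    Columns: region_id, name, reg_class, hemisphere, volume_mm3,
    paired_region_id (empty allowed).  An optional ``# vol_total_mm3 = X``
    comment line carries the whole-brain total; when absent the total is the
    partition sum.
    """
    vol_total = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#") and "vol_total_mm3" in first:
        vol_total = float(first.split("=", 1)[1])
    frame = pd.read_csv(path, sep="\t", comment="#",
                        dtype={"region_id": str, "paired_region_id": str},
                        keep_default_na=False, na_values=[],
                        float_precision="round_trip")
    required = {"region_id", "name", "reg_class", "hemisphere", "volume_mm3",
                "paired_region_id"}
    missing = required - set(frame.columns)
    if missing:
        raise RegionTableError(f"region table missing columns: {sorted(missing)}")
    regions = []
    for i, row in frame.iterrows():
        try:
            vol = float(row["volume_mm3"])
        except (TypeError, ValueError) as exc:
            raise RegionTableError(
                f"row {i + 2}: bad volume {row['volume_mm3']!r}") from exc
        regions.append(
            Region(
                region_id=row["region_id"],
                name=row["name"],
                reg_class=row["reg_class"],
                hemisphere=row["hemisphere"],
                volume_mm3=vol,
                paired_region_id=row["paired_region_id"] or None,
            )
        )
    return RegionTable(regions, vol_total_mm3=vol_total)


def default_region_table(scale: float = 1.0, seed: int = 0) -> RegionTable:
    """Deterministic 171-region table with realistic volume spread.

    Volumes span roughly 0.5-70 cm^3 (accumbens to cerebellar cortex); each
    white-matter rim is by construction smaller than its cortical partner.
    ``scale`` multiplies every volume; the partition total is exact by
    construction.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(901,)))
    regions: list[Region] = []

    for base in DK_CORTICAL:
        # cortical parcel volumes: a few cm^3 up to tens of cm^3
        vols = np.clip(rng.lognormal(np.log(9000.0), 0.55, size=2), 1500, 68000)
        rim_frac = rng.uniform(0.25, 0.6, size=2)
        for hemi, vol, rf in zip(("L", "R"), vols, rim_frac):
            ctx_id = f"{hemi}_{base}"
            rim_id = f"{hemi}_{base}_wm"
            regions.append(Region(ctx_id, f"{hemi} {base}", "cortical", hemi,
                                  float(vol * scale), rim_id))
            regions.append(Region(rim_id, f"{hemi} {base} wm rim", "wm_rim",
                                  hemi, float(vol * rf * scale), ctx_id))

    for base in SUBCORTICAL_BILATERAL:
        if base == "cerebellum":
            vols = np.clip(rng.lognormal(np.log(45000.0), 0.2, size=2),
                           20000, 70000)
        elif base == "accumbens":
            vols = np.clip(rng.lognormal(np.log(600.0), 0.2, size=2), 400, 1200)
        else:
            vols = np.clip(rng.lognormal(np.log(4000.0), 0.4, size=2), 800, 20000)
        for hemi, vol in zip(("L", "R"), vols):
            regions.append(Region(f"{hemi}_{base}", f"{hemi} {base}",
                                  "subcortical", hemi, float(vol * scale)))
    bs_vol = float(np.clip(rng.lognormal(np.log(20000.0), 0.2), 8000, 40000))
    regions.append(Region("brain-stem", "brain stem", "subcortical", "midline",
                          bs_vol * scale))

    for base in TRACT_MIDLINE:
        vol = float(np.clip(rng.lognormal(np.log(6000.0), 0.4), 1000, 30000))
        regions.append(Region(base, f"{base} tract", "deep_tract", "midline",
                              vol * scale))
    for base in TRACT_BILATERAL:
        vols = np.clip(rng.lognormal(np.log(5000.0), 0.4, size=2), 800, 30000)
        for hemi, vol in zip(("L", "R"), vols):
            regions.append(Region(f"{hemi}_{base}", f"{hemi} {base} tract",
                                  "deep_tract", hemi, float(vol * scale)))

    return RegionTable(regions)
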