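"""Core beta-PET regional quantification.

The beta-PET readout is the change in normalized regional glucose uptake
between two scans of the same animal: a baseline scan taken after a
familiarization session (F1) and a second scan taken after the contextual
recall session (F3).  Each scan is first normalized to its whole-brain mean
so that regional values are dimensionless standard-uptake values (SUV);
per-region, per-coronal-slice, per-hemisphere SUVs are then differenced,
``delta_suv = SUV(F3) - SUV(F1)``, yielding a nested table of task-associated
uptake changes.

Conventions
-----------
* Volumes are indexed ``(x, y, z)`` with x = left-right, y = dorsal-ventral
  and z = the coronal slice index; indices are 0-based.
* The hemisphere split is a configurable midline x coordinate; voxels with
  ``x < midline_x`` are assigned to the left hemisphere, voxels with
  ``x >= midline_x`` to the right (midline voxels go right by convention).
* The prefrontal regions PLC and ILC straddle the midline and are scored as
  a single object per slice (hemisphere code ``BOTH``); all other regions
  produce separate ``L`` and ``R`` records per slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Region codes used throughout: basolateral amygdala, prelimbic and
#: infralimbic cortex, dorsal/ventral hippocampus, subiculum, and
#: lateral/medial entorhinal cortex.
REGION_CODES = ("BA", "PLC", "ILC", "DH", "VH", "SB", "LEC", "MEC")

#: Prefrontal regions scored as one object per slice (no hemisphere split).
MIDLINE_REGIONS = frozenset({"PLC", "ILC"})

SUV_COLUMNS = ["subject", "session", "region", "slice_index", "hemisphere", "suv", "n_voxels"]
DELTA_COLUMNS = ["subject", "region", "slice_index", "hemisphere", "delta_suv", "n_voxels"]


@dataclass
class ScanVolume:
    """One registered, skull-stripped 3D uptake volume.

    Parameters
    ----------
    subject_id : str
        Animal identifier.
    session : str
        Scan session tag, ``"F1"`` (baseline) or ``"F3"`` (recall).
    voxels : ndarray, shape (nx, ny, nz)
        Uptake values; finite floats.
    voxel_size_mm : tuple of float
        Per-axis voxel spacing in millimetres.
    normalized : bool
        Whether the volume has been normalized to its whole-brain mean.
    """

    subject_id: str
    session: str
    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (0.78, 0.78, 0.8)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        if self.session not in ("F1", "F3"):
            raise ValueError(f"session must be 'F1' or 'F3', got {self.session!r}")


@dataclass
class RegionMaskSet:
    """Named region masks over a common grid with a hemisphere-splitting rule.

    ``regions`` maps each region code to a 3D boolean array on the scan grid;
    a region's coronal slices are the z indices where the mask has any voxel.
    ``bilateral`` marks regions scored per hemisphere (False for PLC/ILC).
    """

    regions: dict[str, np.ndarray]
    midline_x: int
    bilateral: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            self.regions[code] = mask
            if code not in self.bilateral:
                self.bilateral[code] = code not in MIDLINE_REGIONS
        shapes = {m.shape for m in self.regions.values()}
        if len(shapes) > 1:
            raise ValueError(f"region masks have inconsistent shapes: {shapes}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.regions.values())).shape

    def slices(self, code: str) -> list[int]:
        """z indices on which the region has mask voxels, ascending."""
        mask = self.regions[code]
        return [int(z) for z in np.nonzero(mask.any(axis=(0, 1)))[0]]

    def expected_record_count(self) -> int:
        """Records one scan should yield: slices x (2 if bilateral else 1)."""
        return sum(
            len(self.slices(code)) * (2 if self.bilateral[code] else 1)
            for code in self.regions
        )


def normalize_scan(volume: ScanVolume, brain_mask: np.ndarray) -> ScanVolume:
    """Normalize a scan to its whole-brain mean uptake.

    Every voxel is divided by the mean of in-mask (brain) voxels, so the
    in-mask mean of the result is exactly 1; out-of-mask voxels are zeroed.
    The operation makes all downstream SUVs invariant to global intensity
    scale (injected dose, scanner gain).

    Raises
    ------
    ValueError
        If the volume is already normalized, the mask is empty, or the
        in-mask mean is not strictly positive.
    """
    if volume.normalized:
        raise ValueError(f"scan {volume.subject_id}/{volume.session} is already normalized")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != volume.voxels.shape:
        raise ValueError("brain mask shape does not match volume")
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    mean = float(volume.voxels[brain_mask].mean())
    if mean <= 0:
        raise ValueError(f"in-mask mean must be positive, got {mean}")
    out = np.where(brain_mask, volume.voxels / mean, 0.0)
    return replace(volume, voxels=out, normalized=True)


def region_suv_table(volume: ScanVolume, masks: RegionMaskSet) -> pd.DataFrame:
    """Extract per-region, per-slice, per-hemisphere mean SUVs from one scan.

    Bilateral regions are split at ``masks.midline_x`` into left
    (``x < midline_x``) and right (``x >= midline_x``) records; midline
    regions (PLC, ILC) yield one ``BOTH`` record per slice.  Slices where a
    hemisphere has no mask voxels are omitted with a logged warning rather
    than zero-filled, which would bias region means.

    Returns a DataFrame with columns
    ``subject, session, region, slice_index, hemisphere, suv, n_voxels``.
    """
    if not volume.normalized:
        raise ValueError("volume must be normalized before SUV extraction")
    if masks.grid_shape != volume.voxels.shape:
        raise ValueError(
            f"mask grid {masks.grid_shape} does not match volume {volume.voxels.shape}"
        )
    records = []
    xs = np.arange(volume.voxels.shape[0])
    left = xs < masks.midline_x
    for code, mask in masks.regions.items():
        hemis = (("L", "R") if masks.bilateral[code] else ("BOTH",))
        for z in masks.slices(code):
            plane = mask[:, :, z]
            for hemi in hemis:
                if hemi == "L":
                    sel = plane & left[:, None]
                elif hemi == "R":
                    sel = plane & ~left[:, None]
                else:
                    sel = plane
                n = int(sel.sum())
                if n == 0:
                    logger.warning(
                        "empty mask intersection: subject=%s session=%s region=%s "
                        "slice=%d hemisphere=%s -- record omitted",
                        volume.subject_id, volume.session, code, z, hemi,
                    )
                    continue
                records.append(
                    (
                        volume.subject_id,
                        volume.session,
                        code,
                        z,
                        hemi,
                        float(volume.voxels[:, :, z][sel].mean()),
                        n,
                    )
                )
    return pd.DataFrame(records, columns=SUV_COLUMNS)


_KEY = ["subject", "region", "slice_index", "hemisphere"]


def delta_suv(f1: pd.DataFrame, f3: pd.DataFrame) -> pd.DataFrame:
    """Difference two SUV tables record-wise: ``delta = SUV(F3) - SUV(F1)``.

    Both tables must cover identical (subject, region, slice, hemisphere)
    keys; orphan keys on either side raise with the offending keys listed.
    """
    k1 = set(map(tuple, f1[_KEY].itertuples(index=False)))
    k3 = set(map(tuple, f3[_KEY].itertuples(index=False)))
    if k1 != k3:
        orphans = sorted(k1 ^ k3)
        raise ValueError(f"F1/F3 key mismatch; orphan keys: {orphans[:20]}")
    merged = f1.merge(f3, on=_KEY, suffixes=("_f1", "_f3"), validate="one_to_one")
    out = merged[_KEY].copy()
    out["delta_suv"] = merged["suv_f3"] - merged["suv_f1"]
    out["n_voxels"] = merged["n_voxels_f1"]
    return out[DELTA_COLUMNS]


def subject_region_mean(delta: pd.DataFrame, voxel_weighted: bool = False) -> pd.DataFrame:
    """Collapse a delta-SUV table to one value per (subject, region).

    The default is the unweighted mean over all slice/hemisphere records;
    ``voxel_weighted=True`` weights each record by its voxel count instead.
    """
    if delta.empty:
        raise ValueError("delta table is empty")
    if voxel_weighted:
        def agg(g: pd.DataFrame) -> float:
            return float(np.average(g["delta_suv"], weights=g["n_voxels"]))
        out = (
            delta.groupby(["subject", "region"], sort=True)
            .apply(agg, include_groups=False)
            .rename("delta_suv")
            .reset_index()
        )
    else:
        out = (
            delta.groupby(["subject", "region"], sort=True)["delta_suv"]
            .mean()
            .reset_index()
        )
    return out


def network_map(values: dict[str, dict[str, float]], kind: str) -> dict:
    """Build a JSON-serializable per-group, per-region node map.

    ``values`` maps group -> region -> scalar (a group-mean delta-SUV or a
    Pearson r); every region code must be present for every group.  ``kind``
    records the aggregation (``"mean_delta"`` or ``"pearson_r"``).
    """
    if kind not in ("mean_delta", "pearson_r"):
        raise ValueError(f"unknown network map kind {kind!r}")
    for group, regs in values.items():
        missing = [c for c in REGION_CODES if c not in regs]
        if missing:
            raise ValueError(f"group {group!r} missing regions: {missing}")
    return {
        "kind": kind,
        "regions": list(REGION_CODES),
        "groups": {
            g: {code: float(regs[code]) for code in REGION_CODES}
            for g, regs in values.items()
        },
    }
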