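"""Synthetic two-scan cohorts with known ground truth.

Emulates the contextual-threat-memory imaging design: each subject has a
baseline FDG-PET scan after a familiarization session (F1) and a second
scan after the contextual recall session (F3), plus frame-wise activity
traces for the three behavioral sessions (F1 familiarization, F2
conditioning, F3 recall).  Subjects belong to a control-like group (CON)
whose task-responsive regions show a coherent uptake increase at recall,
or to a long-sepsis-like group (LS) whose responses are small and
incoherent across subjects.

The generator plants per-region uptake increments on top of a known
baseline and adds Gaussian noise at four nesting levels (subject,
hemisphere, slice, voxel), matching the nesting that the downstream mixed
model assumes.  Planted effects are recorded per subject before noise is
added, so every downstream stage can be tested for exact recovery (zero
noise) or statistical recovery (calibrated noise).

Default parameters are anchored to the study design this emulates:
group sizes 9 (CON) and 15 (LS); planted recall increments of
0.15/0.12/0.11/0.059 normalized-uptake units in BA/PLC/ILC/LEC for
CON-like subjects versus 0.049/0.032/0.046/-0.012 for LS-like subjects,
with near-zero planted changes in DH/VH/SB/MEC; session freezing targets
of roughly 38%/40% during conditioning and 73%/45% at recall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import DEFAULT_THRESHOLD, ActivityTrace
from .roi import REGION_CODES, RegionMaskSet, ScanVolume

DEFAULT_GRID = (32, 48, 32)
DEFAULT_VOXEL_MM = (0.78, 0.78, 0.8)

#: Planted recall-minus-baseline uptake increments per group (normalized
#: uptake units), the group-level ground truth the pipeline must recover.
DEFAULT_EFFECTS = {
    "CON": {
        "BA": 0.15, "PLC": 0.12, "ILC": 0.11, "LEC": 0.059,
        "DH": -0.043, "VH": 0.052, "SB": 0.016, "MEC": 0.0086,
    },
    "LS": {
        "BA": 0.049, "PLC": 0.032, "ILC": 0.046, "LEC": -0.012,
        "DH": -0.028, "VH": 0.023, "SB": -0.0024, "MEC": -0.00075,
    },
}

#: Baseline regional uptake above the whole-brain mean (normalized units).
DEFAULT_BASELINES = {
    "BA": 0.25, "PLC": 0.30, "ILC": 0.28, "DH": 0.35,
    "VH": 0.33, "SB": 0.30, "LEC": 0.27, "MEC": 0.26,
}

#: Dispersion of the per-subject response gain (multiplies all of a
#: subject's planted increments).  CON-like subjects respond coherently;
#: LS-like responses are heterogeneous, so an appreciable minority of LS
#: subjects show no or negative task-associated change.
DEFAULT_GAIN_SD = {"CON": 0.3, "LS": 1.0}


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned per-slice box footprint for one region.

    For bilateral regions the box describes the left-hemisphere footprint;
    the right footprint is its mirror image about the grid midline.  For
    midline regions (PLC, ILC) the box itself straddles the midline.
    Ranges are half-open voxel index ranges.
    """

    code: str
    z_range: tuple[int, int]
    y_range: tuple[int, int]
    x_range: tuple[int, int]
    bilateral: bool = True


def default_region_specs(grid_shape=DEFAULT_GRID) -> list[RegionSpec]:
    """Region layout for the default desk-scale grid.

    Boxes occupy disjoint dorsoventral (y) bands so planted values never
    collide; BA spans 12 coronal slices, matching the slice count used for
    that region in the design this emulates.
    """
    if grid_shape != DEFAULT_GRID:
        raise ValueError(
            "default_region_specs covers the default grid only; supply "
            "region_specs explicitly for other grids"
        )
    return [
        RegionSpec("BA", (10, 22), (2, 7), (4, 9), bilateral=True),
        RegionSpec("PLC", (2, 8), (8, 13), (12, 20), bilateral=False),
        RegionSpec("ILC", (2, 8), (14, 19), (12, 20), bilateral=False),
        RegionSpec("DH", (12, 18), (20, 25), (4, 9), bilateral=True),
        RegionSpec("VH", (16, 22), (26, 31), (4, 9), bilateral=True),
        RegionSpec("SB", (20, 26), (32, 37), (4, 9), bilateral=True),
        RegionSpec("LEC", (22, 28), (38, 43), (4, 9), bilateral=True),
        RegionSpec("MEC", (24, 30), (44, 48), (4, 9), bilateral=True),
    ]


@dataclass(frozen=True)
class BoutParams:
    """Target freezing statistics for one group x session."""

    freezing_frac: float      # expected fraction of frames immobile, [0, 1]
    mean_bout_s: float        # mean immobility-run duration, seconds
    bout_shape: float = 2.0   # gamma shape of run durations (dispersion)


DEFAULT_BEHAVIOR = {
    "CON": {
        "F1": BoutParams(0.10, 2.5),
        "F2": BoutParams(0.3827, 4.0),
        "F3": BoutParams(0.7321, 8.0),
    },
    "LS": {
        "F1": BoutParams(0.10, 2.5),
        "F2": BoutParams(0.4022, 3.5),
        "F3": BoutParams(0.4537, 5.0),
    },
}

DEFAULT_SESSION_LENGTH_S = {"F1": 600.0, "F2": 660.0, "F3": 480.0}


@dataclass
class SynthConfig:
    """Full parameterization of a synthetic cohort."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_MM
    n_con: int = 9
    n_ls: int = 15
    region_specs: list[RegionSpec] = field(default_factory=default_region_specs)
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_EFFECTS.items()}
    )
    baseline_map: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    gain_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GAIN_SD))
    sd_subject: float = 0.012
    sd_hemisphere: float = 0.008
    sd_slice: float = 0.010
    sd_voxel: float = 0.050
    behavior_params: dict[str, dict[str, BoutParams]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_BEHAVIOR.items()}
    )
    frame_rate_hz: float = 15.0
    session_length_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SESSION_LENGTH_S)
    )
    seed: int = 0

    @property
    def midline_x(self) -> int:
        return self.grid_shape[0] // 2

    def validate(self) -> None:
        if self.n_con < 1:
            raise ValueError("n_con must be >= 1")
        if self.n_ls < 1:
            raise ValueError("n_ls must be >= 1")
        for name in ("sd_subject", "sd_hemisphere", "sd_slice", "sd_voxel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, sd in self.gain_sd.items():
            if sd < 0:
                raise ValueError(f"gain_sd[{g!r}] must be >= 0")
        nx, ny, nz = self.grid_shape
        for spec in self.region_specs:
            for (lo, hi), n, ax in (
                (spec.x_range, nx, "x"), (spec.y_range, ny, "y"), (spec.z_range, nz, "z"),
            ):
                if not (0 <= lo < hi <= n):
                    raise ValueError(
                        f"region_specs: {spec.code} {ax}_range {(lo, hi)} "
                        f"outside grid axis of size {n}"
                    )
            if spec.code not in self.baseline_map:
                raise ValueError(f"baseline_map missing region {spec.code!r}")
        for group in ("CON", "LS"):
            effects = self.effect_map.get(group, {})
            for spec in self.region_specs:
                if spec.code not in effects:
                    raise ValueError(
                        f"effect_map[{group!r}] missing region {spec.code!r}"
                    )
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        for sess, length in self.session_length_s.items():
            if length <= 0:
                raise ValueError(f"session_length_s[{sess!r}] must be > 0")


@dataclass
class GroundTruth:
    """Per-subject planted effects, recorded before noise is added."""

    planted_increment: dict[str, float]   # region -> realized recall increment
    planted_freezing: dict[str, float]    # session -> target freezing fraction
    response_gain: float = 1.0


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    scans: dict[str, ScanVolume]          # "F1", "F3"
    traces: dict[str, ActivityTrace]      # "F1", "F2", "F3"
    truth: GroundTruth


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    mask_set: RegionMaskSet
    brain_mask: np.ndarray
    config: SynthConfig

    @property
    def labels(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.subjects}


def build_mask_set(cfg: SynthConfig) -> RegionMaskSet:
    """Materialize the region footprints as 3D boolean masks."""
    nx = cfg.grid_shape[0]
    regions: dict[str, np.ndarray] = {}
    bilateral: dict[str, bool] = {}
    for spec in cfg.region_specs:
        mask = np.zeros(cfg.grid_shape, dtype=bool)
        x0, x1 = spec.x_range
        y0, y1 = spec.y_range
        z0, z1 = spec.z_range
        mask[x0:x1, y0:y1, z0:z1] = True
        if spec.bilateral:
            mask[nx - x1:nx - x0, y0:y1, z0:z1] = True
        regions[spec.code] = mask
        bilateral[spec.code] = spec.bilateral
    return RegionMaskSet(regions=regions, midline_x=cfg.midline_x, bilateral=bilateral)


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    """Deterministic per-(subject, stream) generator, independent of the
    order in which subjects are generated."""
    return np.random.default_rng(np.random.SeedSequence((seed, subject_index, stream)))


def _build_volume(
    cfg: SynthConfig,
    mask_set: RegionMaskSet,
    increments: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One raw volume: planted regional values over a background chosen so
    the whole-brain mean is exactly 1, plus nested Gaussian noise."""
    grid = np.zeros(cfg.grid_shape)
    covered = np.zeros(cfg.grid_shape, dtype=bool)
    region_total = 0.0
    for spec in cfg.region_specs:
        mask = mask_set.regions[spec.code]
        value = 1.0 + cfg.baseline_map[spec.code] + increments.get(spec.code, 0.0)
        grid[mask] = value
        covered |= mask
        region_total += value * int(mask.sum())
    n_total = grid.size
    region_voxels = int(covered.sum())
    background = (n_total - region_total) / (n_total - region_voxels)
    grid[~covered] = background

    if cfg.sd_subject > 0:
        grid += rng.normal(0.0, cfg.sd_subject)
    if cfg.sd_hemisphere > 0:
        h = rng.normal(0.0, cfg.sd_hemisphere, size=2)
        grid[: cfg.midline_x] += h[0]
        grid[cfg.midline_x:] += h[1]
    if cfg.sd_slice > 0:
        grid += rng.normal(0.0, cfg.sd_slice, size=cfg.grid_shape[2])[None, None, :]
    if cfg.sd_voxel > 0:
        grid += rng.normal(0.0, cfg.sd_voxel, size=cfg.grid_shape)
    return grid


def generate_activity_trace(
    params: BoutParams,
    frame_rate_hz: float,
    session_length_s: float,
    seed_or_rng,
) -> ActivityTrace:
    """Simulate a frame-wise activity trace with a target freezing fraction.

    Immobility and mobility run durations alternate as a stationary renewal
    process: run lengths are gamma distributed with the configured mean bout
    duration (immobility) and a mobility mean chosen so the long-run
    immobile fraction equals ``params.freezing_frac``; the initial state and
    residual first-run length are drawn from the equilibrium distribution,
    so the expected fraction of immobile frames equals the target exactly,
    without edge bias.  Immobile frames receive activity scores strictly
    below the package default threshold, mobile frames at or above it.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    if session_length_s <= 0:
        raise ValueError("session_length_s must be > 0")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n_frames = int(round(frame_rate_hz * session_length_s))
    times = np.arange(n_frames) / frame_rate_hz
    f = params.freezing_frac
    if f >= 1.0:
        inactive = np.ones(n_frames, dtype=bool)
    elif f <= 0.0:
        inactive = np.zeros(n_frames, dtype=bool)
    else:
        k = params.bout_shape
        theta_i = params.mean_bout_s / k
        theta_m = (params.mean_bout_s * (1.0 - f) / f) / k
        state = bool(rng.random() < f)  # True = immobile
        # equilibrium first run: uniform residual of a length-biased draw
        theta0 = theta_i if state else theta_m
        first = rng.random() * rng.gamma(k + 1.0, theta0)
        boundaries = [first]
        total = first
        s = state
        while total < session_length_s:
            s = not s
            run = rng.gamma(k, theta_i if s else theta_m)
            total += run
            boundaries.append(total)
        # state of the run containing each frame midpoint
        mids = times + 0.5 / frame_rate_hz
        run_idx = np.searchsorted(np.asarray(boundaries), mids, side="right")
        inactive = (run_idx % 2 == 0) == state

    scores = np.empty(n_frames)
    n_in = int(inactive.sum())
    scores[inactive] = rng.uniform(0.0, 0.5 * DEFAULT_THRESHOLD, size=n_in)
    scores[~inactive] = DEFAULT_THRESHOLD * (
        1.0 + rng.exponential(1.0, size=n_frames - n_in)
    )
    return ActivityTrace(times_s=times, scores=scores, frame_rate_hz=frame_rate_hz)


def generate_cohort(cfg: SynthConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from a configuration.

    Deterministic given ``cfg.seed``; per-subject random streams are derived
    by stable hashing of (seed, subject index, stream), so results do not
    depend on generation order.  F1 volumes carry baseline regional uptake
    plus noise; F3 volumes additionally carry the subject's realized planted
    increments (group-level increment times the subject's response gain).
    """
    cfg.validate()
    mask_set = build_mask_set(cfg)
    brain_mask = np.ones(cfg.grid_shape, dtype=bool)
    groups = [("CON", i) for i in range(cfg.n_con)] + [("LS", i) for i in range(cfg.n_ls)]
    subjects = []
    for subj_index, (group, within) in enumerate(groups):
        subject_id = f"{group}{within + 1:02d}"
        gain_sd = cfg.gain_sd.get(group, 0.0)
        gain = 1.0
        if gain_sd > 0:
            gain = float(_subject_rng(cfg.seed, subj_index, 5).normal(1.0, gain_sd))
        realized = {
            code: gain * cfg.effect_map[group][code]
            for code in (s.code for s in cfg.region_specs)
        }
        scans = {}
        for stream, session in ((0, "F1"), (1, "F3")):
            increments = realized if session == "F3" else {}
            vox = _build_volume(
                cfg, mask_set, increments, _subject_rng(cfg.seed, subj_index, stream)
            )
            scans[session] = ScanVolume(
                subject_id=subject_id,
                session=session,
                voxels=vox,
                voxel_size_mm=cfg.voxel_size_mm,
                normalized=False,
            )
        traces = {}
        for stream, session in ((2, "F1"), (3, "F2"), (4, "F3")):
            traces[session] = generate_activity_trace(
                cfg.behavior_params[group][session],
                cfg.frame_rate_hz,
                cfg.session_length_s[session],
                _subject_rng(cfg.seed, subj_index, stream),
            )
        truth = GroundTruth(
            planted_increment=realized,
            planted_freezing={
                sess: cfg.behavior_params[group][sess].freezing_frac
                for sess in ("F1", "F2", "F3")
            },
            response_gain=gain,
        )
        subjects.append(SyntheticSubject(subject_id, group, scans, traces, truth))
    return SyntheticCohort(subjects, mask_set, brain_mask, cfg)


def calibration_config(
    seed: int,
    effect_con: float = 0.15,
    effect_ls: float = 0.049,
    n_con: int = 9,
    n_ls: int = 15,
    **overrides,
) -> SynthConfig:
    """Reduced single-region configuration for repeated-simulation studies.

    Keeps the default noise levels and group sizes but shrinks the grid to
    16 x 24 x 16 voxels with one bilateral amygdala-like region (6 coronal
    slices), so that hundreds of cohorts can be simulated for calibration
    of the mixed-model test.  Planted BA increments default to the
    group-level values of the full design.
    """
    base = dict(
        grid_shape=(16, 24, 16),
        n_con=n_con,
        n_ls=n_ls,
        region_specs=[RegionSpec("BA", (4, 10), (2, 7), (2, 5), bilateral=True)],
        effect_map={"CON": {"BA": effect_con}, "LS": {"BA": effect_ls}},
        baseline_map={"BA": 0.25},
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


# ---------------------------------------------------------------------------
# fixture round-trip


def write_fixtures(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a cohort to disk and return (and save) the manifest.

    Layout: ``volumes/<subject>_<session>.nii`` (NIfTI-1 float32, RAS+),
    ``masks/regions.nii`` (label volume) + ``masks/regions.json`` (legend),
    ``masks/brain_mask.nii``, ``traces/<subject>_<session>.csv``,
    ``labels.csv``, ``ground_truth.json`` and ``manifest.json``.
    """
    from . import io as bio

    out = Path(out_dir)
    try:
        (out / "volumes").mkdir(parents=True, exist_ok=True)
        (out / "traces").mkdir(exist_ok=True)
        (out / "masks").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    manifest: dict = {
        "grid_shape": list(cohort.config.grid_shape),
        "voxel_size_mm": list(cohort.config.voxel_size_mm),
        "seed": cohort.config.seed,
        "frame_rate_hz": cohort.config.frame_rate_hz,
        "subjects": {},
    }
    truth_out = {}
    labels_rows = []
    for subj in cohort.subjects:
        entry = {"group": subj.group, "volumes": {}, "traces": {}}
        for session, scan in subj.scans.items():
            rel = f"volumes/{subj.subject_id}_{session}.nii"
            bio.write_volume(scan, out / rel)
            entry["volumes"][session] = rel
        for session, trace in subj.traces.items():
            rel = f"traces/{subj.subject_id}_{session}.csv"
            trace.to_csv(out / rel)
            entry["traces"][session] = rel
        manifest["subjects"][subj.subject_id] = entry
        labels_rows.append((subj.subject_id, subj.group))
        truth_out[subj.subject_id] = {
            "planted_increment": subj.truth.planted_increment,
            "planted_freezing": subj.truth.planted_freezing,
            "response_gain": subj.truth.response_gain,
        }
    bio.write_mask_set(cohort.mask_set, out / "masks" / "regions.nii")
    bio.write_brain_mask(cohort.brain_mask, cohort.config.voxel_size_mm,
                         out / "masks" / "brain_mask.nii")
    manifest["masks"] = "masks/regions.nii"
    manifest["brain_mask"] = "masks/brain_mask.nii"
    pd.DataFrame(labels_rows, columns=["subject", "group"]).to_csv(
        out / "labels.csv", index=False
    )
    manifest["labels"] = "labels.csv"
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_out, fh, indent=1)
    manifest["ground_truth"] = "ground_truth.json"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def validate_manifest(fixture_dir) -> dict:
    """Check that every file the manifest lists exists; return the manifest.

    Raises ``FileNotFoundError`` naming the subject/session of the first
    missing volume or trace.
    """
    root = Path(fixture_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    for key in ("masks", "brain_mask", "labels", "ground_truth"):
        if not (root / manifest[key]).exists():
            raise FileNotFoundError(f"manifest entry {key!r} missing: {manifest[key]}")
    for subject_id, entry in manifest["subjects"].items():
        for kind in ("volumes", "traces"):
            for session, rel in entry[kind].items():
                if not (root / rel).exists():
                    raise FileNotFoundError(
                        f"missing {kind[:-1]} for subject {subject_id} "
                        f"session {session}: {rel}"
                    )
    return manifest


def read_fixtures(fixture_dir) -> SyntheticCohort:
    """Reconstruct a cohort from fixtures written by :func:`write_fixtures`.

    Volumes come back at float32 storage precision; the configuration is a
    minimal stand-in carrying grid geometry and seed only.
    """
    from . import io as bio

    root = Path(fixture_dir)
    manifest = validate_manifest(root)
    mask_set = bio.read_mask_set(root / manifest["masks"])
    brain_mask = bio.read_brain_mask(root / manifest["brain_mask"])
    with open(root / manifest["ground_truth"]) as fh:
        truth_in = json.load(fh)
    subjects = []
    for subject_id, entry in manifest["subjects"].items():
        scans = {
            session: bio.read_volume(root / rel, subject_id=subject_id, session=session)
            for session, rel in entry["volumes"].items()
        }
        traces = {
            session: ActivityTrace.from_csv(root / rel, manifest["frame_rate_hz"])
            for session, rel in entry["traces"].items()
        }
        t = truth_in[subject_id]
        truth = GroundTruth(
            planted_increment=t["planted_increment"],
            planted_freezing=t["planted_freezing"],
            response_gain=t.get("response_gain", 1.0),
        )
        subjects.append(
            SyntheticSubject(subject_id, entry["group"], scans, traces, truth)
        )
    cfg = SynthConfig(
        grid_shape=tuple(manifest["grid_shape"]),
        voxel_size_mm=tuple(manifest["voxel_size_mm"]),
        n_con=sum(1 for s in subjects if s.group == "CON"),
        n_ls=sum(1 for s in subjects if s.group == "LS"),
        region_specs=default_region_specs()
        if tuple(manifest["grid_shape"]) == DEFAULT_GRID
        else [],
        seed=manifest["seed"],
        frame_rate_hz=manifest["frame_rate_hz"],
    )
    return SyntheticCohort(subjects, mask_set, brain_mask, cfg)
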