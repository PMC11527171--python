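"""Ordinal-trends canonical variates analysis of paired scans.

Given each subject's baseline (F1) and recall (F3) normalized volumes, the
analysis looks for a voxel-weight covariance pattern whose per-scan
expression increases from F1 to F3 in as many subjects as possible:

1.  Stack the scans into a matrix (rows = scans, subject-major with F1
    before F3; columns = in-brain-mask voxels) and grand-mean center the
    columns.
2.  Decompose by SVD into principal components (voxel-weight vectors) and
    per-scan expression scores.
3.  Select the component subset best fitting the condition design
    (F1 = -1, F3 = +1) by ordinary least squares, scoring each singleton
    {PCk} and each prefix {PC1..PCk} with ``AIC = n ln(RSS/n) + 2(k+1)``
    and keeping the lowest (ties favor the smaller set).  The selected
    components are combined with their regression weights into a single
    unit-norm pattern whose sign is fixed so that the majority of subjects
    increase from F1 to F3.
4.  Test the ordinal trend by permutation: each subject's condition pair is
    flipped with probability 1/2 and the full selection pipeline re-run;
    the p value is the add-one fraction of permutations whose count of
    increasing subjects reaches the observed count.
5.  Assess voxel-weight reliability by bootstrap over subjects (keeping
    F1/F3 pairs together): ``z = original weight / bootstrap SD``, with
    one-tailed significance in the direction of the original weight sign.

A subject's "nodal expression" is a scan's projection onto the pattern,
z-scored across the evaluation set; its F1-to-F3 change is the per-subject
trend readout that can be compared between groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import ScanVolume
from .stats import TTestResult, t_test

logger = logging.getLogger(__name__)

CONDITIONS = ("F1", "F3")
ONE_TAILED_Z = 1.6448536269514722  # standard normal 95th percentile


@dataclass
class OrtMatrix:
    """Scans-by-voxels data matrix with row and column provenance."""

    data: np.ndarray                  # (2 * n_subjects, n_voxels)
    row_meta: pd.DataFrame            # columns: subject, condition
    voxel_index: np.ndarray           # (n_voxels, 3) int voxel coordinates
    grid_shape: tuple[int, int, int]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.row_meta["subject"]))

    @property
    def design(self) -> np.ndarray:
        """Condition codes per row: F1 -> -1, F3 -> +1."""
        return np.where(self.row_meta["condition"].to_numpy() == "F3", 1.0, -1.0)

    def coords_to_columns(self, coords: np.ndarray) -> np.ndarray:
        """Inverse of ``voxel_index``: (x,y,z) rows -> column indices."""
        flat = np.ravel_multi_index(self.voxel_index.T, self.grid_shape)
        lookup = {int(v): i for i, v in enumerate(flat)}
        want = np.ravel_multi_index(np.asarray(coords).T, self.grid_shape)
        return np.array([lookup[int(v)] for v in want])


@dataclass
class PcSet:
    """SVD of the grand-mean-centered scan matrix."""

    components: np.ndarray            # (rank, n_voxels), orthonormal rows
    expressions: np.ndarray           # (n_rows, rank) = centered data @ components.T
    singular_values: np.ndarray
    explained_variance: np.ndarray    # fractions summing to 1
    column_mean: np.ndarray


@dataclass
class Pattern:
    """AIC-selected, sign-fixed combination of principal components."""

    selected_pc_indices: list[int]    # 0-based component indices
    weights: np.ndarray               # unit-norm voxel weights
    aic_trace: dict[str, float]       # candidate set label -> AIC
    sign_flipped: bool
    coef: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class OrtResult:
    pattern: Pattern
    expressions: pd.DataFrame          # subject, condition, expression (z-scored)
    n_increasing: int
    n_subjects: int
    perm_p: float
    boot_z: np.ndarray | None
    sig_mask: np.ndarray | None
    seeds: dict[str, int]
    metadata: dict


def build_ort_matrix(scans: list[ScanVolume], brain_mask: np.ndarray) -> OrtMatrix:
    """Flatten paired normalized scans into a rows-by-voxels matrix.

    Rows are subject-major, each subject's F1 row directly before its F3
    row; columns are in-mask voxels in fixed C order.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    by_subject: dict[str, dict[str, ScanVolume]] = {}
    for scan in scans:
        by_subject.setdefault(scan.subject_id, {})[scan.session] = scan
    for sid, sessions in by_subject.items():
        missing = [c for c in CONDITIONS if c not in sessions]
        if missing:
            raise ValueError(f"subject {sid} missing condition(s): {missing}")
    coords = np.argwhere(brain_mask)
    rows, meta = [], []
    for sid in by_subject:
        for cond in CONDITIONS:
            vol = by_subject[sid][cond]
            if vol.voxels.shape != brain_mask.shape:
                raise ValueError(f"scan {sid}/{cond} grid does not match brain mask")
            rows.append(vol.voxels[brain_mask])
            meta.append((sid, cond))
    return OrtMatrix(
        data=np.asarray(rows),
        row_meta=pd.DataFrame(meta, columns=["subject", "condition"]),
        voxel_index=coords,
        grid_shape=brain_mask.shape,
    )


def pca_decompose(data: np.ndarray) -> PcSet:
    """Grand-mean (column-wise) centering followed by economy SVD."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    mean = data.mean(axis=0)
    centered = data - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("matrix is constant: rank 0 after centering")
    s = s[:rank]
    Vt = Vt[:rank]
    U = U[:, :rank]
    return PcSet(
        components=Vt,
        expressions=U * s,
        singular_values=s,
        explained_variance=s**2 / np.sum(s**2),
        column_mean=mean,
    )


RSS_FLOOR = np.finfo(float).eps


def default_k_max(n_rows: int, rank: int) -> int:
    """Largest candidate-set size considered by AIC selection.

    Capped at roughly one predictor per six scans: with an intercept plus
    k expression scores fit to only ``n_rows`` condition codes, larger
    candidate sets overfit any design, collapsing the residual sum of
    squares and defeating both the AIC comparison and the permutation
    null.  Pass ``k_max`` explicitly to override.
    """
    return min(8, rank, max(2, n_rows // 6))


def _candidate_sets(rank: int, k_max: int) -> list[tuple[int, ...]]:
    k_max = min(k_max, rank)
    singles = [(k,) for k in range(k_max)]
    prefixes = [tuple(range(k + 1)) for k in range(1, k_max)]
    return singles + prefixes


def select_pattern_aic(
    pcs: PcSet, design: np.ndarray, k_max: int | None = None
) -> Pattern:
    """Select the PC subset best matching the condition design by AIC.

    Candidates are every singleton {PCk} and every prefix {PC1..PCk} for
    k <= k_max.  Each candidate is scored by OLS of the design (+/-1 per
    scan) on its expression scores (with intercept):
    ``AIC = n ln(RSS/n) + 2(k+1)``; lowest wins, ties favoring the smaller
    then earlier set.  Combined voxel weights are the regression-weighted
    sum of the selected components, renormalized to unit norm, with sign
    fixed so that the majority of subjects increase from F1 to F3.
    """
    design = np.asarray(design, dtype=float)
    n = design.size
    if k_max is None:
        k_max = default_k_max(n, pcs.components.shape[0])
    E = pcs.expressions
    best_key = None
    best_aic = np.inf
    trace: dict[str, float] = {}
    coefs: dict[tuple[int, ...], np.ndarray] = {}
    for cand in _candidate_sets(pcs.components.shape[0], k_max):
        Xd = np.column_stack([np.ones(n), E[:, list(cand)]])
        beta, *_ = np.linalg.lstsq(Xd, design, rcond=None)
        resid = design - Xd @ beta
        rss = float(resid @ resid)
        if rss < RSS_FLOOR:
            logger.warning("RSS underflow for candidate %s; floored", cand)
            rss = RSS_FLOOR
        k = len(cand)
        aic = n * np.log(rss / n) + 2.0 * (k + 1)
        label = "+".join(f"PC{c + 1}" for c in cand)
        trace[label] = float(aic)
        coefs[cand] = beta[1:]
        if aic < best_aic - 1e-12 or (
            abs(aic - best_aic) <= 1e-12
            and best_key is not None
            and len(cand) < len(best_key)
        ):
            best_aic = aic
            best_key = cand
    coef = coefs[best_key]
    weights = coef @ pcs.components[list(best_key)]
    norm = np.linalg.norm(weights)
    if norm == 0:
        weights = pcs.components[best_key[0]].copy()
        norm = 1.0
    weights = weights / norm
    # sign convention: majority of subjects increase F1 -> F3
    expr = E[:, list(best_key)] @ (coef / norm)
    deltas = _pair_deltas(expr, design)
    flipped = bool(np.sum(deltas > 0) < deltas.size / 2.0)
    if flipped:
        weights = -weights
        coef = -coef
    return Pattern(
        selected_pc_indices=list(best_key),
        weights=weights,
        aic_trace=trace,
        sign_flipped=flipped,
        coef=coef / norm,
    )


def _pair_deltas(expr: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-subject expression change: (+1)-condition row minus (-1) row.

    Rows are subject-major pairs: rows 2i and 2i+1 belong to subject i.
    """
    expr = expr.reshape(-1, 2)
    sign = design.reshape(-1, 2)[:, 1]  # +1 if second row is the +1 condition
    return (expr[:, 1] - expr[:, 0]) * sign


def _n_increasing(pcs: PcSet, design: np.ndarray, k_max: int | None) -> int:
    pattern = select_pattern_aic(pcs, design, k_max)
    expr = pcs.expressions[:, pattern.selected_pc_indices] @ pattern.coef
    return int(np.sum(_pair_deltas(expr, design) > 0))


def ordinal_trend_permutation(
    matrix: OrtMatrix,
    n_perm: int = 500,
    seed: int = 0,
    k_max: int | None = None,
    mode: str = "full",
) -> tuple[int, float, Pattern]:
    """Permutation test of the ordinal trend.

    The observed statistic is the number of subjects whose pattern
    expression increases from F1 to F3 under the full pipeline (PCA ->
    AIC selection -> sign fix).  Each permutation independently flips each
    subject's condition pair with probability 1/2 and re-runs the pipeline
    (``mode="full"``) or only re-scores the fixed observed pattern
    (``mode="fixed_pattern"``).  ``perm_p = (1 + #{perm >= obs}) / (1 + n_perm)``.

    Swapping a subject's two rows leaves the column means and the SVD
    component vectors unchanged (the matrix holds the same rows), so the
    full-pipeline re-run is computed exactly by flipping that subject's
    design codes against the fixed decomposition.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("full", "fixed_pattern"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(seed)
    pcs = pca_decompose(matrix.data)
    design = matrix.design
    n_subj = design.size // 2
    pattern = select_pattern_aic(pcs, design, k_max)
    expr_obs = pcs.expressions[:, pattern.selected_pc_indices] @ pattern.coef
    observed = int(np.sum(_pair_deltas(expr_obs, design) > 0))
    count = 0
    for _ in range(n_perm):
        flips = rng.random(n_subj) < 0.5
        sign = np.where(np.repeat(flips, 2), -1.0, 1.0)
        d_perm = design * sign
        if mode == "full":
            stat = _n_increasing(pcs, d_perm, k_max)
        else:
            stat = int(np.sum(_pair_deltas(expr_obs, d_perm) > 0))
            # fixed pattern keeps the observed sign; enforce the majority
            # convention on the permuted design
            stat = max(stat, n_subj - stat)
        if stat >= observed:
            count += 1
    perm_p = (1.0 + count) / (1.0 + n_perm)
    return observed, float(perm_p), pattern


def bootstrap_voxel_weights(
    matrix: OrtMatrix,
    pattern: Pattern,
    n_boot: int = 500,
    seed: int = 0,
    k_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap reliability z map for the pattern's voxel weights.

    Each iteration resamples subjects with replacement (keeping each
    subject's F1/F3 pair together), re-runs PCA and AIC selection, and
    sign-aligns the resampled pattern to the original (the sign maximizing
    their correlation).  ``z_v = original weight_v / bootstrap SD_v``; a
    voxel is significant when z exceeds the one-tailed 5% normal quantile
    in the direction of the original weight's sign, i.e.
    ``|w_v| / SD_v > 1.645``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n_subj = matrix.data.shape[0] // 2
    design_pair = matrix.design.reshape(n_subj, 2)
    data_pair = matrix.data.reshape(n_subj, 2, -1)
    boot_weights = np.empty((n_boot, matrix.data.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        data_b = data_pair[idx].reshape(2 * n_subj, -1)
        design_b = design_pair[idx].reshape(-1)
        try:
            pcs_b = pca_decompose(data_b)
        except ValueError:
            boot_weights[b] = 0.0
            continue
        pat_b = select_pattern_aic(pcs_b, design_b, k_max)
        w = pat_b.weights
        if np.dot(w, pattern.weights) < 0:
            w = -w
        boot_weights[b] = w
    sd = boot_weights.std(axis=0, ddof=1)
    floored = sd < 1e-12
    if floored.any():
        logger.warning("bootstrap SD floored at 1e-12 for %d voxels", int(floored.sum()))
        sd = np.where(floored, 1e-12, sd)
    boot_z = pattern.weights / sd
    sig_mask = np.abs(boot_z) > ONE_TAILED_Z
    return boot_z, sig_mask


def expression_change(
    pattern: Pattern,
    matrix: OrtMatrix,
    labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Nodal expression change per subject, plus a group summary.

    Expression per scan is the in-mask dot product with the pattern
    weights, z-scored across all scans in the evaluation set; the
    per-subject change is E(F3) - E(F1).  When two groups are present the
    summary includes each group's fraction of increasing subjects and a
    pooled two-sample t test of the change.
    """
    if matrix.data.shape[1] != pattern.weights.size:
        raise ValueError("matrix voxel index does not match pattern weights")
    raw = matrix.data @ pattern.weights
    z = (raw - raw.mean()) / raw.std(ddof=0)
    expr = matrix.row_meta.copy()
    expr["expression"] = z
    wide = expr.pivot(index="subject", columns="condition", values="expression")
    delta = (wide["F3"] - wide["F1"]).rename("delta_expression").reset_index()
    if labels is not None:
        delta["group"] = delta["subject"].map(labels)
    summary: dict = {
        "fraction_increasing": float(np.mean(delta["delta_expression"] > 0)),
        "n_subjects": int(len(delta)),
    }
    if labels is not None:
        by_group = {}
        for g, sub in delta.groupby("group"):
            by_group[g] = {
                "fraction_increasing": float(np.mean(sub["delta_expression"] > 0)),
                "mean_delta_expression": float(sub["delta_expression"].mean()),
                "n": int(len(sub)),
            }
        summary["groups"] = by_group
        groups = sorted(by_group)
        if len(groups) == 2:
            a = delta.loc[delta["group"] == groups[0], "delta_expression"]
            b = delta.loc[delta["group"] == groups[1], "delta_expression"]
            if len(a) >= 2 and len(b) >= 2:
                tt: TTestResult = t_test(a, b)
                summary["t_test"] = {
                    "groups": groups, "T": tt.T_stat, "p": tt.p_value, "df": tt.df,
                }
    return delta, summary


def run_ort(
    scans: list[ScanVolume],
    brain_mask: np.ndarray,
    n_perm: int = 500,
    n_boot: int = 500,
    seed: int = 0,
    k_max: int | None = None,
    eval_scans: list[ScanVolume] | None = None,
    labels: dict[str, str] | None = None,
) -> OrtResult:
    """End-to-end ordinal-trends analysis on one reference group.

    The pattern is derived (and tested) on ``scans``; expressions are
    evaluated on ``eval_scans`` (default: the same scans), which may
    include other groups.
    """
    matrix = build_ort_matrix(scans, brain_mask)
    observed, perm_p, pattern = ordinal_trend_permutation(
        matrix, n_perm=n_perm, seed=seed, k_max=k_max
    )
    boot_z, sig_mask = bootstrap_voxel_weights(
        matrix, pattern, n_boot=n_boot, seed=seed + 1, k_max=k_max
    )
    eval_matrix = (
        build_ort_matrix(eval_scans, brain_mask) if eval_scans is not None else matrix
    )
    expressions, summary = expression_change(pattern, eval_matrix, labels=labels)
    return OrtResult(
        pattern=pattern,
        expressions=expressions,
        n_increasing=observed,
        n_subjects=matrix.data.shape[0] // 2,
        perm_p=perm_p,
        boot_z=boot_z,
        sig_mask=sig_mask,
        seeds={"permutation": seed, "bootstrap": seed + 1},
        metadata={
            "n_perm": n_perm,
            "n_boot": n_boot,
            "k_max": k_max if k_max is not None
            else default_k_max(matrix.data.shape[0], min(matrix.data.shape) - 1),
            "selected_pcs": [i + 1 for i in pattern.selected_pc_indices],
            "centering": "grand_mean_columns",
            "candidates": "singletons_and_prefixes",
            "aic": "n*ln(RSS/n) + 2(k+1)",
            "trend_statistic": "count_of_increasing_subjects",
            "permutation": "within_subject_condition_flip",
            "bootstrap": "subject_pairs_resampling",
            "expression_summary": summary,
        },
    )
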