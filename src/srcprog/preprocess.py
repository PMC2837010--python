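"""Array normalization and probe-set summarization.

Implements the dChip-style pipeline: per-array median scaling to a common
target, rank-based invariant-set selection against a baseline array, a running-
median monotone normalization curve, and the PM-only model-based expression
index (MBEI), i.e. the rank-1 factorization PM(i, j) = phi(i) * theta(j) + eps
fitted by alternating least squares under mean(phi) = 1, with one 3-sd outlier
pass. The cited method publications do not fix the iteration thresholds; the
defaults here (rank_threshold 0.005, 30 iterations, 10% running-median window)
are declared substitutes, configurable throughout.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DifferentialResult, ExpressionMatrix, ProbeAnnotation, ProbeLevelMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "scale_to_common_median",
    "select_invariant_probes",
    "normalize_to_baseline",
    "choose_baseline_array",
    "normalize_experiment",
    "compute_mbei",
    "collapse_to_genes",
]


def scale_to_common_median(
    matrices: list[ProbeLevelMatrix], target_median: float | str = "auto"
) -> list[ProbeLevelMatrix]:
    """Rescale every array multiplicatively so its median intensity hits the target.

    ``target_median="auto"`` uses the mean of all input array medians. Within-
    array intensity ratios are unchanged.
    """
    if not matrices:
        raise ValueError("no matrices given")
    medians = []
    for m in matrices:
        med = m.intensities.median(axis=0)
        if (med <= 0).any():
            bad = list(med.index[med <= 0])
            raise ValueError(f"arrays with nonpositive median intensity: {bad}")
        medians.append(med)
    if target_median == "auto":
        target = float(np.mean(np.concatenate([m.to_numpy() for m in medians])))
    else:
        target = float(target_median)
        if target <= 0:
            raise ValueError("target_median must be positive")
    out = []
    for m, med in zip(matrices, medians):
        out.append(ProbeLevelMatrix(m.intensities * (target / med), m.samples.copy(), m.name))
    return out


def select_invariant_probes(
    target_array: np.ndarray,
    baseline_array: np.ndarray,
    rank_threshold: float = 0.005,
    max_iter: int = 30,
) -> np.ndarray:
    """Iteratively select probes whose ranks are stable between two arrays.

    At each pass, ranks are recomputed within the currently retained set and
    probes with normalized rank difference |r_t - r_b| / N_current below the
    threshold are kept; iteration stops when the set shrinks by < 1% or after
    max_iter passes. If a pass empties the set, the N/10 probes with the
    smallest full-array rank differences are returned instead.
    """
    t = np.asarray(target_array, dtype=float)
    b = np.asarray(baseline_array, dtype=float)
    if t.shape != b.shape:
        raise ValueError("target and baseline arrays must have the same length")
    n = t.size
    if n < 10:
        raise ValueError("need at least 10 probes")

    full_diff = np.abs(rankdata(t) - rankdata(b)) / n
    current = np.arange(n)
    for _ in range(max_iter):
        rt = rankdata(t[current])
        rb = rankdata(b[current])
        diff = np.abs(rt - rb) / current.size
        keep = diff < rank_threshold
        if not keep.any():
            k = max(1, n // 10)
            return np.sort(np.argsort(full_diff, kind="stable")[:k])
        new = current[keep]
        shrunk = (current.size - new.size) / current.size
        current = new
        if shrunk < 0.01:
            break
    return current


def _monotone_curve(x: np.ndarray, y: np.ndarray, window_frac: float = 0.10):
    """Running-median normalization curve (x -> y), forced monotone."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    w = max(3, int(round(window_frac * xs.size)))
    xr = pd.Series(xs).rolling(w, center=True, min_periods=1).median().to_numpy()
    yr = pd.Series(ys).rolling(w, center=True, min_periods=1).median().to_numpy()
    xr = np.maximum.accumulate(xr)
    yr = np.maximum.accumulate(yr)
    # collapse duplicate x knots, keeping the mean y at each knot
    knots = pd.DataFrame({"x": xr, "y": yr}).groupby("x", sort=True)["y"].mean()
    return knots.index.to_numpy(), knots.to_numpy()


def normalize_to_baseline(
    target_array: np.ndarray,
    baseline_array: np.ndarray,
    invariant_set: np.ndarray,
    window_frac: float = 0.10,
) -> np.ndarray:
    """Map target intensities through a monotone curve fitted on invariant probes.

    The curve is a running median of (target, baseline) pairs over the invariant
    set with piecewise-linear interpolation and linear extrapolation at the
    tails; within-array rank order is preserved. Fewer than 10 invariant probes
    triggers a median-ratio fallback with a warning.
    """
    t = np.asarray(target_array, dtype=float)
    b = np.asarray(baseline_array, dtype=float)
    inv = np.asarray(invariant_set, dtype=int)
    if inv.size == 0:
        raise ValueError("invariant set is empty")
    if inv.size < 10:
        logger.warning("invariant set has %d probes; falling back to median-ratio scaling", inv.size)
        return t * (np.median(b) / np.median(t))

    xk, yk = _monotone_curve(t[inv], b[inv], window_frac)
    out = np.interp(t, xk, yk)
    if xk.size >= 2:
        lo_slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        hi_slope = (yk[-1] - yk[-2]) / (xk[-1] - xk[-2])
        if lo_slope <= 0:
            lo_slope = yk[0] / xk[0] if xk[0] > 0 else 1.0
        if hi_slope <= 0:
            hi_slope = yk[-1] / xk[-1] if xk[-1] > 0 else 1.0
        below = t < xk[0]
        above = t > xk[-1]
        out[below] = yk[0] + (t[below] - xk[0]) * lo_slope
        out[above] = yk[-1] + (t[above] - xk[-1]) * hi_slope
    return np.clip(out, 0.0, None)


def choose_baseline_array(plm: ProbeLevelMatrix) -> str:
    """The array whose median intensity is the median of the per-array medians."""
    medians = plm.intensities.median(axis=0).sort_values(kind="stable")
    return str(medians.index[(len(medians) - 1) // 2])


def normalize_experiment(
    plm: ProbeLevelMatrix,
    rank_threshold: float = 0.005,
    max_iter: int = 30,
    baseline: str | None = None,
) -> ProbeLevelMatrix:
    """Invariant-set normalize every array of one experimental group to its baseline."""
    baseline = baseline or choose_baseline_array(plm)
    b = plm.intensities[baseline].to_numpy()
    out = plm.intensities.copy()
    for col in plm.array_ids:
        if col == baseline:
            continue
        t = plm.intensities[col].to_numpy()
        inv = select_invariant_probes(t, b, rank_threshold=rank_threshold, max_iter=max_iter)
        out[col] = normalize_to_baseline(t, b, inv)
    return ProbeLevelMatrix(out, plm.samples.copy(), plm.name)


def _als_fit(x: np.ndarray, mask: np.ndarray, n_iter: int = 60, tol: float = 1e-10):
    """Masked rank-1 alternating least squares on a (sets, probes, arrays) tensor.

    Returns (phi, theta) with mean(phi) = 1 per probe set.
    """
    xm = x * mask
    phi = np.ones(x.shape[:2])
    theta = xm.sum(axis=1) / np.maximum(mask.sum(axis=1), 1.0)
    for _ in range(n_iter):
        prev = theta
        denom = np.einsum("spj,sp->sj", mask, phi**2)
        theta = np.einsum("spj,sp->sj", xm, phi) / np.where(denom > 0, denom, 1.0)
        denom = np.einsum("spj,sj->sp", mask, theta**2)
        phi = np.einsum("spj,sj->sp", xm, theta) / np.where(denom > 0, denom, 1.0)
        scale = phi.mean(axis=1, keepdims=True)
        scale = np.where(np.abs(scale) > 1e-12, scale, 1.0)
        phi = phi / scale
        theta = theta * scale[:, 0][:, None]
        num = np.abs(theta - prev).max(axis=1)
        den = np.maximum(np.abs(prev).max(axis=1), 1e-12)
        if (num / den).max() < tol:
            break
    return phi, theta


def compute_mbei(
    probe_matrix: ProbeLevelMatrix, outlier_sd: float = 3.0, floor_scale: float = 1e-6
) -> ExpressionMatrix:
    """Model-based expression index from perfect-match probes only.

    Per probe set, fits PM(i, j) = phi(i) * theta(j) + eps by alternating least
    squares under the identifiability constraint mean(phi) = 1, masks residuals
    beyond ``outlier_sd`` standard deviations in one pass and refits, and
    reports theta(j) as the expression value. Values are floored at
    ``floor_scale`` times the median theta; single-probe sets pass through.
    """
    df = probe_matrix.intensities
    if df.shape[1] < 2:
        raise ValueError("need at least two arrays")
    sizes = df.groupby(level=0, sort=False).size()
    arrays = list(df.columns)
    pieces = []
    for size, ids in sizes.groupby(sizes).groups.items():
        probesets = list(ids)
        sub = df.loc[probesets]
        x = sub.to_numpy().reshape(len(probesets), int(size), len(arrays))
        if size == 1:
            theta = x[:, 0, :]
        else:
            mask = np.ones_like(x)
            phi, theta = _als_fit(x, mask)
            resid = x - phi[:, :, None] * theta[:, None, :]
            sd = resid.std(axis=(1, 2), keepdims=True)
            mask = (np.abs(resid) <= outlier_sd * np.maximum(sd, 1e-300)).astype(float)
            # never mask out a full array column within a set
            empty_cols = mask.sum(axis=1) == 0
            if empty_cols.any():
                s, j = np.where(empty_cols)
                mask[s, :, j] = 1.0
            if (mask < 1).any():
                phi, theta = _als_fit(x, mask, n_iter=30)
        pieces.append(pd.DataFrame(theta, index=probesets, columns=arrays))
    values = pd.concat(pieces).loc[sizes.index]

    med = float(np.median(values.to_numpy()[values.to_numpy() > 0])) if (values.to_numpy() > 0).any() else 1.0
    floor = floor_scale * med
    n_floored = int((values.to_numpy() < floor).sum())
    if n_floored:
        logger.warning("floored %d expression values at %.3g", n_floored, floor)
    values = values.clip(lower=floor)
    values.index.name = "feature_id"
    return ExpressionMatrix(values, probe_matrix.samples.copy(), name=probe_matrix.name)


def _retained_by_min_p(result: DifferentialResult, annotation: ProbeAnnotation) -> pd.Series:
    """gene_id -> retained probeset_id (smallest p, ties by lexicographic id)."""
    tab = result.table.copy()
    tab.index = tab.index.rename(None)  # avoid clash with the probeset_id column
    tab["gene_id"] = annotation.table.loc[tab.index, "gene_id"].to_numpy()
    tab = tab.sort_values(["gene_id", "p_value"], kind="stable")
    tab["probeset_id"] = tab.index
    tab = tab.sort_values(["gene_id", "p_value", "probeset_id"], kind="stable")
    first = tab.groupby("gene_id", sort=True).head(1)
    return pd.Series(first["probeset_id"].to_numpy(), index=first["gene_id"].to_numpy())


def _check_annotated(features, annotation: ProbeAnnotation) -> None:
    missing = [f for f in features if f not in annotation.table.index]
    if missing:
        raise KeyError(f"unannotated features: {missing[:10]}{'...' if len(missing) > 10 else ''}")


def collapse_to_genes(
    obj: DifferentialResult | ExpressionMatrix,
    annotation: ProbeAnnotation,
    retained: pd.Series | None = None,
):
    """Collapse redundant probe sets to unique gene IDs.

    For a DifferentialResult, the probe set with the smallest p-value per gene
    is retained (ties broken by lexicographic probeset_id). For an
    ExpressionMatrix, ``retained`` (gene_id -> probeset_id, e.g. from a prior
    differential collapse) selects the row; without it the probe set with the
    highest mean intensity is kept.
    """
    if isinstance(obj, DifferentialResult):
        _check_annotated(obj.table.index, annotation)
        keep = _retained_by_min_p(obj, annotation)
        table = obj.table.loc[keep.to_numpy()].copy()
        table.index = pd.Index(keep.index, name="gene_id")
        table["probeset_id"] = keep.to_numpy()
        return DifferentialResult(table.sort_index(), obj.test_kind, obj.comparison)

    if isinstance(obj, ExpressionMatrix):
        _check_annotated(obj.values.index, annotation)
        if retained is None:
            means = obj.values.mean(axis=1)
            tab = pd.DataFrame(
                {
                    "gene_id": annotation.table.loc[obj.values.index, "gene_id"].to_numpy(),
                    "mean": means.to_numpy(),
                    "probeset_id": obj.values.index,
                }
            ).sort_values(["gene_id", "mean", "probeset_id"], ascending=[True, False, True], kind="stable")
            first = tab.groupby("gene_id", sort=True).head(1)
            retained = pd.Series(first["probeset_id"].to_numpy(), index=first["gene_id"].to_numpy())
        values = obj.values.loc[retained.to_numpy()].copy()
        values.index = pd.Index(retained.index, name="gene_id")
        return ExpressionMatrix(values.sort_index(), obj.samples.copy(), name=obj.name)

    raise TypeError(f"cannot collapse object of type {type(obj).__name__}")
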