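"""Shared-misregistration inference.

Centers electrode tips, regresses tip displacement on signed registration
errors axis-by-axis, runs per-landmark and stacked PCA of the error vectors,
builds pairwise r-squared matrices in Cartesian or principal-component
bases, and attributes tip-position variance along its leading principal
axis to the leading shared registration-error component.

Tip tables are plain DataFrames with columns ``subject``, ``side``,
``x_mm``, ``y_mm``, ``z_mm``. Registration-error inputs are the tables
produced by :mod:`afidreg.metrics` (kind ``AFRE``), with one row per
subject and landmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import DegenerateStatisticsError, InputError
from .metrics import compare_unpaired, validate_error_table

__all__ = [
    "RegressionFit",
    "PrincipalAxes",
    "AttributionResult",
    "center_targets",
    "simple_regression",
    "r2_map",
    "covariate_screen",
    "multivariate_regression",
    "pca",
    "afre_pivot",
    "afre_correlation_matrix",
    "stacked_pca",
    "attribute_variance",
]

_AXIS_COLS = {"x": ("x_mm", "dx_mm"), "y": ("y_mm", "dy_mm"), "z": ("z_mm", "dz_mm")}
TIP_COLUMNS = ["subject", "side", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PrincipalAxes:
    """Result of a covariance-based PCA.

    ``components`` holds unit eigenvectors as columns (features x k),
    sorted by descending eigenvalue and sign-fixed so each component's
    largest-magnitude loading is positive. ``explained_fraction`` is
    eigenvalue over total variance (trace). ``scores`` are the centered
    data projected on the components (samples x k).
    """

    components: np.ndarray
    explained_fraction: np.ndarray
    scores: np.ndarray
    feature_labels: tuple[str, ...]
    column_means: np.ndarray
    sample_ids: tuple[Hashable, ...]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass(frozen=True)
class AttributionResult:
    """Variance attribution of tip position to shared registration error."""

    r2_matrix: pd.DataFrame  # AFRE PrCs (rows) x tip PrCs (columns)
    p_matrix: pd.DataFrame
    explained_mm: pd.Series  # |fitted tip-PrC1 value| per electrode, mm
    summary: dict


def center_targets(
    tips: pd.DataFrame, grouping: str = "per_side"
) -> pd.DataFrame:
    """Subtract the mean tip coordinate within each grouping cell.

    ``per_side`` centers within each ``side``; the alternative
    ``pooled_after_per_side_centering`` applies the identical per-side
    centering and marks the result for pooled downstream use. Output adds
    ``dx_mm``/``dy_mm``/``dz_mm`` (signed) and ``euclidean_mm`` columns.
    """
    if grouping not in {"per_side", "pooled_after_per_side_centering"}:
        raise InputError(f"unknown grouping: {grouping!r}")
    missing = [c for c in TIP_COLUMNS if c not in tips.columns]
    if missing:
        raise InputError(f"tip table is missing columns: {missing}")
    out = tips.copy().reset_index(drop=True)
    for side, idx in out.groupby("side").groups.items():
        if len(idx) < 2:
            raise InputError(
                f"grouping cell side={side!r} has a single electrode; "
                "centering needs >=2"
            )
        for world, disp in zip(("x_mm", "y_mm", "z_mm"), ("dx_mm", "dy_mm", "dz_mm")):
            vals = out.loc[idx, world].to_numpy(dtype=float)
            out.loc[idx, disp] = vals - vals.mean()
    out["euclidean_mm"] = np.sqrt(
        out["dx_mm"] ** 2 + out["dy_mm"] ** 2 + out["dz_mm"] ** 2
    )
    out.attrs["grouping"] = grouping
    return out


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares line of y on x with t-based two-sided p (n-2 df)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise InputError(f"x and y differ in length: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise InputError(f"simple regression needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateStatisticsError("x is constant; slope is undefined")
    if np.ptp(y) == 0:
        # y carries no variance: flat fit, nothing explained
        return RegressionFit(0.0, float(y[0]), 0.0, 1.0, n)
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=n,
    )


def _merge_afre_tips(
    afre: pd.DataFrame, tips: pd.DataFrame, afid: int
) -> pd.DataFrame:
    sub = afre.loc[afre["afid"] == afid, ["subject", "dx_mm", "dy_mm", "dz_mm"]]
    return tips.merge(
        sub, on="subject", how="inner", suffixes=("_tip", "_afre")
    )


def r2_map(
    afre: pd.DataFrame,
    tips: pd.DataFrame,
    *,
    alpha: float = 0.05,
    bonferroni_m: int = 32,
) -> pd.DataFrame:
    """Regress each tip displacement axis on the same-axis signed AFRE.

    One row per (landmark, axis) with slope, r_squared, p_value, n, and
    two-tier significance flags (``alpha`` and ``alpha / bonferroni_m``).
    Cells with fewer than 3 aligned electrodes are marked missing (NaN).
    """
    validate_error_table(afre)
    if not (afre["kind"] == "AFRE").all():
        raise InputError("r2_map expects a kind == 'AFRE' table")
    rows = []
    for afid in sorted(afre["afid"].unique()):
        merged = _merge_afre_tips(afre, tips, afid)
        for axis in _AXIS_COLS:
            # tips must already be centered: regress displacement on AFRE
            disp_col = _AXIS_COLS[axis][1]
            y = merged[disp_col + "_tip"]
            x = merged[disp_col + "_afre"]
            row = dict(afid=int(afid), axis=axis, n=len(merged))
            if len(merged) < 3 or np.ptp(x.to_numpy()) == 0:
                row.update(slope=np.nan, r_squared=np.nan, p_value=np.nan)
            else:
                fit = simple_regression(x, y)
                row.update(
                    slope=fit.slope, r_squared=fit.r_squared, p_value=fit.p_value
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    table["significant_nominal"] = table["p_value"] < alpha
    table["significant_corrected"] = table["p_value"] < alpha / bonferroni_m
    return table


def covariate_screen(
    tips: pd.DataFrame,
    covariates: pd.DataFrame,
    types: dict[str, str],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate screen of covariates against tip displacement per axis.

    Binary covariates use the rank-sum test between the two levels;
    continuous covariates use Spearman rank correlation. The Bonferroni
    correction is per covariate, over the number of axes tested.
    """
    merged = tips.merge(covariates, on="subject", how="inner")
    axes = ["dx_mm", "dy_mm", "dz_mm", "euclidean_mm"]
    rows = []
    for cov, kind in types.items():
        if cov not in merged.columns:
            raise InputError(f"covariate {cov!r} not found")
        if kind not in {"binary", "continuous"}:
            raise InputError(f"covariate type must be binary|continuous, got {kind!r}")
        vals = merged[cov]
        if kind == "binary":
            levels = sorted(pd.unique(vals.dropna()))
            if len(levels) < 2:
                import warnings

                warnings.warn(f"covariate {cov!r} has one level; skipped", stacklevel=2)
                continue
            if len(levels) > 2:
                raise InputError(f"binary covariate {cov!r} has {len(levels)} levels")
        for ax in axes:
            y = merged[ax].to_numpy(dtype=float)
            if kind == "binary":
                g0 = y[(vals == levels[0]).to_numpy()]
                g1 = y[(vals == levels[1]).to_numpy()]
                res = compare_unpaired(g0, g1)
                stat, p = res.statistic, res.p_value
                method = res.method
            else:
                rho, p = stats.spearmanr(vals.to_numpy(dtype=float), y)
                stat, method = float(rho), "spearman"
            rows.append(
                dict(covariate=cov, type=kind, axis=ax.replace("_mm", ""),
                     statistic=stat, p_value=float(p), method=method)
            )
    table = pd.DataFrame(rows)
    if len(table):
        m = len(axes)
        table["significant_nominal"] = table["p_value"] < alpha
        table["significant_corrected"] = table["p_value"] < alpha / m
    return table


def multivariate_regression(design: pd.DataFrame, y: Sequence[float]) -> dict:
    """Ordinary least squares of y on all design columns plus an intercept.

    Returns a dict with a per-coefficient table (estimate, se, t, p) and the
    overall R-squared. Rank-deficient designs raise an error naming the
    collinear columns (identified by QR with column pivoting).
    """
    y = np.asarray(list(y), dtype=float)
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if y.size != n:
        raise InputError(f"y length {y.size} != design rows {n}")
    if n <= k + 1:
        raise InputError(f"need n > p + 1 (n={n}, p={k})")
    names = ["intercept"] + list(design.columns)
    Xd = np.column_stack([np.ones(n), X])
    _, R, piv = linalg.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < k + 1:
        bad = sorted(names[piv[j]] for j in range(rank, k + 1))
        raise InputError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    dof = n - (k + 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    coef = pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "t": tvals, "p_value": pvals}
    )
    return {"coefficients": coef, "r_squared": r2, "n": n, "dof": dof}


def pca(
    matrix: np.ndarray | pd.DataFrame,
    feature_labels: Sequence[str] | None = None,
    sample_ids: Sequence[Hashable] | None = None,
) -> PrincipalAxes:
    """Eigendecomposition of the sample covariance of column-centered data.

    Components are unit eigenvectors sorted by descending eigenvalue;
    ``explained_fraction`` is eigenvalue over trace; component signs are
    fixed so the largest-magnitude loading of each component is positive.
    """
    if isinstance(matrix, pd.DataFrame):
        if feature_labels is None:
            feature_labels = [str(c) for c in matrix.columns]
        if sample_ids is None:
            sample_ids = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InputError(f"pca expects a 2D matrix, got shape {X.shape}")
    n, p = X.shape
    if n < 2:
        raise InputError(f"pca needs >= 2 samples, got {n}")
    if feature_labels is None:
        feature_labels = [f"f{i}" for i in range(p)]
    if sample_ids is None:
        sample_ids = list(range(n))
    means = X.mean(axis=0)
    Xc = X - means
    cov = (Xc.T @ Xc) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(p):
        pivot = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    trace = eigvals.sum()
    frac = eigvals / trace if trace > 0 else np.zeros_like(eigvals)
    return PrincipalAxes(
        components=eigvecs,
        explained_fraction=frac,
        scores=Xc @ eigvecs,
        feature_labels=tuple(str(l) for l in feature_labels),
        column_means=means,
        sample_ids=tuple(sample_ids),
    )


def afre_pivot(afre: pd.DataFrame, afids: Sequence[int]) -> pd.DataFrame:
    """Subjects x (3 * len(afids)) matrix of signed AFRE components.

    Columns are labeled ``AFIDnn.x`` etc.; only subjects with complete rows
    for every requested landmark are kept; an empty intersection errors.
    """
    validate_error_table(afre)
    blocks = []
    for afid in afids:
        sub = afre.loc[afre["afid"] == afid]
        if sub["subject"].duplicated().any():
            raise InputError(
                f"multiple AFRE rows per subject for afid {afid}; "
                "aggregate raters first"
            )
        block = sub.set_index("subject")[["dx_mm", "dy_mm", "dz_mm"]]
        block.columns = [f"AFID{afid:02d}.{ax}" for ax in ("x", "y", "z")]
        blocks.append(block)
    wide = pd.concat(blocks, axis=1, join="inner")
    if wide.empty:
        raise InputError(
            f"no subjects shared across landmarks {list(afids)}"
        )
    return wide.sort_index()


def afre_correlation_matrix(
    afre: pd.DataFrame,
    afids: Sequence[int],
    basis: str = "cartesian",
) -> pd.DataFrame:
    """Pairwise r-squared between error features of the selected landmarks.

    ``basis="cartesian"`` uses the signed x/y/z components directly;
    ``basis="per_afid_prc"`` first runs a 3-feature PCA per landmark and
    correlates the principal-component scores instead.
    """
    if basis not in {"cartesian", "per_afid_prc"}:
        raise InputError(f"unknown basis: {basis!r}")
    wide = afre_pivot(afre, afids)
    if basis == "per_afid_prc":
        cols = {}
        for afid in afids:
            block = wide[[f"AFID{afid:02d}.{ax}" for ax in ("x", "y", "z")]]
            axes = pca(block)
            for j in range(3):
                cols[f"AFID{afid:02d}.PrC{j + 1}"] = axes.scores[:, j]
        wide = pd.DataFrame(cols, index=wide.index)
    corr = wide.corr(method="pearson")
    return corr**2


def stacked_pca(afre: pd.DataFrame, afids: Sequence[int]) -> PrincipalAxes:
    """PCA over the stacked signed components of several landmarks (3k features)."""
    if len(afids) < 2:
        raise InputError("stacked PCA needs at least two landmarks")
    wide = afre_pivot(afre, afids)
    return pca(wide)


def _subject_of(sample_id: Hashable) -> Hashable:
    if isinstance(sample_id, (tuple, list)):
        return sample_id[0]
    return sample_id


def attribute_variance(
    afre_axes: PrincipalAxes,
    tip_axes: PrincipalAxes,
    *,
    n_afre_components: int = 4,
) -> AttributionResult:
    """Correlate leading shared error components with tip principal axes.

    Each tip sample (``(subject, side)`` id or bare subject) is matched to
    its subject's stacked-PCA score. The r2/p matrices cover the top
    ``n_afre_components`` error components against all tip components.
    ``explained_mm`` is the absolute fitted value of the PrC1-on-PrC1
    regression, i.e. millimeters of tip displacement along the tip's first
    principal axis accounted for by the leading shared error component.
    """
    afre_scores = {
        _subject_of(sid): afre_axes.scores[i]
        for i, sid in enumerate(afre_axes.sample_ids)
    }
    subjects = [_subject_of(sid) for sid in tip_axes.sample_ids]
    missing = sorted({s for s in subjects if s not in afre_scores})
    if missing:
        raise InputError(f"tip subjects missing from AFRE scores: {missing}")
    k_afre = min(n_afre_components, afre_axes.n_components)
    x_all = np.stack([afre_scores[s] for s in subjects])  # tips x afre comps
    y_all = tip_axes.scores
    r2 = np.full((k_afre, tip_axes.n_components), np.nan)
    pmat = np.full_like(r2, np.nan)
    fits: dict[tuple[int, int], RegressionFit] = {}
    for i in range(k_afre):
        for j in range(tip_axes.n_components):
            x = x_all[:, i]
            y = y_all[:, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # degenerate component; leave the cell missing
            fit = simple_regression(x, y)
            fits[(i, j)] = fit
            r2[i, j] = fit.r_squared
            pmat[i, j] = fit.p_value
    row_idx = [f"AFRE_PrC{i + 1}" for i in range(k_afre)]
    col_idx = [f"tip_PrC{j + 1}" for j in range(tip_axes.n_components)]
    r2_df = pd.DataFrame(r2, index=row_idx, columns=col_idx)
    p_df = pd.DataFrame(pmat, index=row_idx, columns=col_idx)
    if (0, 0) not in fits:
        raise DegenerateStatisticsError(
            "PrC1-on-PrC1 regression is degenerate (zero-variance component)"
        )
    lead = fits[(0, 0)]
    fitted = lead.intercept + lead.slope * x_all[:, 0]
    explained = pd.Series(
        np.abs(fitted), index=pd.Index(tip_axes.sample_ids), name="explained_mm"
    )
    summary = {
        "r2_prc1": float(r2_df.iloc[0, 0]),
        "p_prc1": float(p_df.iloc[0, 0]),
        "explained_mm_median": float(explained.median()),
        "explained_mm_min": float(explained.min()),
        "explained_mm_max": float(explained.max()),
        "n_electrodes": int(len(explained)),
    }
    return AttributionResult(
        r2_matrix=r2_df, p_matrix=p_df, explained_mm=explained, summary=summary
    )
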