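"""Localization and registration error metrics.

Three error kinds share one tabular layout (:data:`ERROR_TABLE_COLUMNS`):

``LD``
    inter-rater localization distance; per-axis components are unsigned.
``AFLE``
    rater-to-consensus localization error; components signed
    (rater minus consensus).
``AFRE``
    template-space registration error; components signed
    (transformed minus template consensus), as the downstream correlation
    analysis needs direction.

Nonparametric tests are implemented here with exact null distributions for
small samples (dynamic programming over mid-ranks) and a tie-corrected,
continuity-corrected normal approximation otherwise. Zero differences are
dropped before signed-ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateStatisticsError, InputError
from .io import FiducialSet

__all__ = [
    "ERROR_TABLE_COLUMNS",
    "SummaryRow",
    "TestResult",
    "validate_error_table",
    "consensus_coordinates",
    "localization_distance",
    "localization_error",
    "registration_error",
    "global_afre",
    "summarize",
    "summarize_table",
    "rmse_by_axis",
    "compare_paired",
    "compare_unpaired",
    "bonferroni",
]

ERROR_TABLE_COLUMNS = [
    "subject",
    "rater",
    "afid",
    "label",
    "dx_mm",
    "dy_mm",
    "dz_mm",
    "euclidean_mm",
    "kind",
]

_AXES = ("dx_mm", "dy_mm", "dz_mm")
EXACT_LIMIT = 25  # at or below this n the exact null distribution is used


def _build_table(rows: list[dict], kind: str) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=ERROR_TABLE_COLUMNS)
    table["kind"] = kind
    validate_error_table(table)
    return table


def validate_error_table(table: pd.DataFrame) -> None:
    """Check the Euclidean-norm invariant and column layout."""
    missing = [c for c in ERROR_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"error table is missing columns: {missing}")
    if len(table) == 0:
        return
    norm = np.sqrt(
        table["dx_mm"] ** 2 + table["dy_mm"] ** 2 + table["dz_mm"] ** 2
    )
    if not np.allclose(norm, table["euclidean_mm"], atol=1e-9):
        raise InputError("euclidean_mm != sqrt(dx^2+dy^2+dz^2) in error table")
    if (table["euclidean_mm"] < 0).any():
        raise InputError("euclidean_mm must be nonnegative")


def _shared_ids(a: FiducialSet, b: FiducialSet) -> list[int]:
    ids = [i for i in a.afid_ids if i != 0 and i in set(b.afid_ids)]
    # afid_id 0 rows (ad-hoc points) are matched by label instead
    return ids


def consensus_coordinates(
    sets: Sequence[FiducialSet], min_raters: int = 3
) -> FiducialSet:
    """Component-wise mean placement per landmark across rater sets.

    Every landmark must be present in at least ``min_raters`` sets;
    violating landmarks are reported together in the raised error.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise InputError("consensus requires at least two rater sets")
    subjects = {s.subject_id for s in sets}
    spaces = {s.space for s in sets}
    if len(subjects) > 1 or len(spaces) > 1:
        raise InputError(
            f"rater sets must share subject and space; got {subjects}, {spaces}"
        )
    counts: dict[int, list[np.ndarray]] = {}
    labels: dict[int, tuple[str, str]] = {}
    for s in sets:
        for rec in s:
            if rec.afid_id == 0:
                continue
            counts.setdefault(rec.afid_id, []).append(rec.coordinate)
            labels.setdefault(rec.afid_id, (rec.label, rec.description))
    too_few = sorted(i for i, v in counts.items() if len(v) < min_raters)
    if too_few:
        raise InputError(
            f"landmarks below min_raters={min_raters}: afid_ids {too_few}"
        )
    from .io import FiducialRecord

    records = tuple(
        FiducialRecord(
            afid_id=i,
            label=labels[i][0],
            coordinate=np.mean(np.stack(v), axis=0),
            rater_id="consensus",
            subject_id=sets[0].subject_id,
            space=sets[0].space,
            description=labels[i][1],
        )
        for i, v in sorted(counts.items())
    )
    return FiducialSet(records=records, provenance="consensus")


def localization_distance(set_a: FiducialSet, set_b: FiducialSet) -> pd.DataFrame:
    """Pairwise inter-rater distance per landmark (unsigned axis components)."""
    if set_a.subject_id != set_b.subject_id or set_a.space != set_b.space:
        raise InputError("localization distance requires same subject and space")
    ids = _shared_ids(set_a, set_b)
    if not ids:
        raise InputError("no shared landmarks between the two sets")
    rows = []
    for i in ids:
        ra, rb = set_a.get(i), set_b.get(i)
        d = np.abs(ra.coordinate - rb.coordinate)
        rows.append(
            dict(
                subject=set_a.subject_id,
                rater=f"{set_a.rater_id}|{set_b.rater_id}",
                afid=i,
                label=ra.label,
                dx_mm=d[0],
                dy_mm=d[1],
                dz_mm=d[2],
                euclidean_mm=float(np.linalg.norm(ra.coordinate - rb.coordinate)),
                kind="LD",
            )
        )
    return _build_table(rows, "LD")


def localization_error(
    rater_sets: Sequence[FiducialSet],
    consensus: FiducialSet | None = None,
    *,
    min_raters: int = 3,
    allow_fewer: bool = False,
) -> pd.DataFrame:
    """Signed rater-minus-consensus error, one row per rater and landmark.

    Requires at least three raters unless ``allow_fewer=True``; a two-rater
    "consensus" is a pairwise midpoint and is easy to misread.
    """
    rater_sets = list(rater_sets)
    if len(rater_sets) < 3 and not allow_fewer:
        raise InputError(
            f"localization error needs >=3 raters (got {len(rater_sets)}); "
            "pass allow_fewer=True to override"
        )
    if consensus is None:
        consensus = consensus_coordinates(
            rater_sets, min_raters=min(min_raters, len(rater_sets))
        )
    rows = []
    cons_ids = set(consensus.afid_ids)
    for s in rater_sets:
        for rec in s:
            if rec.afid_id == 0 or rec.afid_id not in cons_ids:
                continue
            d = rec.coordinate - consensus.get(rec.afid_id).coordinate
            rows.append(
                dict(
                    subject=s.subject_id,
                    rater=s.rater_id,
                    afid=rec.afid_id,
                    label=rec.label,
                    dx_mm=d[0],
                    dy_mm=d[1],
                    dz_mm=d[2],
                    euclidean_mm=float(np.linalg.norm(d)),
                    kind="AFLE",
                )
            )
    if not rows:
        raise InputError("no landmarks shared with the consensus")
    return _build_table(rows, "AFLE")


def registration_error(
    transformed: FiducialSet, template_consensus: FiducialSet
) -> pd.DataFrame:
    """Signed transformed-minus-consensus displacement in template space."""
    if transformed.space != "template":
        raise InputError(
            f"transformed set must be in template space, got {transformed.space!r}"
        )
    if template_consensus.space != "template":
        raise InputError("consensus set must be in template space")
    ids = _shared_ids(transformed, template_consensus)
    if not ids:
        raise InputError("no shared landmarks with the template consensus")
    rows = []
    for i in ids:
        rec = transformed.get(i)
        d = rec.coordinate - template_consensus.get(i).coordinate
        rows.append(
            dict(
                subject=transformed.subject_id,
                rater=transformed.rater_id,
                afid=i,
                label=rec.label,
                dx_mm=d[0],
                dy_mm=d[1],
                dz_mm=d[2],
                euclidean_mm=float(np.linalg.norm(d)),
                kind="AFRE",
            )
        )
    return _build_table(rows, "AFRE")


def global_afre(table: pd.DataFrame) -> pd.Series:
    """Per-subject mean Euclidean registration error over available landmarks."""
    validate_error_table(table)
    if len(table) == 0:
        raise InputError("empty AFRE table")
    if not (table["kind"] == "AFRE").all():
        raise InputError("global AFRE is defined on kind == 'AFRE' tables only")
    out = table.groupby("subject")["euclidean_mm"].mean()
    out.name = "global_afre_mm"
    return out


@dataclass(frozen=True)
class SummaryRow:
    """Median/IQR, mean/variance, and RMSE of one list of millimeter values."""

    median: float
    iqr_low: float
    iqr_high: float
    mean: float
    variance: float
    rmse: float
    n: int


def summarize(values: Iterable[float]) -> SummaryRow:
    """Summary statistics with linear-interpolation percentiles and n-1 variance."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("cannot summarize an empty list")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return SummaryRow(
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
        mean=float(np.mean(v)),
        variance=float(np.var(v, ddof=1)) if v.size > 1 else 0.0,
        rmse=float(np.sqrt(np.mean(v**2))),
        n=int(v.size),
    )


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-axis and Euclidean summaries of an error table (one row per axis)."""
    validate_error_table(table)
    if len(table) == 0:
        raise InputError("cannot summarize an empty table")
    rows = []
    for name, col in [("x", "dx_mm"), ("y", "dy_mm"), ("z", "dz_mm"),
                      ("euclidean", "euclidean_mm")]:
        s = summarize(table[col].to_numpy())
        rows.append(dict(axis=name, **s.__dict__))
    return pd.DataFrame(rows)


def rmse_by_axis(table: pd.DataFrame) -> pd.Series:
    """Root-mean-square of the signed axis errors, one value per axis."""
    validate_error_table(table)
    if len(table) == 0:
        raise InputError("cannot compute RMSE of an empty table")
    out = pd.Series(
        {ax[1]: float(np.sqrt(np.mean(table[col] ** 2)))
         for ax, col in zip(("dx", "dy", "dz"), _AXES)},
        name="rmse_mm",
    )
    out.index = pd.Index(["x", "y", "z"], name="axis")
    return out


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def _two_sided_from_counts(counts: np.ndarray, observed: int) -> float:
    """Two-sided p from an integer-support null distribution.

    ``counts[s]`` is the (unnormalized) null mass at statistic value ``s``;
    p = min(1, 2 * min(P(S <= s_obs), P(S >= s_obs))).
    """
    total = counts.sum()
    p_le = counts[: observed + 1].sum() / total
    p_ge = counts[observed:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _signed_rank_counts(doubled_ranks: np.ndarray) -> np.ndarray:
    """Null distribution of the doubled positive-rank sum over 2^n signings."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def compare_paired(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped; ties get mid-ranks. Exact distribution for
    n <= 25 nonzero differences (valid under ties, conditioning on the
    observed ranks), otherwise a tie- and continuity-corrected normal
    approximation. All-zero differences degenerate to p = 1 with a warning.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise InputError(f"paired samples differ in length: {a.size} vs {b.size}")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn(
            "all paired differences are zero; signed-rank test is degenerate "
            "(reported as non-significant)",
            stacklevel=2,
        )
        return TestResult(statistic=0.0, p_value=1.0, n=0, method="degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _signed_rank_counts(doubled)
        observed = int(round(2 * w_plus))
        p = _two_sided_from_counts(counts, observed)
        return TestResult(w_plus, p, int(n), "wilcoxon-signed-rank-exact")
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    if sigma2 <= 0:
        return TestResult(w_plus, 1.0, int(n), "degenerate")
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(w_plus, p, int(n), "wilcoxon-signed-rank-normal")


def _rank_sum_counts(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Null distribution of the doubled rank sum of a size-n1 group.

    Dynamic program over subsets of the pooled (doubled, integer) ranks:
    ``counts[k][s]`` = number of k-subsets with doubled rank sum s.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros((n1 + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : total + 1 - r]
    return counts[n1]


def compare_unpaired(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum test, two-sided, mid-ranks for ties.

    Exact distribution when the pooled sample size is <= 25, otherwise a
    tie- and continuity-corrected normal approximation. The reported
    statistic is the rank sum of the first sample.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= EXACT_LIMIT:
        doubled = np.rint(2 * ranks).astype(int)
        counts = _rank_sum_counts(doubled, n1)
        p = _two_sided_from_counts(counts, int(round(2 * r1)))
        return TestResult(r1, p, n, "wilcoxon-rank-sum-exact")
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = (n1 * n2 / 12.0) * (
        (n + 1) - np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    )
    if sigma2 <= 0:
        return TestResult(r1, 1.0, n, "degenerate")
    diff = r1 - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(r1, p, n, "wilcoxon-rank-sum-normal")


def bonferroni(
    pvals: Sequence[float], m: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-tier significance flags: nominal (p < alpha) and corrected (p < alpha/m)."""
    if m < 1:
        raise InputError(f"m must be >= 1, got {m}")
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    return pd.DataFrame(
        {
            "p_value": p,
            "significant_nominal": p < alpha,
            "significant_corrected": p < alpha / m,
        }
    )
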