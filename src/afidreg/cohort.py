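"""Synthetic cohorts with a known misregistration structure.

The generative model is an explicit idealization. Each subject ``k`` draws
a latent score ``s_k ~ N(0, score_sd^2)`` that scales a shared smooth
vector field ``phi`` (a sum of Gaussian bumps). The observed template-space
position of landmark ``j`` with true position ``T_j`` is::

    T_j + s_k * phi(T_j) + R_k(T_j) + eta_jk

where ``R_k`` is a subject-specific smooth residual field (fixed Gaussian
bump centers, per-subject random 3-vector amplitudes of scale
``residual_sd``) and ``eta`` is iid per-axis localization noise. Electrode
tips at target ``E`` add an independent per-axis surgical deviation::

    E + s_k * phi(E) + R_k(E) + delta_k

Everything is reproducible bit-for-bit from (spec, seed); random draws are
consumed strictly in subject order, so cohorts are prefix-stable: the first
``m`` subjects of an ``n``-subject cohort equal an ``m``-subject cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .io import FiducialSet, load_template_consensus
from .transforms import DisplacementField

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "make_pattern",
    "simulate_cohort",
    "theoretical_r2",
    "tune_surgical_sd",
    "displacement_field_for_subject",
]

SIDES = ("R", "L")

# Midline residual-bump centers: left/right mirrored targets see identical
# residual variance, keeping the analytic moments exact for both sides.
_DEFAULT_RESIDUAL_CENTERS = (
    (0.0, -26.0, -8.0),
    (0.0, 0.0, 0.0),
    (0.0, -50.0, 0.0),
    (0.0, 20.0, 10.0),
    (0.0, -20.0, -30.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort generator."""

    n_subjects: int = 24
    seed: int = 0
    pattern_centers: tuple = ((0.0, -26.0, -8.0),)
    pattern_widths: tuple = (30.0,)
    pattern_amplitudes: tuple = ((0.2, 1.0, 0.6),)
    score_sd: float = 1.0
    residual_sd: float = 0.15
    localization_sd: float = 0.1
    surgical_sd: float = 1.2
    residual_centers: tuple = _DEFAULT_RESIDUAL_CENTERS
    residual_width: float = 25.0
    electrode_target: tuple = (12.0, -13.0, -7.0)
    analysis_afids: tuple = (2, 3, 4, 14)
    fiducial_truth: FiducialSet | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InputError("n_subjects must be >= 2")
        if len(self.pattern_centers) < 1:
            raise InputError("at least one pattern center is required")
        if not (
            len(self.pattern_centers)
            == len(self.pattern_widths)
            == len(self.pattern_amplitudes)
        ):
            raise InputError(
                "pattern_centers, pattern_widths, pattern_amplitudes must align"
            )
        if any(w <= 0 for w in self.pattern_widths) or self.residual_width <= 0:
            raise InputError("pattern and residual widths must be > 0")
        for name in ("score_sd", "residual_sd", "localization_sd", "surgical_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")

    def truth_set(self) -> FiducialSet:
        return self.fiducial_truth or load_template_consensus()

    def targets(self) -> dict[str, np.ndarray]:
        e = np.asarray(self.electrode_target, dtype=float)
        return {"R": e, "L": e * np.array([-1.0, 1.0, 1.0])}


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of one simulated cohort."""

    subjects: tuple[str, ...]
    scores: np.ndarray  # (n,)
    afid_ids: tuple[int, ...]
    pattern_at_fiducials: np.ndarray  # (n_fid, 3)
    pattern_at_targets: dict  # side -> (3,)
    surgical_deviations: np.ndarray  # (n, 2, 3) ordered by SIDES
    residual_amplitudes: np.ndarray  # (n, n_residual_centers, 3)


def make_pattern(spec: CohortSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Return the shared smooth vector field phi as a vectorized callable."""
    centers = np.asarray(spec.pattern_centers, dtype=float)
    widths = np.asarray(spec.pattern_widths, dtype=float)
    amps = np.asarray(spec.pattern_amplitudes, dtype=float)

    def phi(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        weights = np.exp(-d2 / (2.0 * widths[None, :] ** 2))  # (n_pts, n_centers)
        out = weights @ amps
        return out if np.asarray(points).ndim == 2 else out[0]

    return phi


def _residual_basis(spec: CohortSpec, points: np.ndarray) -> np.ndarray:
    """Gaussian bump values g_b(p): shape (n_points, n_centers)."""
    centers = np.asarray(spec.residual_centers, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * spec.residual_width**2))


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[FiducialSet], pd.DataFrame, CohortTruth]:
    """Generate transformed fiducial sets, an electrode tip table and truth."""
    truth_set = spec.truth_set()
    afid_ids = tuple(i for i in truth_set.afid_ids if i != 0)
    T = truth_set.coordinates(afid_ids)  # (n_fid, 3)
    phi = make_pattern(spec)
    phi_fid = phi(T)
    targets = spec.targets()
    phi_tgt = {side: phi(t[None, :])[0] for side, t in targets.items()}
    g_fid = _residual_basis(spec, T)  # (n_fid, n_res)
    g_tgt = {side: _residual_basis(spec, t[None, :])[0] for side, t in targets.items()}
    n_res = len(spec.residual_centers)

    rng = np.random.default_rng(spec.seed)
    sets: list[FiducialSet] = []
    tip_rows: list[dict] = []
    scores = np.empty(spec.n_subjects)
    deviations = np.empty((spec.n_subjects, len(SIDES), 3))
    amplitudes = np.empty((spec.n_subjects, n_res, 3))
    subjects = tuple(f"sub-{k + 1:04d}" for k in range(spec.n_subjects))

    for k, subject in enumerate(subjects):
        # one fixed draw sequence per subject => prefix-stable cohorts
        s_k = rng.normal(0.0, spec.score_sd)
        A_k = rng.normal(0.0, spec.residual_sd, size=(n_res, 3))
        eta = rng.normal(0.0, spec.localization_sd, size=T.shape)
        delta = rng.normal(0.0, spec.surgical_sd, size=(len(SIDES), 3))
        scores[k] = s_k
        amplitudes[k] = A_k
        deviations[k] = delta

        observed = T + s_k * phi_fid + g_fid @ A_k + eta
        # rebuild records in truth order with the subject identity
        coords_full = []
        for rec in truth_set:
            if rec.afid_id == 0:
                coords_full.append(rec.coordinate)
            else:
                coords_full.append(observed[afid_ids.index(rec.afid_id)])
        sets.append(
            truth_set.with_coordinates(
                np.asarray(coords_full),
                subject_id=subject,
                rater_id="transformed",
                space="template",
            )
        )
        for i, side in enumerate(SIDES):
            tip = targets[side] + s_k * phi_tgt[side] + g_tgt[side] @ A_k + delta[i]
            tip_rows.append(
                dict(subject=subject, side=side,
                     x_mm=tip[0], y_mm=tip[1], z_mm=tip[2])
            )

    tips = pd.DataFrame(tip_rows, columns=["subject", "side", "x_mm", "y_mm", "z_mm"])
    truth = CohortTruth(
        subjects=subjects,
        scores=scores,
        afid_ids=afid_ids,
        pattern_at_fiducials=phi_fid,
        pattern_at_targets=phi_tgt,
        surgical_deviations=deviations,
        residual_amplitudes=amplitudes,
    )
    return sets, tips, truth


def _noise_terms(spec: CohortSpec) -> tuple[float, float, float, float]:
    """(A, Nx, A_E, Ny) variance components of the PrC1 attribution model."""
    truth_set = spec.truth_set()
    ids = [i for i in spec.analysis_afids if i in truth_set.afid_ids]
    if len(ids) < 1:
        raise InputError("analysis_afids not present in the truth set")
    T = truth_set.coordinates(ids)
    phi = make_pattern(spec)
    v = phi(T)  # (k, 3) stacked pattern at the analysed landmarks
    v_flat = v.ravel()
    norm_v2 = float(v_flat @ v_flat)
    A = spec.score_sd**2 * norm_v2
    g2_fid = (_residual_basis(spec, T) ** 2).sum(axis=1)  # G(T_j)
    if norm_v2 > 0:
        block_w = (v**2).sum(axis=1) / norm_v2  # ||v_hat_j||^2 per landmark
    else:
        block_w = np.zeros(len(ids))
    Nx = float(
        np.sum((spec.residual_sd**2 * g2_fid + spec.localization_sd**2) * block_w)
    )
    E = spec.targets()["R"]
    phi_E = phi(E[None, :])[0]
    A_E = spec.score_sd**2 * float(phi_E @ phi_E)
    G_E = float((_residual_basis(spec, E[None, :]) ** 2).sum())
    Ny = spec.residual_sd**2 * G_E + spec.surgical_sd**2
    return A, Nx, A_E, Ny


def theoretical_r2(spec: CohortSpec) -> float:
    """Expected PrC1-on-PrC1 attribution r-squared under the generative model.

    Derived by projecting the model onto the pattern direction in both the
    stacked-landmark space and the tip space; exact when the shared pattern
    dominates the landmark-side noise (so the empirical first principal axes
    align with the pattern), and for mirrored targets when all bump centers
    sit on the midline.
    """
    A, Nx, A_E, Ny = _noise_terms(spec)
    if A == 0.0 or A_E == 0.0:
        return 0.0
    return float((A * A_E) / ((A + Nx) * (A_E + Ny)))


def tune_surgical_sd(spec: CohortSpec, target_r2: float) -> CohortSpec:
    """Spec copy whose surgical noise makes :func:`theoretical_r2` hit a target."""
    if not (0.0 < target_r2 < 1.0):
        raise InputError("target_r2 must be in (0, 1)")
    A, Nx, A_E, _ = _noise_terms(spec)
    if A == 0.0 or A_E == 0.0:
        raise InputError("spec has no shared pattern at landmarks or target")
    ny_needed = (A * A_E) / (target_r2 * (A + Nx)) - A_E
    E = spec.targets()["R"]
    G_E = float((_residual_basis(spec, E[None, :]) ** 2).sum())
    app_var = ny_needed - spec.residual_sd**2 * G_E
    if app_var < 0:
        raise InputError(
            f"target r2={target_r2} unreachable: required surgical variance "
            f"is negative ({app_var:.4g})"
        )
    return replace(spec, surgical_sd=float(np.sqrt(app_var)))


def displacement_field_for_subject(
    spec: CohortSpec,
    truth: CohortTruth,
    subject_index: int,
    *,
    grid_shape: tuple[int, int, int] = (16, 16, 16),
    origin: tuple[float, float, float] = (-80.0, -110.0, -70.0),
    spacing: float = 10.0,
) -> DisplacementField:
    """Subject's misregistration field (s_k * phi + R_k) on a coarse grid."""
    phi = make_pattern(spec)
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = vox * spacing + np.asarray(origin)
    s_k = truth.scores[subject_index]
    A_k = truth.residual_amplitudes[subject_index]
    vectors = s_k * phi(world) + _residual_basis(spec, world) @ A_k
    return DisplacementField(
        vectors=vectors.reshape(nx, ny, nz, 3), voxel_to_world=affine
    )
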