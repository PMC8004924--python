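"""Trajectory stability metrics: fitted RMSD series and per-atom RMSF.

RMSD of a ligand is conventionally measured against its initial
configuration after a translational and rotational fit of the protein
backbone — the fit selection and measure selection are therefore
independent arguments throughout.  Superposition uses the optimal
least-squares proper rotation (Kabsch); reflections are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .stats import mean_sd
from .topology import Trajectory

__all__ = [
    "kabsch_fit",
    "apply_fit",
    "rmsd_series",
    "rmsf",
    "aggregate_metric",
    "MetricSeries",
    "MetricAggregate",
]


class FitError(ValueError):
    """Degenerate superposition problem."""


def _check_fit_points(points: np.ndarray, label: str) -> None:
    if points.ndim != 2 or points.shape[1] != 3:
        raise FitError(f"{label} coordinates must have shape (n, 3)")
    if points.shape[0] < 3:
        raise FitError("superposition needs at least 3 points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise FitError(f"{label} points are collinear")


def kabsch_fit(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted_rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates into the
    reference frame; the transform minimizes the RMSD over proper
    rotations (determinant +1) and translations.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise FitError("mobile and reference must have equal point counts")
    _check_fit_points(mobile, "mobile")
    _check_fit_points(reference, "reference")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    # scipy's align_vectors implements the Kabsch solution restricted to
    # proper rotations; the residual is recomputed from the fitted
    # coordinates because the returned rssd loses precision near zero
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    matrix = rot.as_matrix()
    translation = cr - matrix @ cm
    fitted_rmsd = _rmsd(apply_fit(mobile, matrix, translation), reference)
    return matrix, translation, fitted_rmsd


def apply_fit(coords: np.ndarray, rotation: np.ndarray,
              translation: np.ndarray) -> np.ndarray:
    return coords @ rotation.T + translation


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))


@dataclass
class MetricSeries:
    """One RMSD series (per frame) or RMSF profile (per atom), in Å."""

    kind: str
    values: np.ndarray
    fit_selection: np.ndarray
    measure_selection: np.ndarray
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("metric values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        index_name = "atom_index" if self.kind == "rmsf" else "frame_index"
        return pd.DataFrame(
            {
                index_name: (
                    self.measure_selection
                    if self.kind == "rmsf"
                    else np.arange(len(self.values))
                ),
                "value": self.values,
                "kind": self.kind,
                "run_id": self.run_id,
            }
        )


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray,
    kind: str = "rmsd",
    run_id: str = "",
) -> MetricSeries:
    """Per-frame RMSD over ``measure_selection`` after fitting on
    ``fit_selection`` against a reference frame (full-system coordinates).

    With identical fit and measure selections this is ordinary fitted
    RMSD; with backbone fit and ligand measure it is the ligand's
    displacement within the binding-site frame.
    """
    fit_selection = np.asarray(fit_selection, dtype=int)
    measure_selection = np.asarray(measure_selection, dtype=int)
    if fit_selection.size == 0 or measure_selection.size == 0:
        raise ValueError("fit and measure selections must be non-empty")
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (trajectory.n_atoms, 3):
        raise ValueError("reference frame does not match the trajectory")
    ref_fit = reference[fit_selection]
    ref_measure = reference[measure_selection]
    values = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        rot, trans, _ = kabsch_fit(frame[fit_selection], ref_fit)
        values[f] = _rmsd(apply_fit(frame[measure_selection], rot, trans),
                          ref_measure)
    return MetricSeries(
        kind=kind, values=values,
        fit_selection=fit_selection, measure_selection=measure_selection,
        run_id=run_id,
    )


def rmsf(
    trajectory: Trajectory,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray,
    reference_frame: int = 0,
    run_id: str = "",
) -> MetricSeries:
    """Per-atom root-mean-square fluctuation about the time-averaged
    position, after fitting every frame to ``reference_frame`` on
    ``fit_selection``."""
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_selection = np.asarray(fit_selection, dtype=int)
    measure_selection = np.asarray(measure_selection, dtype=int)
    ref = trajectory.frame(reference_frame)[fit_selection]
    fitted = np.empty((trajectory.n_frames, measure_selection.size, 3))
    for f in range(trajectory.n_frames):
        frame = trajectory.frame(f)
        rot, trans, _ = kabsch_fit(frame[fit_selection], ref)
        fitted[f] = apply_fit(frame[measure_selection], rot, trans)
    mean_pos = fitted.mean(axis=0)
    values = np.sqrt(((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return MetricSeries(
        kind="rmsf", values=values,
        fit_selection=fit_selection, measure_selection=measure_selection,
        run_id=run_id,
    )


@dataclass(frozen=True)
class MetricAggregate:
    """Cross-run summary of a metric: per-run means, then mean ± sd."""

    kind: str
    per_run_means: tuple[float, ...]
    mean: float
    sd: float
    n_runs: int
    single_run: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"run_id": f"run{i + 1}", "mean": m}
            for i, m in enumerate(self.per_run_means)
        ]
        rows.append({"run_id": "mean", "mean": self.mean})
        rows.append({"run_id": "sd", "mean": self.sd})
        df = pd.DataFrame(rows)
        df["kind"] = self.kind
        return df


def aggregate_metric(series_list: list[MetricSeries]) -> MetricAggregate:
    """Per-run means, then cross-run mean and sample sd (n−1).

    A single run is aggregated with sd 0 and ``single_run=True``.
    """
    if not series_list:
        raise ValueError("no runs to aggregate")
    per_run = [s.mean for s in series_list]
    mean, sd = mean_sd(per_run)
    return MetricAggregate(
        kind=series_list[0].kind,
        per_run_means=tuple(per_run),
        mean=mean,
        sd=sd,
        n_runs=len(per_run),
        single_run=len(per_run) == 1,
    )
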