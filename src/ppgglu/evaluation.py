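"""Accuracy metrics, Clarke Error Grid, Monte Carlo CV and uncertainty.

All public APIs take glucose in mmol/L (converted internally to mg/dL for
the Clarke grid with the conventional factor 18.016).  MARD — the mean
absolute relative difference, mean(|y' - y| / y) * 100 — is the standard
accuracy figure for glucose monitors and is reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ValidationError

__all__ = [
    "EvalReport",
    "ClarkeReport",
    "UncertaintyReport",
    "MCCVResult",
    "compute_metrics",
    "clarke_zone",
    "clarke_report",
    "monte_carlo_cv",
    "estimate_uncertainty",
    "MMOL_TO_MGDL",
]

MMOL_TO_MGDL = 18.016


@dataclass(frozen=True)
class EvalReport:
    """Point-accuracy metrics plus the per-point relative differences (%)."""

    mse: float
    rmse: float
    mae: float
    mard: float
    r2: float
    n: int
    rd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "mard": self.mard,
            "r2": self.r2,
            "n": self.n,
            "rd": [float(v) for v in self.rd],
        }


def _check_pair(y_ref, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ref.shape != y_pred.shape or y_ref.ndim != 1:
        raise ValidationError(
            f"y_ref and y_pred must be equal-length 1-D arrays, got "
            f"{y_ref.shape} and {y_pred.shape}"
        )
    if len(y_ref) == 0:
        raise ValidationError("empty input")
    return y_ref, y_pred


def compute_metrics(y_ref, y_pred) -> EvalReport:
    """MSE, RMSE, MAE, MARD (%), R2 and signed relative differences (%).

    R2 = 1 - SS_res/SS_tot; it requires n >= 2, and is NaN when the
    references have zero variance.  MARD requires strictly positive
    references.
    """
    y_ref, y_pred = _check_pair(y_ref, y_pred)
    if np.any(y_ref <= 0):
        raise ValidationError("MARD undefined: references must be strictly positive")
    if len(y_ref) < 2:
        raise ValidationError("R2 undefined for n < 2")
    err = y_pred - y_ref
    mse = float(np.mean(err**2))
    rd = err / y_ref * 100.0
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return EvalReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        mard=float(np.mean(np.abs(rd))),
        r2=r2,
        n=len(y_ref),
        rd=rd,
    )


# ---------------------------------------------------------------------------
# Clarke Error Grid (1987)
# ---------------------------------------------------------------------------

_ZONES = np.array(["A", "B", "C", "D", "E"])


def _clarke_zones_mgdl(ref: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Vectorized canonical 1987 zone inequalities on mg/dL pairs.

    Zones are assigned by the conventional decision chain (A, E, C, D, else
    B), with inclusive boundaries so that points on the A-zone border count
    as clinically accurate:

      A: |pred - ref| <= 0.2 * ref, or both below 70
      E: (ref <= 70 and pred >= 180) or (ref >= 180 and pred <= 70)
      C: (70 <= ref <= 290 and pred >= ref + 110)
         or (130 <= ref <= 180 and pred <= (7/5) * ref - 182)
      D: (ref >= 240 and 70 <= pred <= 180)
         or (ref <= 175/3 and 70 <= pred <= 180)
         or (175/3 <= ref <= 70 and pred >= (6/5) * ref)
      B: everything else
    """
    zone_a = ((ref <= 70) & (pred <= 70)) | (np.abs(pred - ref) <= 0.2 * ref)
    zone_e = ((ref <= 70) & (pred >= 180)) | ((ref >= 180) & (pred <= 70))
    zone_c = ((ref >= 70) & (ref <= 290) & (pred >= ref + 110)) | (
        (ref >= 130) & (ref <= 180) & (pred <= (7.0 / 5.0) * ref - 182)
    )
    zone_d = (
        ((ref >= 240) & (pred >= 70) & (pred <= 180))
        | ((ref <= 175.0 / 3.0) & (pred >= 70) & (pred <= 180))
        | ((ref >= 175.0 / 3.0) & (ref <= 70) & (pred >= (6.0 / 5.0) * ref))
    )
    out = np.full(ref.shape, "B", dtype="<U1")
    out[zone_d] = "D"
    out[zone_c] = "C"
    out[zone_e] = "E"
    out[zone_a] = "A"
    return out


def clarke_zone(ref_mmol: float, pred_mmol: float) -> str:
    """Clarke Error Grid zone of one (reference, predicted) pair in mmol/L."""
    if not (ref_mmol > 0 and pred_mmol > 0):
        raise ValidationError("Clarke zoning requires strictly positive glucose values")
    return str(
        _clarke_zones_mgdl(
            np.array([ref_mmol * MMOL_TO_MGDL]), np.array([pred_mmol * MMOL_TO_MGDL])
        )[0]
    )


@dataclass(frozen=True)
class ClarkeReport:
    """Per-point zone labels and zone percentages (summing to 100)."""

    zones: np.ndarray
    percentages: dict[str, float]

    @property
    def n(self) -> int:
        return len(self.zones)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "percentages": self.percentages,
            "zones": [str(z) for z in self.zones],
        }


def clarke_report(y_ref, y_pred) -> ClarkeReport:
    """Vectorized Clarke zoning with zone percentages over all points."""
    y_ref, y_pred = _check_pair(y_ref, y_pred)
    if np.any(y_ref <= 0) or np.any(y_pred <= 0):
        raise ValidationError("Clarke zoning requires strictly positive glucose values")
    zones = _clarke_zones_mgdl(y_ref * MMOL_TO_MGDL, y_pred * MMOL_TO_MGDL)
    n = len(zones)
    percentages = {str(z): float(np.sum(zones == z) / n * 100.0) for z in _ZONES}
    return ClarkeReport(zones=zones, percentages=percentages)


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation
# ---------------------------------------------------------------------------

#: A model factory takes an integer seed and returns an unfitted model with
#: fit(X, y) and predict(X).
ModelFactory = Callable[[int], object]


@dataclass(frozen=True)
class MCCVResult:
    """Per-repeat metric reports plus the mean/min/max summary."""

    reports: tuple[EvalReport, ...]

    def metric(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.reports])

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name in ("mse", "rmse", "mae", "mard", "r2"):
            values = self.metric(name)
            out[name] = {
                "mean": float(np.mean(values)),
                "min": float(np.min(values)),
                "max": float(np.max(values)),
            }
        return out


def _split_indices(
    n: int, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValidationError(
            f"test_fraction {test_fraction} gives a test set of size {n_test} for n={n}"
        )
    perm = rng.permutation(n)
    return perm[n_test:], perm[:n_test]


def monte_carlo_cv(
    X,
    y,
    model_factory: ModelFactory,
    n_repeats: int = 50,
    test_fraction: float = 0.2,
    seed: int | None = None,
) -> MCCVResult:
    """Repeated random train/test splitting (seeded), one report per repeat."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_repeats < 1:
        raise ValidationError(f"n_repeats must be >= 1, got {n_repeats}")
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng = np.random.default_rng(ss)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_repeats)]
    reports = []
    for rep in range(n_repeats):
        train, test = _split_indices(len(y), test_fraction, rng)
        model = model_factory(child_seeds[rep])
        model.fit(X[train], y[train])
        reports.append(compute_metrics(y[test], model.predict(X[test])))
    return MCCVResult(reports=tuple(reports))


# ---------------------------------------------------------------------------
# Uncertainty decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UncertaintyReport:
    """Aleatoric (mean +/- sd of per-point prediction variability, mmol/L)
    and epistemic (mean bootstrap-ensemble spread, mmol/L) uncertainty."""

    aleatoric_mean: float
    aleatoric_sd: float
    epistemic: float

    def to_dict(self) -> dict:
        return {
            "aleatoric_mean": self.aleatoric_mean,
            "aleatoric_sd": self.aleatoric_sd,
            "epistemic": self.epistemic,
        }


def estimate_uncertainty(
    X,
    y,
    model_factory: ModelFactory,
    n_ensemble: int = 20,
    n_repeats: int = 20,
    test_fraction: float = 0.2,
    seed: int | None = None,
) -> UncertaintyReport:
    """Ensemble-based uncertainty decomposition.

    Epistemic: models are trained on bootstrap resamples and the mean over
    points of the across-ensemble prediction standard deviation is reported.
    Aleatoric: across Monte Carlo CV repeats, each point's held-out
    predictions are collected and their per-point standard deviation is
    summarised as mean +/- sd over points.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_ensemble < 2:
        raise ValidationError(f"n_ensemble must be >= 2, got {n_ensemble}")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng = np.random.default_rng(ss)
    children = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_ensemble + n_repeats)]

    n = len(y)
    ensemble_preds = np.empty((n_ensemble, n))
    for b in range(n_ensemble):
        idx = rng.integers(0, n, size=n)
        model = model_factory(children[b])
        model.fit(X[idx], y[idx])
        ensemble_preds[b] = model.predict(X)
    epistemic = float(np.mean(np.std(ensemble_preds, axis=0, ddof=1)))

    held_out: list[list[float]] = [[] for _ in range(n)]
    for rep in range(n_repeats):
        train, test = _split_indices(n, test_fraction, rng)
        model = model_factory(children[n_ensemble + rep])
        model.fit(X[train], y[train])
        preds = model.predict(X[test])
        for i, p in zip(test, preds):
            held_out[i].append(float(p))
    spreads = np.array([np.std(v, ddof=1) for v in held_out if len(v) >= 2])
    if len(spreads) == 0:
        raise ValidationError(
            "not enough Monte Carlo repeats to estimate aleatoric uncertainty"
        )
    return UncertaintyReport(
        aleatoric_mean=float(np.mean(spreads)),
        aleatoric_sd=float(np.std(spreads, ddof=1)) if len(spreads) > 1 else 0.0,
        epistemic=epistemic,
    )
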