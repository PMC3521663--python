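"""Fitting expression data to the occupancy model and unit reductions.

Two fits are provided, both in natural-log expression space (residuals and
their RMSD are defined on ln expression):

* :func:`fit_boltzmann_intercept` — slope fixed at -1 (pure Boltzmann
  scaling); the single parameter is the intercept ``log_k``.
* :func:`fit_full_occupancy` — two-parameter fit of the full occupancy
  form ``k * x / (1 + x)`` with ``x = (P/N_NS) * exp(-energy)``; reduces
  to the intercept fit deep in the weak-promoter limit, where ``P/N_NS``
  is only weakly identified.

:func:`measured_energy` inverts the fitted line to turn a measured
expression value into an empirical binding energy, and the small helpers
at the bottom implement the Miller-unit formula and the protein burst
size from steady-state copy numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import constants


class DataError(ValueError):
    """Raised for unusable expression data (e.g. nonpositive values)."""


@dataclass(frozen=True)
class ExpressionRecord:
    """One expression measurement for one promoter."""

    promoter_id: str
    value: float
    units: str = "mrna_per_cell"  # or "miller_units"
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DataError(f"{self.promoter_id}: expression must be >= 0")
        if self.units not in ("mrna_per_cell", "miller_units"):
            raise DataError(f"{self.promoter_id}: unknown units {self.units!r}")


@dataclass(frozen=True)
class FitResult:
    """Fitted proportionality constant and goodness of fit.

    ``log_k`` is the natural log of the expression expected at zero
    (genome-average) binding energy; ``rmsd_log`` is the RMS residual of
    ln expression.  ``p_over_nns`` is present only for the full-occupancy
    fit; ``p_over_nns_identified`` is False when the data never leave the
    weak-promoter limit, in which case the value is not meaningful.
    """

    log_k: float
    rmsd_log: float
    n_points: int
    p_over_nns: float | None = None
    p_over_nns_identified: bool | None = None

    @property
    def k(self) -> float:
        return math.exp(self.log_k)


def _prepare(
    records: Sequence[ExpressionRecord],
    energies: Mapping[str, float],
    average_replicates: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired arrays (energy, ln value), optionally averaging replicates per promoter."""
    bad = [r.promoter_id for r in records if r.value <= 0]
    if bad:
        raise DataError(f"nonpositive expression for promoters: {sorted(set(bad))}")
    missing = sorted({r.promoter_id for r in records} - set(energies))
    if missing:
        raise DataError(f"no model energy for promoters: {missing}")
    df = pd.DataFrame(
        {"id": [r.promoter_id for r in records], "value": [r.value for r in records]}
    )
    if average_replicates:
        df = df.groupby("id", as_index=False)["value"].mean()
    eps = np.array([energies[i] for i in df["id"]])
    logv = np.log(df["value"].to_numpy())
    if len(set(df["id"])) < 2:
        raise DataError("need measurements for at least 2 distinct promoters")
    return eps, logv


def fit_boltzmann_intercept(
    records: Sequence[ExpressionRecord],
    energies: Mapping[str, float],
    average_replicates: bool = False,
) -> FitResult:
    """Fit ln(expression) = log_k - energy with the slope fixed at -1.

    The least-squares intercept is the mean of (ln value + energy);
    rmsd_log is the RMS of the remaining residuals.  By default every
    individual measurement enters the fit; set ``average_replicates`` to
    fit per-promoter means instead.
    """
    eps, logv = _prepare(records, energies, average_replicates)
    log_k = float(np.mean(logv + eps))
    resid = logv - (log_k - eps)
    return FitResult(
        log_k=log_k,
        rmsd_log=float(np.sqrt(np.mean(resid**2))),
        n_points=len(logv),
    )


#: Below this maximum occupancy weight the full fit cannot distinguish
#: p_over_nns from the intercept; the parameter is flagged unidentified.
_X_IDENTIFIABILITY_THRESHOLD = 0.01

_P_OVER_NNS_BOUNDS = (1e-8, 1.0)


def fit_full_occupancy(
    records: Sequence[ExpressionRecord],
    energies: Mapping[str, float],
    average_replicates: bool = False,
    p_over_nns_init: float = 1e-3,
) -> FitResult:
    """Two-parameter log-space fit of expression = k * x / (1 + x).

    ``x = p_over_nns * exp(-energy)``.  Initialized from the intercept fit
    with ``p_over_nns`` bounded to [1e-8, 1] for biological plausibility
    and numerical stability in the weakly identified regime.
    """
    eps, logv = _prepare(records, energies, average_replicates)
    if eps.max() - eps.min() < 2.0:
        raise DataError("full-occupancy fit needs promoters spanning >= 2 kBT")
    lo, hi = math.log(_P_OVER_NNS_BOUNDS[0]), math.log(_P_OVER_NNS_BOUNDS[1])

    # Writing the model as ln v = L - eps - ln(1 + x), x = p * exp(-eps),
    # with the lumped intercept L = ln(k * p), the conditional optimum in L
    # is closed-form, so the fit reduces to a 1-D profile over ln p.  This
    # is far more robust than a joint 2-D search in the weak limit, where
    # the (ln k, ln p) valley is essentially flat.
    def profile_ssr(log_p: float) -> float:
        t = logv + eps + np.log1p(np.exp(log_p - eps))
        return float(np.sum((t - t.mean()) ** 2))

    sol = minimize_scalar(
        profile_ssr, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
    )
    if not sol.success:
        raise DataError(f"full-occupancy fit did not converge: {sol.message}")
    log_p = float(sol.x)
    # polish against the initialization-anchored candidate in case the
    # bounded search stalled on a flat stretch
    if profile_ssr(math.log(p_over_nns_init)) < sol.fun:
        log_p = math.log(p_over_nns_init)
    p = float(np.exp(log_p))
    x = np.exp(log_p - eps)
    lumped = float(np.mean(logv + eps + np.log1p(x)))
    resid = logv - (lumped - eps - np.log1p(x))
    x_max = p * float(np.exp(-eps.min()))
    return FitResult(
        log_k=lumped,  # weak-limit intercept ln(k * P/N_NS), comparable across fits
        rmsd_log=float(np.sqrt(np.mean(resid**2))),
        n_points=len(logv),
        p_over_nns=p,
        p_over_nns_identified=bool(x_max >= _X_IDENTIFIABILITY_THRESHOLD),
    )


def measured_energy(value: float, fit: FitResult) -> float:
    """Binding energy (kBT) at which the fitted Boltzmann line predicts ``value``.

    Inverts ln(expression) = log_k - energy; applied per promoter this
    back-calculates an empirical binding energy from a measurement.
    """
    if value <= 0:
        raise DataError("expression value must be > 0")
    return fit.log_k - math.log(value)


def corrected_energies(
    records: Sequence[ExpressionRecord], fit: FitResult
) -> dict[str, float]:
    """Per-promoter measured energies from constitutive (R = 0) data.

    Averages ln expression over replicates first, then inverts the fitted
    line.  Feeding these corrected energies into the repression model
    removes the constant log-offset that model-predicted energies inherit.
    """
    by_id: dict[str, list[float]] = {}
    for r in records:
        if r.value <= 0:
            raise DataError(f"nonpositive expression for {r.promoter_id}")
        by_id.setdefault(r.promoter_id, []).append(math.log(r.value))
    return {pid: fit.log_k - float(np.mean(lv)) for pid, lv in by_id.items()}


@dataclass(frozen=True)
class BurstInputs:
    """Steady-state copy numbers and turnover rates for the burst-size ratio.

    ``gamma_p`` is the protein dilution rate (inverse division time, 1/min)
    and ``gamma_m`` the mRNA decay rate (1/min).
    """

    protein_per_cell: float
    mrna_per_cell: float
    gamma_p: float = constants.GAMMA_P_PER_MIN
    gamma_m: float = constants.GAMMA_M_PER_MIN

    def __post_init__(self) -> None:
        for name in ("protein_per_cell", "mrna_per_cell", "gamma_p", "gamma_m"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")


def burst_size(bi: BurstInputs) -> float:
    """Average proteins produced per mRNA.

    At steady state copy number = production rate / decay rate, so the
    ratio of production rates is (protein * gamma_p) / (mRNA * gamma_m).
    """
    return (bi.protein_per_cell * bi.gamma_p) / (bi.mrna_per_cell * bi.gamma_m)


def burst_size_from_miller(
    miller_units: float,
    mrna_per_cell: float,
    gamma_p: float = constants.GAMMA_P_PER_MIN,
    gamma_m: float = constants.GAMMA_M_PER_MIN,
    tetramers_per_miller_unit: float = constants.TETRAMERS_PER_MILLER_UNIT,
) -> tuple[float, float]:
    """Burst size from a LacZ activity measurement.

    Converts Miller units to tetramer copy number first; returns
    (tetramers per mRNA, monomers per mRNA) where monomers = 4 * tetramers.
    """
    protein = miller_units * tetramers_per_miller_unit
    b_tet = burst_size(
        BurstInputs(
            protein_per_cell=protein,
            mrna_per_cell=mrna_per_cell,
            gamma_p=gamma_p,
            gamma_m=gamma_m,
        )
    )
    return b_tet, b_tet * constants.MONOMERS_PER_TETRAMER


@dataclass(frozen=True)
class MillerAssayRecord:
    """Raw optical densities and assay geometry for one LacZ measurement.

    ``dilution_factor`` corrects for a nonstandard stop-solution volume
    that changes the final ONP concentration relative to the classical
    protocol (1.0 = classical volumes).
    """

    od420: float
    od550: float
    od600: float
    t_min: float
    v_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.t_min <= 0:
            raise DataError("t_min must be > 0")
        if self.v_ml <= 0:
            raise DataError("v_ml must be > 0")


def miller_units(rec: MillerAssayRecord) -> float:
    """LacZ activity in Miller units.

    MU = 1000 * dilution_factor * (OD420 - 1.75 * OD550) / (t * v * OD600),
    where the OD550 term corrects OD420 for light scattered by cell debris.
    Constants live in :mod:`promtune.constants`.
    """
    if rec.od600 == 0:
        raise DataError("od600 must be nonzero")
    corrected = rec.od420 - constants.MILLER_SCATTER_COEFF * rec.od550
    return (
        constants.MILLER_PREFACTOR
        * rec.dilution_factor
        * corrected
        / (rec.t_min * rec.v_ml * rec.od600)
    )
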