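"""Seeded generators emulating the study's data structure.

Everything here is a pure function of (seed, config): same inputs, byte-
identical outputs.  The generators emulate the structure of the real
experiment — an 18-promoter ladder spanning ~7 kBT of binding energy whose
expression follows Boltzmann scaling with multiplicative lognormal
measurement scatter, and repressor titrations following the simple-
repression fold-change — without reproducing any real measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .matrix import BASES, EnergyMatrix
from .thermo import RepressionParams, fold_change_repression


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults for the synthetic datasets.

    ``true_log_k`` is the natural-log expression at zero (genome-average)
    binding energy — the lumped constant ln(k * P/N_NS) of the weak limit.
    ``sigma_ln`` is the lognormal measurement scatter in natural-log units
    (1.0 matches the RMSD magnitude seen in real promoter-ladder data).
    ``p_over_nns_true`` switches generation to the full occupancy form
    when set; leave None for the pure weak limit.
    """

    seed: int = 0
    n_promoters: int = 18
    true_log_k: float = float(np.log(100.0))
    sigma_ln: float = 1.0
    p_over_nns_true: float | None = None
    energy_range: tuple[float, float] = (-4.5, 2.5)
    r_values: tuple[float, ...] = (0.0, 11.0, 30.0, 62.0, 130.0, 610.0, 900.0)
    de_r_true: float = constants.DE_R_O2_KBT
    n_ns: float = constants.N_NS
    genome_length: int = 50_000
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.sigma_ln < 0:
            raise ValueError("sigma_ln must be >= 0")
        if self.energy_range[0] >= self.energy_range[1]:
            raise ValueError("energy_range must be ordered (min, max)")
        if self.n_promoters < 1 or self.n_replicates < 1 or self.genome_length < 1:
            raise ValueError("counts must be >= 1")


def generate_toy_matrix(seed: int, width: int = 41) -> EnergyMatrix:
    """Random calibrated-style energy matrix with high-weight -10/-35 boxes.

    Per-position substitution deltas span roughly 0-3 kBT in the hexamer
    boxes and are an order of magnitude smaller elsewhere, mimicking the
    weight structure of the real RNAP matrix.  Entries are shifted so each
    row has zero mean (a genome-zeroed-style convention for toys).
    """
    rng = np.random.default_rng(seed)
    entries = rng.uniform(0.0, 0.3, size=(width, 4))
    box_positions = [p for p in constants.DEFAULT_MUTABLE_POSITIONS if -width <= p <= -1]
    for pos in box_positions:
        entries[pos + width] = rng.uniform(0.0, 3.0, size=4)
    entries -= entries.mean(axis=1, keepdims=True)
    return EnergyMatrix(entries=entries, units="kBT", offset_state="genome_zeroed")


def generate_random_genome(seed: int, length: int, circular: bool = True) -> str:
    """Uniform-ACGT random genome (a stand-in for a real chromosome in tests)."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _expression(cfg: SynthConfig, energies: np.ndarray) -> np.ndarray:
    """Noiseless expression at each energy under the configured model."""
    if cfg.p_over_nns_true is None:
        return np.exp(cfg.true_log_k - energies)
    x = cfg.p_over_nns_true * np.exp(-energies)
    # lumped intercept convention: weak limit reduces to exp(true_log_k - e)
    return np.exp(cfg.true_log_k - energies) / (1.0 + x)


def simulate_constitutive_dataset(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic promoter ladder: (energies table, expression records table).

    Energies are evenly spread over ``energy_range``; expression follows
    the occupancy model with multiplicative lognormal noise of width
    ``sigma_ln``.  Returns two DataFrames: (promoter_id, energy_kbt) and
    (promoter_id, value, units, replicate).
    """
    rng = np.random.default_rng(cfg.seed)
    energies = np.linspace(cfg.energy_range[0], cfg.energy_range[1], cfg.n_promoters)
    ids = [f"P{i:02d}" for i in range(cfg.n_promoters)]
    mean_values = _expression(cfg, energies)
    rows = []
    for rep in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.sigma_ln, size=cfg.n_promoters) if cfg.sigma_ln else 0.0
        values = mean_values * np.exp(noise)
        rows.extend(
            {"promoter_id": pid, "value": v, "units": "mrna_per_cell", "replicate": rep}
            for pid, v in zip(ids, values)
        )
    energy_table = pd.DataFrame({"promoter_id": ids, "energy_kbt": energies})
    return energy_table, pd.DataFrame(rows)


def simulate_repression_dataset(
    cfg: SynthConfig, energy_misspecification: float = 0.0
) -> pd.DataFrame:
    """Synthetic repressor titration over the promoter ladder.

    Values follow the weak-limit simple-repression model built from the
    *true* promoter energies, with lognormal noise; the reported
    ``model_energy_kbt`` column is true energy + ``energy_misspecification``
    so downstream analyses can reproduce (and then correct) the inherited
    constant log-offset between prediction and measurement.

    Columns: promoter_id, R, value, units, replicate, model_energy_kbt,
    true_energy_kbt.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    energies = np.linspace(cfg.energy_range[0], cfg.energy_range[1], cfg.n_promoters)
    ids = [f"P{i:02d}" for i in range(cfg.n_promoters)]
    rows = []
    for R in cfg.r_values:
        fc = fold_change_repression(
            RepressionParams(R=R, dE_R=cfg.de_r_true), n_ns=cfg.n_ns
        )
        for rep in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, cfg.sigma_ln, size=cfg.n_promoters)
                if cfg.sigma_ln
                else np.zeros(cfg.n_promoters)
            )
            values = np.exp(cfg.true_log_k - energies) * fc * np.exp(noise)
            rows.extend(
                {
                    "promoter_id": pid,
                    "R": R,
                    "value": v,
                    "units": "mrna_per_cell",
                    "replicate": rep,
                    "model_energy_kbt": e + energy_misspecification,
                    "true_energy_kbt": e,
                }
                for pid, e, v in zip(ids, energies, values)
            )
    return pd.DataFrame(rows)
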