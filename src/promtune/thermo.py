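"""Thermodynamic occupancy models for constitutive and simply repressed promoters.

The promoter is treated as competing with ``N_NS`` nonspecific genomic
sites for ``P`` polymerases.  With the promoter binding energy ``dE_P``
measured in kBT relative to the nonspecific background (genome-zeroed
scale), the equilibrium probability that RNAP occupies the promoter is

    p_bound = x / (1 + x),    x = (P / N_NS) * exp(-dE_P)

and expression is assumed proportional to p_bound with constant ``k``.
In the weak-promoter limit (x << 1) expression reduces to pure Boltzmann
scaling, ``k * (P/N_NS) * exp(-dE_P)``.  A simple-repression architecture
adds a mutually exclusive repressor-bound state with statistical weight
``(heads * R / N_NS) * exp(-dE_R)``.

All energies are in kBT with beta = 1 absorbed; there is no temperature
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants


@dataclass(frozen=True)
class ThermoParams:
    """Parameters of the constitutive occupancy model.

    Either give ``p_over_nns`` directly or give ``P`` (with ``N_NS``);
    ``dE_P`` is the promoter binding energy on the genome-zeroed kBT scale
    and ``k`` converts occupancy to expression units (Miller units or
    mRNA/cell).
    """

    k: float
    dE_P: float
    p_over_nns: float | None = None
    P: float | None = None
    N_NS: float = constants.N_NS

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.N_NS <= 0:
            raise ValueError("N_NS must be > 0")
        if self.p_over_nns is None and self.P is None:
            raise ValueError("give either p_over_nns or P")
        if self.p_over_nns is not None and self.p_over_nns <= 0:
            raise ValueError("p_over_nns must be > 0")
        if self.P is not None and self.P <= 0:
            raise ValueError("P must be > 0")

    @property
    def ratio(self) -> float:
        """P / N_NS, however parameterized."""
        return self.p_over_nns if self.p_over_nns is not None else self.P / self.N_NS

    @property
    def x(self) -> float:
        """Statistical weight of the RNAP-bound state."""
        return self.ratio * float(np.exp(-self.dE_P))


@dataclass(frozen=True)
class RepressionParams:
    """Repressor copy number and operator binding energy for simple repression.

    ``dE_R`` is relative to the nonspecific background; ``heads_factor``
    is 2 for LacI (two DNA-binding heads per tetramer).
    """

    R: float
    dE_R: float
    heads_factor: float = constants.LACI_HEADS_FACTOR

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("R must be >= 0")
        if self.heads_factor < 1:
            raise ValueError("heads_factor must be >= 1")

    def weight(self, n_ns: float) -> float:
        """Statistical weight of the repressor-bound state."""
        return (self.heads_factor * self.R / n_ns) * float(np.exp(-self.dE_R))


def p_bound_full(tp: ThermoParams) -> float:
    """Occupancy x/(1+x): Boltzmann weight of the bound state over the partition sum."""
    x = tp.x
    return x / (1.0 + x)


def p_bound_weak(tp: ThermoParams) -> float:
    """Weak-promoter limit of the occupancy: the Boltzmann weight itself.

    Valid when x << 1; the caller is responsible for checking the limit
    (relative error vs. the full form is exactly x/(1+x)).
    """
    return tp.x


def energy_to_kd(tp: ThermoParams, concentration_per_copy: float) -> float:
    """In vivo dissociation constant equivalent to the occupancy model.

    ``concentration_per_copy`` converts copy number to concentration (e.g.
    ~1.6 nM per molecule per E. coli cell).  The returned K_d satisfies
    p_bound = ([P]/K_d) / (1 + [P]/K_d) with [P] = P * concentration_per_copy,
    i.e. K_d = concentration_per_copy * N_NS * exp(dE_P).
    """
    if concentration_per_copy <= 0:
        raise ValueError("concentration_per_copy must be > 0")
    if tp.P is not None:
        p_conc = tp.P * concentration_per_copy
    else:
        p_conc = tp.p_over_nns * tp.N_NS * concentration_per_copy
    return p_conc / tp.x


def expression_constitutive(tp: ThermoParams, weak: bool = True) -> float:
    """Expression from an unregulated promoter: k times the RNAP occupancy."""
    if weak:
        return tp.k * tp.x
    return tp.k * p_bound_full(tp)


def fold_change_repression(rp: RepressionParams, n_ns: float = constants.N_NS) -> float:
    """Repressed / constitutive expression in the weak-promoter limit.

    fold_change = 1 / (1 + (heads * R / N_NS) * exp(-dE_R)); equals 1 with
    no repressor and decreases monotonically in R.
    """
    return 1.0 / (1.0 + rp.weight(n_ns))


def expression_repression(
    tp: ThermoParams, rp: RepressionParams, weak: bool = True
) -> float:
    """Expression under simple repression.

    Full form: k * x / (1 + x + y) with y the repressor weight; weak form:
    constitutive weak expression times the fold-change.  Both reduce to the
    constitutive forms at R = 0.
    """
    y = rp.weight(tp.N_NS)
    if weak:
        return expression_constitutive(tp, weak=True) * fold_change_repression(rp, tp.N_NS)
    x = tp.x
    return tp.k * x / (1.0 + x + y)
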