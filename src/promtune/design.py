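"""Promoter design: search sequence space for a targeted binding energy.

Because the energy model is additive, mutating position *p* from base *a*
to base *b* changes the total energy by ``eps(b, p) - eps(a, p)``
independently of every other position.  Designing a promoter with a target
energy therefore reduces to picking a set of per-position substitution
deltas whose sum lands within tolerance of ``target - score(start)``.

The search is exact: iterative deepening over the number of mutations
(fewer mutations always preferred), with branch-and-bound pruning at each
level using the extreme achievable delta sums of the remaining positions.
Ties are broken deterministically — smaller residual first, then the
lexicographically smaller sequence — so design involves no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import constants
from .matrix import BASES, EnergyMatrix, PromoterSequence, score_sequence

_EPS = 1e-9  # float slack so pruning never discards a true optimum


@dataclass(frozen=True)
class DesignSpec:
    """Target and constraints for a single promoter design.

    ``mutable_positions`` are promoter coordinates (-width..-1); the default
    is the -35 and -10 hexamer boxes, where matrix weights are largest.
    """

    start_sequence: PromoterSequence
    target_energy: float
    tolerance: float = 0.25
    mutable_positions: tuple[int, ...] = constants.DEFAULT_MUTABLE_POSITIONS
    max_mutations: int = 9

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")
        object.__setattr__(self, "mutable_positions", tuple(sorted(set(self.mutable_positions))))


@dataclass(frozen=True)
class DesignResult:
    sequence: PromoterSequence
    achieved_energy: float
    n_mutations: int
    residual: float
    target_energy: float
    status: str = "success"  # "success" | "infeasible"

    @property
    def feasible(self) -> bool:
        return self.status == "success"


class InfeasibleTargetError(ValueError):
    """No sequence within tolerance of the target; carries the closest found."""

    def __init__(self, closest: DesignResult):
        self.closest = closest
        super().__init__(
            f"no sequence within {abs(closest.target_energy - closest.achieved_energy):.4g} "
            f"of target {closest.target_energy:.4g} kBT "
            f"(closest achievable: {closest.achieved_energy:.4g} kBT)"
        )


def _check_spec(matrix: EnergyMatrix, spec: DesignSpec) -> None:
    if matrix.units != "kBT" or matrix.offset_state != "genome_zeroed":
        raise ValueError("design requires a calibrated (kBT, genome_zeroed) matrix")
    if len(spec.start_sequence) != matrix.width:
        raise ValueError(
            f"start sequence length {len(spec.start_sequence)} != matrix width {matrix.width}"
        )
    lo, hi = -matrix.width, -1
    for p in spec.mutable_positions:
        if not lo <= p <= hi:
            raise ValueError(f"mutable position {p} outside [{lo}, {hi}]")


def _position_deltas(
    matrix: EnergyMatrix, start: PromoterSequence, positions: Sequence[int]
) -> list[list[tuple[float, str]]]:
    """For each mutable position, the (delta, new_base) substitution options."""
    out = []
    for pos in positions:
        row = matrix.row_index(pos)
        cur = start.bases[row]
        opts = [
            (float(matrix.entries[row, bi] - matrix.entries[row, BASES.index(cur)]), b)
            for bi, b in enumerate(BASES)
            if b != cur
        ]
        # base order A<C<G<T preserved; lexicographic tie-breaks rely on it
        out.append(opts)
    return out


@dataclass
class _Best:
    residual: float = np.inf
    sequence: str | None = None
    energy: float = 0.0
    n_mutations: int = 0


def _search_exact_k(
    deltas: list[list[tuple[float, str]]],
    rows: list[int],
    start_bases: str,
    base_energy: float,
    target: float,
    k: int,
    matrix: EnergyMatrix,
    forbidden: frozenset[str],
    best: _Best,
) -> None:
    """Enumerate all candidates with exactly k mutations, updating ``best``.

    Prunes a subtree when even the extreme achievable delta sums of the
    remaining positions cannot beat the incumbent residual.
    """
    n = len(deltas)
    # suffix extreme sums for exactly r mutations among positions i..n-1,
    # tabulated once: bounds[i][r] = (min sum, max sum)
    pos_min = [min(d for d, _ in opts) for opts in deltas]
    pos_max = [max(d for d, _ in opts) for opts in deltas]
    bounds: list[list[tuple[float, float]]] = []
    for i in range(n + 1):
        mins = sorted(pos_min[i:])
        maxs = sorted(pos_max[i:], reverse=True)
        row_b = [(0.0, 0.0)]
        for r in range(1, min(k, n - i) + 1):
            row_b.append((row_b[r - 1][0] + mins[r - 1], row_b[r - 1][1] + maxs[r - 1]))
        bounds.append(row_b)

    def suffix_bounds(i: int, r: int) -> tuple[float, float]:
        return bounds[i][r]

    seq = list(start_bases)

    def recurse(i: int, used: int, acc: float) -> None:
        remaining = k - used
        if remaining == 0:
            cand = "".join(seq)
            if cand in forbidden:
                return
            energy = score_sequence(matrix, cand)  # full sum: exact, no drift
            residual = abs(energy - target)
            if residual < best.residual or (
                residual == best.residual
                and best.sequence is not None
                and cand < best.sequence
            ):
                best.residual = residual
                best.sequence = cand
                best.energy = energy
                best.n_mutations = k
            return
        if n - i < remaining:
            return
        lo, hi = suffix_bounds(i, remaining)
        gap = target - (base_energy + acc)
        dist = max(gap - hi, lo - gap, 0.0)
        if dist > best.residual + _EPS:
            return
        # option 1: mutate position i
        row = rows[i]
        original = seq[row]
        for d, b in deltas[i]:
            seq[row] = b
            recurse(i + 1, used + 1, acc + d)
        seq[row] = original
        # option 2: leave position i unchanged
        recurse(i + 1, used, acc)

    recurse(0, 0, 0.0)


def design_promoter(
    matrix: EnergyMatrix,
    spec: DesignSpec,
    forbidden: Iterable[str] = (),
) -> DesignResult:
    """Find the sequence whose calibrated energy is within tolerance of the target.

    Preference order among candidates: within-tolerance first, then fewest
    mutations from the start sequence, then smallest residual, then the
    lexicographically smallest sequence.  ``forbidden`` excludes exact
    sequences (used by :func:`design_ladder` to keep rungs distinct).

    Raises :class:`InfeasibleTargetError` (carrying the closest achievable
    design) when no candidate lands within tolerance.
    """
    _check_spec(matrix, spec)
    forbidden = frozenset(forbidden)
    start = spec.start_sequence
    base_energy = score_sequence(matrix, start)
    deltas = _position_deltas(matrix, start, spec.mutable_positions)
    rows = [matrix.row_index(p) for p in spec.mutable_positions]

    closest = _Best()
    if start.bases not in forbidden:
        closest.residual = abs(base_energy - spec.target_energy)
        closest.sequence = start.bases
        closest.energy = base_energy
        closest.n_mutations = 0

    max_k = min(spec.max_mutations, len(spec.mutable_positions))
    for k in range(0, max_k + 1):
        level = _Best()
        if k == 0:
            if start.bases not in forbidden:
                level = _Best(
                    residual=abs(base_energy - spec.target_energy),
                    sequence=start.bases,
                    energy=base_energy,
                    n_mutations=0,
                )
        else:
            _search_exact_k(
                deltas, rows, start.bases, base_energy, spec.target_energy,
                k, matrix, forbidden, level,
            )
        if level.sequence is not None:
            if level.residual <= spec.tolerance:
                return DesignResult(
                    sequence=PromoterSequence(level.sequence, id=start.id),
                    achieved_energy=level.energy,
                    n_mutations=level.n_mutations,
                    residual=level.residual,
                    target_energy=spec.target_energy,
                )
            if level.residual < closest.residual:
                closest = level
    raise InfeasibleTargetError(
        DesignResult(
            sequence=PromoterSequence(closest.sequence, id=start.id),
            achieved_energy=closest.energy,
            n_mutations=closest.n_mutations,
            residual=closest.residual,
            target_energy=spec.target_energy,
            status="infeasible",
        )
    )


def design_ladder(
    matrix: EnergyMatrix,
    start: PromoterSequence,
    energy_min: float,
    energy_max: float,
    step: float = constants.DEFAULT_LADDER_STEP_KBT,
    tolerance: float = 0.25,
    mutable_positions: tuple[int, ...] = constants.DEFAULT_MUTABLE_POSITIONS,
    max_mutations: int = 9,
) -> list[DesignResult]:
    """Design one promoter per energy rung {min, min+step, ..., <= max}.

    Returned sequences are all distinct (later rungs exclude earlier picks).
    Infeasible rungs are reported in place with ``status="infeasible"`` and
    the closest achievable design, never silently dropped.
    """
    if energy_min >= energy_max:
        raise ValueError("energy_min must be < energy_max")
    if step <= 0:
        raise ValueError("step must be > 0")
    rungs = np.arange(energy_min, energy_max + 1e-12, step)
    if rungs.size == 0:
        raise ValueError("empty rung set")
    results: list[DesignResult] = []
    used: set[str] = set()
    for i, target in enumerate(rungs):
        spec = DesignSpec(
            start_sequence=PromoterSequence(start.bases, id=f"{start.id or 'rung'}_{i}"),
            target_energy=float(target),
            tolerance=tolerance,
            mutable_positions=mutable_positions,
            max_mutations=max_mutations,
        )
        try:
            res = design_promoter(matrix, spec, forbidden=used)
        except InfeasibleTargetError as exc:
            res = exc.closest
        results.append(res)
        used.add(res.sequence.bases)
    return results
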