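"""Energy-matrix scoring, genome scanning and calibration to kBT units.

The binding energy of RNA polymerase to a candidate site is modelled as a
linear (additive) function of sequence: a matrix ``epsilon[i, b]`` gives the
energy contribution of base *b* at position *i* of the site, and the total
energy of a sequence is the sum of the contributions of its bases.  The
published matrix covers positions -41..-1 relative to the transcription
start and is expressed in arbitrary units (AU); :func:`calibrate` rescales
it to physical kBT units using two reference energies and re-zeroes it so
that the genome-wide mean window energy is exactly zero.

Sign convention: more positive = less favourable binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G

_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


class MatrixFormatError(ValueError):
    """Raised when an energy-matrix file cannot be parsed."""


class DimensionError(ValueError):
    """Raised when a sequence length does not match the matrix width."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside ACGT."""


class DegenerateCalibrationError(ValueError):
    """Raised when the two calibration anchors coincide (zero denominator)."""


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes A=0 C=1 G=2 T=3; other chars -> -1."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter site aligned to positions -width..-1 of the transcription start."""

    bases: str
    id: str = ""

    def __post_init__(self) -> None:
        if any(c not in _BASE_INDEX for c in self.bases.upper()):
            bad = sorted({c for c in self.bases.upper() if c not in _BASE_INDEX})
            raise AlphabetError(f"sequence {self.id!r} contains non-ACGT characters: {bad}")
        object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)

    def codes(self) -> np.ndarray:
        return encode(self.bases)


@dataclass(frozen=True)
class EnergyMatrix:
    """Per-position, per-base additive binding-energy contributions.

    ``entries`` has shape (width, 4) with columns ordered A, C, G, T and row
    *i* corresponding to promoter position ``-width + i`` (first row = the
    most upstream position, last row = -1).
    """

    entries: np.ndarray
    units: Literal["AU", "kBT"] = "AU"
    offset_state: Literal["raw", "genome_zeroed"] = "raw"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[1] != 4 or entries.shape[0] < 1:
            raise MatrixFormatError(f"expected a (width, 4) array, got shape {entries.shape}")
        if not np.all(np.isfinite(entries)):
            raise MatrixFormatError("matrix entries must all be finite")
        object.__setattr__(self, "entries", entries)

    @property
    def width(self) -> int:
        return self.entries.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Promoter coordinates -width..-1 (0 = transcription start)."""
        return np.arange(-self.width, 0)

    def row_index(self, position: int) -> int:
        """Convert a promoter coordinate (-width..-1) to a row index."""
        if not -self.width <= position <= -1:
            raise IndexError(f"position {position} outside [-{self.width}, -1]")
        return position + self.width

    def entry(self, base: str, position: int) -> float:
        """Energy contribution of ``base`` at promoter coordinate ``position``."""
        if base not in _BASE_INDEX:
            raise AlphabetError(f"unknown base {base!r}")
        return float(self.entries[self.row_index(position), _BASE_INDEX[base]])

    def shifted(self, constant: float) -> "EnergyMatrix":
        """Add a constant to every entry (physically meaningless shift)."""
        return replace(self, entries=self.entries + constant)


def read_energy_matrix(path: str | Path, expected_width: int | None = None) -> EnergyMatrix:
    """Read a whitespace-delimited energy matrix: one row per position, columns A C G T.

    Row *i* of the file maps to promoter position ``-n_rows + (i - 1)``
    (first row = most upstream).  Blank lines and ``#`` comment lines are
    ignored.  Malformed rows raise :class:`MatrixFormatError` naming the
    offending line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 4:
                raise MatrixFormatError(
                    f"{path.name}, line {lineno}: expected 4 columns (A C G T), got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise MatrixFormatError(f"{path.name}, line {lineno}: non-numeric field ({exc})") from None
    if not rows:
        raise MatrixFormatError(f"{path.name}: no data rows found")
    if expected_width is not None and len(rows) != expected_width:
        raise MatrixFormatError(
            f"{path.name}: expected {expected_width} rows, found {len(rows)}"
        )
    return EnergyMatrix(entries=np.array(rows, dtype=float), units="AU", offset_state="raw")


def write_energy_matrix(matrix: EnergyMatrix, path: str | Path) -> None:
    """Write a matrix in the same whitespace-delimited dialect read_energy_matrix parses."""
    np.savetxt(path, matrix.entries, fmt="%.6f")


def score_sequence(matrix: EnergyMatrix, seq: PromoterSequence | str) -> float:
    """Total binding energy of ``seq``: the sum of per-position matrix entries.

    Equivalent to the inner product of the matrix with the 0/1 indicator
    matrix of the sequence.  Units follow the matrix.
    """
    if isinstance(seq, str):
        seq = PromoterSequence(seq)
    if len(seq) != matrix.width:
        raise DimensionError(
            f"sequence length {len(seq)} != matrix width {matrix.width}"
        )
    codes = seq.codes()
    return float(matrix.entries[np.arange(matrix.width), codes].sum())


@dataclass
class GenomeScan:
    """Result of scanning a genome with an energy matrix.

    ``forward`` / ``reverse`` hold one energy per window start position
    (NaN where the window was skipped for containing non-ACGT characters);
    ``reverse`` is empty when only the forward strand was scanned.
    """

    forward: np.ndarray
    reverse: np.ndarray
    n_skipped: int
    circular: bool

    @property
    def energies(self) -> np.ndarray:
        """All retained window energies, both strands concatenated."""
        both = np.concatenate([self.forward, self.reverse])
        return both[~np.isnan(both)]

    @property
    def n_windows(self) -> int:
        return int(self.energies.size)

    @property
    def mean(self) -> float:
        return float(self.energies.mean())

    def windows(self) -> Iterator[tuple[int, str, float]]:
        """Yield (0-based window start, strand, energy) for retained windows."""
        for strand, arr in (("+", self.forward), ("-", self.reverse)):
            for start, e in enumerate(arr):
                if not np.isnan(e):
                    yield start, strand, float(e)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("position\tstrand\tenergy\n")
            for start, strand, e in self.windows():
                fh.write(f"{start}\t{strand}\t{e:.6f}\n")


def _window_energies(entries: np.ndarray, codes: np.ndarray, n_windows: int) -> np.ndarray:
    """Energies of windows starting at 0..n_windows-1 over the code array."""
    width = entries.shape[0]
    acc = np.zeros(n_windows)
    safe = np.clip(codes, 0, 3)
    for j in range(width):
        acc += entries[j, safe[j : j + n_windows]]
    return acc


def scan_genome(
    matrix: EnergyMatrix,
    genome: str,
    circular: bool = True,
    strands: Literal["both", "forward"] = "both",
) -> GenomeScan:
    """Score every width-bp window of ``genome`` with ``matrix``.

    With ``circular=True`` windows wrap across the origin, so each strand
    contributes exactly ``len(genome)`` windows; linear genomes contribute
    ``L - width + 1``.  With ``strands="both"`` each window is additionally
    scored as the reverse complement read 5'->3' (the matrix is defined on
    the promoter sense strand).  Windows containing non-ACGT characters are
    skipped and counted in ``n_skipped``.
    """
    width = matrix.width
    L = len(genome)
    if L < width:
        raise DimensionError(f"genome length {L} < matrix width {width}")
    codes = encode(genome)
    if circular:
        codes_ext = np.concatenate([codes, codes[: width - 1]])
        n_windows = L
    else:
        codes_ext = codes
        n_windows = L - width + 1

    # windows containing any non-ACGT base are invalid on both strands
    bad = (codes_ext < 0).astype(np.int64)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    invalid = (bad_cum[width:] - bad_cum[:-width])[:n_windows] > 0

    forward = _window_energies(matrix.entries, codes_ext, n_windows)
    forward[invalid] = np.nan
    n_skipped = int(invalid.sum())

    if strands == "both":
        # Scoring revcomp(window) with M equals scoring the window with the
        # reversed, base-complemented matrix M'[j, b] = M[width-1-j, comp(b)].
        rc_entries = matrix.entries[::-1][:, _COMPLEMENT_INDEX]
        reverse = _window_energies(rc_entries, codes_ext, n_windows)
        reverse[invalid] = np.nan
        n_skipped *= 2
    elif strands == "forward":
        reverse = np.empty(0)
    else:
        raise ValueError(f"strands must be 'both' or 'forward', got {strands!r}")

    if np.all(np.isnan(forward)) and (reverse.size == 0 or np.all(np.isnan(reverse))):
        raise DimensionError("no valid windows: every window contains non-ACGT characters")
    return GenomeScan(forward=forward, reverse=reverse, n_skipped=n_skipped, circular=circular)


@dataclass
class CalibrationRefs:
    """The two reference energies anchoring the AU -> kBT conversion.

    ``wt_lac_specific_energy_kbt`` is the known specific binding energy of
    RNAP at the WT lac promoter relative to the nonspecific genomic
    background (negative: binding is favourable).  ``genome_mean_au`` and
    ``conversion_au_per_kbt`` are filled in by :func:`calibrate`.
    """

    wt_lac_sequence: PromoterSequence
    wt_lac_specific_energy_kbt: float
    genome_mean_au: float | None = None
    conversion_au_per_kbt: float | None = None

    def au_to_kbt(self, energy_au: float) -> float:
        """Map a raw AU score onto the calibrated, genome-zeroed kBT scale."""
        if self.genome_mean_au is None or self.conversion_au_per_kbt is None:
            raise ValueError("calibration not yet performed")
        return (energy_au - self.genome_mean_au) / self.conversion_au_per_kbt


def calibrate(
    matrix: EnergyMatrix,
    genome: str,
    refs: CalibrationRefs,
    circular: bool = True,
    strands: Literal["both", "forward"] = "both",
) -> tuple[EnergyMatrix, CalibrationRefs]:
    """Convert a raw AU matrix to kBT units, zeroed on the genome-wide mean.

    Two anchors pin the affine transform: (1) the genome-wide mean window
    energy defines zero, and (2) the WT lac promoter must score its known
    specific energy (in kBT, relative to nonspecific background).  The
    conversion factor is ``(genome_mean_au - score_au(wt_lac)) /
    |wt_lac_specific_energy_kbt|``; it is positive whenever the WT lac site
    binds better (scores lower) than the genomic average.

    Returns the calibrated matrix together with a completed copy of
    ``refs`` carrying ``genome_mean_au`` and ``conversion_au_per_kbt``.
    """
    if matrix.units != "AU":
        raise ValueError(f"calibrate expects a raw AU matrix, got units={matrix.units!r}")
    mean_au = scan_genome(matrix, genome, circular=circular, strands=strands).mean
    wt_au = score_sequence(matrix, refs.wt_lac_sequence)
    if wt_au == mean_au:
        raise DegenerateCalibrationError(
            "WT lac score equals the genome mean; conversion factor undefined"
        )
    conversion = (mean_au - wt_au) / abs(refs.wt_lac_specific_energy_kbt)
    # per-entry offset so a full window's score shifts by exactly mean_au
    entries_kbt = (matrix.entries - mean_au / matrix.width) / conversion
    calibrated = EnergyMatrix(entries=entries_kbt, units="kBT", offset_state="genome_zeroed")
    done = replace(refs, genome_mean_au=mean_au, conversion_au_per_kbt=conversion)
    return calibrated, done
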