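"""Energy-matrix parsing, scoring, genome scanning and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promtune import (
    AlphabetError,
    CalibrationRefs,
    DegenerateCalibrationError,
    DimensionError,
    EnergyMatrix,
    MatrixFormatError,
    PromoterSequence,
    calibrate,
    read_energy_matrix,
    scan_genome,
    score_sequence,
)
from promtune.matrix import encode
from promtune.synth import generate_random_genome, generate_toy_matrix

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


# ---------------------------------------------------------------- parsing

class TestReadEnergyMatrix:
    def test_zero_matrix_41_rows(self, tmp_path):
        path = tmp_path / "zeros.txt"
        path.write_text("0 0 0 0\n" * 41)
        m = read_energy_matrix(path)
        assert m.width == 41
        assert np.all(m.entries == 0)
        assert m.units == "AU" and m.offset_state == "raw"

    def test_two_row_hand_transcription(self, tmp_path):
        path = tmp_path / "toy.txt"
        path.write_text("0.5 0 0 0\n0 -1.0 0 0\n")
        m = read_energy_matrix(path)
        assert m.width == 2
        # first row = most upstream position (-2), last row = -1
        assert m.entry("A", -2) == 0.5
        assert m.entry("C", -1) == -1.0

    def test_wrong_row_count_rejected(self, tmp_path):
        path = tmp_path / "short.txt"
        path.write_text("0 0 0 0\n" * 40)
        with pytest.raises(MatrixFormatError, match="expected 41 rows"):
            read_energy_matrix(path, expected_width=41)

    @pytest.mark.parametrize(
        "content, match",
        [
            ("0 0 0\n", "line 1"),
            ("0 0 0 0\n1 2 x 4\n", "line 2"),
            ("", "no data rows"),
        ],
    )
    def test_malformed_rows_name_line(self, tmp_path, content, match):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(MatrixFormatError, match=match):
            read_energy_matrix(path)


# ---------------------------------------------------------------- scoring

class TestScoreSequence:
    def test_zero_matrix_scores_zero(self):
        m = EnergyMatrix(entries=np.zeros((41, 4)))
        assert score_sequence(m, "A" * 41) == 0.0

    def test_manual_summation(self, toy2_matrix):
        assert score_sequence(toy2_matrix, "AC") == pytest.approx(0.5 - 1.0)

    def test_length_mismatch(self, toy2_matrix):
        with pytest.raises(DimensionError):
            score_sequence(toy2_matrix, "ACG")

    def test_non_acgt_rejected(self):
        with pytest.raises(AlphabetError):
            PromoterSequence("AN")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        shift=st.floats(-10, 10, allow_nan=False),
        data=st.data(),
    )
    def test_constant_shift_moves_score_by_width_times_c(self, seed, shift, data):
        m = generate_toy_matrix(seed, width=8)
        seq = "".join(data.draw(st.sampled_from(BASES)) for _ in range(8))
        base = score_sequence(m, seq)
        shifted = score_sequence(m.shifted(shift), seq)
        assert shifted == pytest.approx(base + 8 * shift, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 1000), pos=st.integers(0, 7), data=st.data())
    def test_point_mutation_changes_score_by_entry_delta(self, seed, pos, data):
        m = generate_toy_matrix(seed, width=8)
        seq = list("ACGTACGT")
        new = data.draw(st.sampled_from(BASES))
        old = seq[pos]
        before = score_sequence(m, "".join(seq))
        seq[pos] = new
        after = score_sequence(m, "".join(seq))
        expected = m.entries[pos, BASES.index(new)] - m.entries[pos, BASES.index(old)]
        assert after - before == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- scanning

def brute_force_scan(matrix, genome, circular, strands):
    """Independent window-extraction oracle: slice strings, score each."""
    W = matrix.width
    g = genome + genome[: W - 1] if circular else genome
    n = len(genome) if circular else len(genome) - W + 1
    energies = []
    for i in range(n):
        win = g[i : i + W]
        if any(c not in BASES for c in win):
            continue
        energies.append(score_sequence(matrix, win))
        if strands == "both":
            energies.append(score_sequence(matrix, revcomp(win)))
    return energies


class TestScanGenome:
    def test_uniform_matrix_every_window_scores_width(self):
        m = EnergyMatrix(entries=np.ones((41, 4)))
        genome = generate_random_genome(seed=3, length=100)
        scan = scan_genome(m, genome, circular=True, strands="both")
        assert np.allclose(scan.energies, 41.0)
        assert scan.mean == pytest.approx(41.0)

    def test_linear_forward_windows_match_hand_extraction(self):
        m = generate_toy_matrix(seed=5, width=41)
        genome = generate_random_genome(seed=9, length=45)
        scan = scan_genome(m, genome, circular=False, strands="forward")
        expected = brute_force_scan(m, genome, circular=False, strands="forward")
        assert scan.n_windows == 5
        assert np.allclose(sorted(scan.energies), sorted(expected))

    @pytest.mark.parametrize("circular", [True, False])
    @pytest.mark.parametrize("strands", ["both", "forward"])
    def test_matches_brute_force_oracle(self, circular, strands):
        m = generate_toy_matrix(seed=2, width=6)
        genome = generate_random_genome(seed=4, length=60)
        scan = scan_genome(m, genome, circular=circular, strands=strands)
        expected = brute_force_scan(m, genome, circular, strands)
        assert scan.n_windows == len(expected)
        assert scan.mean == pytest.approx(np.mean(expected), rel=1e-12)

    def test_both_strands_circular_gives_2L_windows(self, random_genome):
        m = generate_toy_matrix(seed=1, width=41)
        scan = scan_genome(m, random_genome, circular=True, strands="both")
        assert scan.n_windows == 2 * len(random_genome)

    def test_ambiguous_windows_skipped_and_counted(self):
        m = generate_toy_matrix(seed=1, width=5)
        genome = "ACGTACGTNNACGTACGTACG"
        scan = scan_genome(m, genome, circular=False, strands="forward")
        expected = brute_force_scan(m, genome, circular=False, strands="forward")
        assert scan.n_windows == len(expected)
        assert scan.n_skipped == (len(genome) - 5 + 1) - len(expected)

    def test_genome_shorter_than_width_rejected(self):
        m = generate_toy_matrix(seed=1, width=41)
        with pytest.raises(DimensionError):
            scan_genome(m, "ACGT")

    def test_windows_iterator_agrees_with_tsv_columns(self, tmp_path):
        m = generate_toy_matrix(seed=1, width=5)
        genome = generate_random_genome(seed=2, length=20)
        scan = scan_genome(m, genome, circular=True, strands="both")
        rows = list(scan.windows())
        assert len(rows) == scan.n_windows
        out = tmp_path / "scan.tsv"
        scan.to_tsv(out)
        assert out.read_text().count("\n") == scan.n_windows + 1


# ---------------------------------------------------------------- calibration

def make_refs(matrix, genome):
    """Pick a WT-anchor 41-mer from the genome that scores below the mean."""
    scan = scan_genome(matrix, genome, circular=True, strands="both")
    idx = int(np.nanargmin(scan.forward))
    W = matrix.width
    g = genome + genome[: W - 1]
    wt = PromoterSequence(g[idx : idx + W], id="anchor")
    return CalibrationRefs(wt_lac_sequence=wt, wt_lac_specific_energy_kbt=-5.0)


class TestCalibrate:
    def test_genome_mean_is_zero_after_calibration(self, random_genome):
        raw = EnergyMatrix(entries=generate_toy_matrix(seed=13, width=41).entries + 2.0)
        refs = make_refs(raw, random_genome)
        cal, _ = calibrate(raw, random_genome, refs)
        span = np.ptp(scan_genome(raw, random_genome).energies)
        mean = scan_genome(cal, random_genome, circular=True, strands="both").mean
        assert abs(mean) <= 1e-9 * max(span, 1.0)
        assert cal.units == "kBT" and cal.offset_state == "genome_zeroed"

    def test_wt_anchor_scores_reference_energy_exactly(self, random_genome):
        raw = EnergyMatrix(entries=generate_toy_matrix(seed=13, width=41).entries + 2.0)
        refs = make_refs(raw, random_genome)
        cal, done = calibrate(raw, random_genome, refs)
        assert score_sequence(cal, refs.wt_lac_sequence) == pytest.approx(-5.0, abs=1e-9)
        assert done.conversion_au_per_kbt > 0

    def test_affine_transform_matches_hand_computation(self):
        """Toy 60 bp genome: calibration is the affine map (E - mean)/conversion."""
        raw = generate_toy_matrix(seed=21, width=6)
        raw = EnergyMatrix(entries=raw.entries)  # units AU
        genome = generate_random_genome(seed=22, length=60)
        refs = make_refs(raw, genome)
        cal, done = calibrate(raw, genome, refs)
        mean_au = scan_genome(raw, genome).mean
        wt_au = score_sequence(raw, refs.wt_lac_sequence)
        conversion = (mean_au - wt_au) / 5.0
        assert done.genome_mean_au == pytest.approx(mean_au)
        assert done.conversion_au_per_kbt == pytest.approx(conversion)
        for probe in ("ACGTAC", "TTTTTT", "GATTAC"):
            expected = (score_sequence(raw, probe) - mean_au) / conversion
            assert score_sequence(cal, probe) == pytest.approx(expected, abs=1e-12)
            assert done.au_to_kbt(score_sequence(raw, probe)) == pytest.approx(expected)

    def test_energy_differences_are_units_invariant(self, random_genome):
        raw = EnergyMatrix(entries=generate_toy_matrix(seed=31, width=41).entries * 7.0 + 3.0)
        refs = make_refs(raw, random_genome)
        cal, done = calibrate(raw, random_genome, refs)
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list(BASES), size=41))
            b = "".join(rng.choice(list(BASES), size=41))
            diff_au = score_sequence(raw, a) - score_sequence(raw, b)
            diff_kbt = score_sequence(cal, a) - score_sequence(cal, b)
            assert diff_kbt == pytest.approx(diff_au / done.conversion_au_per_kbt, abs=1e-9)

    def test_degenerate_anchor_rejected(self):
        raw = EnergyMatrix(entries=np.ones((5, 4)))  # every sequence scores 5
        genome = generate_random_genome(seed=1, length=50)
        refs = CalibrationRefs(
            wt_lac_sequence=PromoterSequence("ACGTA"), wt_lac_specific_energy_kbt=-5.0
        )
        with pytest.raises(DegenerateCalibrationError):
            calibrate(raw, genome, refs)


def test_encode_maps_acgt_and_flags_others():
    assert list(encode("ACGTacgtN")) == [0, 1, 2, 3, 0, 1, 2, 3, -1]
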