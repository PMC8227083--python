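"""Progressive MSA, Clustal symbols and the percent conservation score."""

import shutil
import subprocess

import numpy as np
import pytest

from ltp_epimap.conservation import (
    conservation_profile,
    conservation_symbols,
    distance_matrix,
    eq1_scores,
    fully_conserved_count,
)
from ltp_epimap.msa import MultipleAlignment, progressive_msa, read_aligned_fasta, write_aligned_fasta
from ltp_epimap.seq_io import SequenceRecord, write_fasta
from ltp_epimap.synthetic import DEFAULT_CYSTEINES, FamilySpec, generate_family


def msa_from_rows(*rows):
    return MultipleAlignment(tuple(f"r{i}" for i in range(len(rows))), tuple(rows))


class TestProgressiveMsa:
    def test_requires_two_records(self):
        with pytest.raises(ValueError):
            progressive_msa([SequenceRecord("a", "", "ACDE")])

    def test_identical_sequences_gap_free(self):
        records = [SequenceRecord(x, "", "ACDEFGHIKL") for x in "ab"]
        msa = progressive_msa(records)
        assert msa.rows == ("ACDEFGHIKL", "ACDEFGHIKL")

    def test_single_insertion_gets_single_gap_run(self):
        # the three-residue insertion should align as one contiguous gap run,
        # exactly as the optimal pairwise alignment places it
        from ltp_epimap.homology import pairwise_align

        a, b = "ACDEFGHIKL", "ACDEWWWFGHIKL"
        msa = progressive_msa([SequenceRecord("a", "", a), SequenceRecord("b", "", b)])
        assert msa.rows == pairwise_align(a, b)

    def test_degapping_recovers_inputs_row_order_preserved(self):
        spec = FamilySpec(n_descendants=5, target_identity=0.6, seed=3)
        records, _ = generate_family(spec)
        msa = progressive_msa(records)
        assert msa.ids == tuple(r.id for r in records)
        for record in records:
            assert msa.degapped(record.id) == record.residues

    def test_cysteine_scaffold_columns_fully_conserved(self):
        spec = FamilySpec(n_descendants=9, target_identity=0.7, seed=11)
        records, _ = generate_family(spec)
        msa = progressive_msa(records)
        symbols = conservation_symbols(msa)
        reference = msa.row("ancestor")
        # map each scaffold position through the (gapless here) reference row
        scores = {r.position: r for r in eq1_scores(msa, "ancestor")}
        for pos in DEFAULT_CYSTEINES:
            assert scores[pos].residue == "C"
            assert scores[pos].score == 100.0
            assert symbols[scores[pos].column] == "*"

    def test_agrees_with_mafft_on_cysteine_columns(self, tmp_path):
        """Independent cross-check: an external aligner also recovers the
        eight invariant cysteine columns on a synthetic family."""
        mafft = shutil.which("mafft")
        assert mafft is not None, "mafft expected on PATH for this cross-check"
        records, _ = generate_family(FamilySpec(n_descendants=8, target_identity=0.65, seed=5))
        fasta = tmp_path / "family.fasta"
        write_fasta(records, fasta)
        result = subprocess.run(
            [mafft, "--auto", str(fasta)], capture_output=True, text=True, check=True
        )
        out = tmp_path / "mafft.afa"
        out.write_text(result.stdout)
        theirs = read_aligned_fasta(out)
        ours = progressive_msa(records)
        for msa in (ours, theirs):
            stars = [j for j, s in enumerate(conservation_symbols(msa)) if s == "*"]
            cys_cols = [
                j for j in stars if set(msa.column(j)) == {"C"}
            ]
            assert len(cys_cols) >= len(DEFAULT_CYSTEINES)

    def test_round_trip_aligned_fasta(self, tmp_path):
        records, _ = generate_family(FamilySpec(n_descendants=3, seed=2))
        msa = progressive_msa(records)
        path = tmp_path / "aln.afa"
        write_aligned_fasta(msa, path)
        assert read_aligned_fasta(path) == msa


class TestConservationSymbols:
    @pytest.mark.parametrize(
        "column,symbol",
        [
            ("AAA", "*"),
            ("ILV", ":"),  # MILV strong group
            ("STA", ":"),
            ("NEQK", ":"),
            ("CSA", "."),  # weak group only
            ("ATV", "."),
            ("AW", " "),
            ("A-A", " "),  # any gap disqualifies
        ],
    )
    def test_symbol_assignment(self, column, symbol):
        # build a 1-column MSA whose rows are the column characters
        msa = MultipleAlignment(
            tuple(f"r{i}" for i in range(len(column))), tuple(column)
        )
        assert conservation_symbols(msa)[0] == symbol

    def test_invariant_under_row_reordering(self):
        records, _ = generate_family(FamilySpec(n_descendants=6, seed=9))
        msa = progressive_msa(records)
        shuffled = msa.reorder(tuple(reversed(msa.ids)))
        assert conservation_symbols(shuffled) == conservation_symbols(msa)


class TestEq1Score:
    def build(self, counts, n=15, residue="Y", other="A"):
        """One-column MSA with `counts` rows carrying `residue`."""
        rows = tuple([residue] * counts + [other] * (n - counts))
        return MultipleAlignment(tuple(f"r{i}" for i in range(n)), rows)

    @pytest.mark.parametrize(
        "count,n,exact,floored",
        [(15, 15, 100.0, 100), (14, 15, 93.3333, 93), (2, 15, 13.3333, 13)],
    )
    def test_printed_range_cases(self, count, n, exact, floored):
        msa = self.build(count, n)
        (score,) = eq1_scores(msa, "r0")
        assert score.score == pytest.approx(exact, abs=1e-3)
        assert score.score_floor == floored

    def test_scores_are_multiples_of_100_over_n(self):
        records, _ = generate_family(FamilySpec(n_descendants=7, seed=21))
        msa = progressive_msa(records)
        n = msa.n_rows
        allowed = {k * 100.0 / n for k in range(n + 1)}
        for res in eq1_scores(msa, "ancestor"):
            assert any(abs(res.score - v) < 1e-9 for v in allowed)

    def test_score_100_iff_star_symbol(self):
        records, _ = generate_family(FamilySpec(n_descendants=7, seed=22))
        msa = progressive_msa(records)
        for res in eq1_scores(msa, "ancestor"):
            assert (res.score == 100.0) == (res.symbol == "*")

    def test_gaps_never_count_as_matches(self):
        msa = MultipleAlignment(("a", "b", "c"), ("A", "-", "A"))
        (score,) = eq1_scores(msa, "a")
        assert score.score == pytest.approx(200.0 / 3)

    def test_missing_reference_errors(self):
        msa = msa_from_rows("AC", "AC")
        with pytest.raises(KeyError):
            eq1_scores(msa, "nope")

    def test_fixed_panel_denominator(self):
        # scoring a 3-row alignment against the conventional 15-LTP panel size
        msa = MultipleAlignment(("a", "b", "c"), ("A", "A", "A"))
        (score,) = eq1_scores(msa, "a", n_total=15)
        assert score.score == pytest.approx(20.0)

    def test_profile_table_has_display_floor(self):
        msa = self.build(14, 15)
        profile = conservation_profile(msa, "r0")
        frame = profile.to_frame()
        assert list(frame.columns) == [
            "position", "residue", "column", "symbol", "eq1_score", "eq1_score_floor",
        ]
        assert frame.loc[0, "eq1_score_floor"] == 93

    def test_fully_conserved_count_on_known_alignment(self):
        msa = MultipleAlignment(("a", "b"), ("ACDE", "ACDW"))
        assert fully_conserved_count(msa, "a") == 3


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = msa_from_rows("ACDE", "ACDE")
        assert distance_matrix(msa)[0, 1] == 0.0

    def test_one_in_ten_difference(self):
        msa = msa_from_rows("ACDEFGHIKL", "ACDEFGHIKV")
        assert distance_matrix(msa)[0, 1] == pytest.approx(0.1)

    def test_gapped_columns_excluded(self):
        msa = msa_from_rows("AC-E", "ACDE")
        assert distance_matrix(msa)[0, 1] == 0.0

    def test_symmetric_zero_diagonal(self):
        records, _ = generate_family(FamilySpec(n_descendants=5, seed=4))
        msa = progressive_msa(records)
        d = distance_matrix(msa)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_no_comparable_columns_errors(self):
        msa = msa_from_rows("A-", "-C")
        with pytest.raises(ValueError, match="no gap-free columns"):
            distance_matrix(msa)
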