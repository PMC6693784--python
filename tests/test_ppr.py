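"""PPR motif arrays, upstream windows and combinatorial-code scoring."""

from itertools import product

import numpy as np
import pytest

from orgedit.errors import CoordinateError, ValidationError
from orgedit.ppr import (
    CodeTable,
    PPRMotif,
    PPRProtein,
    extract_window,
    load_ppr,
    rank_candidate_sites,
    score_alignment,
)


def make_protein(pairs, types=None):
    """Protein from (aa6, aa1prime) pairs, plus the E1/E2/DYW tail."""
    motifs = [
        PPRMotif(index=i + 1, motif_type=(types[i] if types else "P"), aa6=a, aa1prime=b)
        for i, (a, b) in enumerate(pairs)
    ]
    motifs += [
        PPRMotif(index=len(pairs) + 1, motif_type="E1", aa6=None, aa1prime=None),
        PPRMotif(index=len(pairs) + 2, motif_type="E2", aa6=None, aa1prime=None),
        PPRMotif(index=len(pairs) + 3, motif_type="DYW", aa6=None, aa1prime=None),
    ]
    return PPRProtein(protein_id="toy", motifs=tuple(motifs))


class TestLoadPpr:
    def _write(self, tmp_path, rows):
        path = tmp_path / "motifs.tsv"
        path.write_text("index\ttype\taa6\taa1prime\n" + "".join(rows))
        return path

    def test_eleven_array_motifs(self, tmp_path):
        """An EMP21-like array: 11 P/L/S motifs followed by E1, E2, DYW."""
        types = ["P1", "L1", "S1", "P1", "L1", "S1", "P2", "L2", "S2", "P1", "S1"]
        rows = [f"{i + 1}\t{t}\tT\tD\n" for i, t in enumerate(types)]
        rows += ["12\tE1\t-\t-\n", "13\tE2\t-\t-\n", "14\tDYW\t-\t-\n"]
        protein = load_ppr(self._write(tmp_path, rows))
        assert len(protein.array_motifs) == 11
        assert len(protein.motifs) == 14

    def test_missing_last_aa1prime_accepted_with_flag(self, tmp_path):
        rows = ["1\tP\tT\tD\n", "2\tS\tN\t-\n"]
        with pytest.warns(UserWarning, match="no aa1'"):
            protein = load_ppr(self._write(tmp_path, rows))
        assert protein.array_motifs[-1].aa1prime is None

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="empty"):
            load_ppr(self._write(tmp_path, []))

    def test_invalid_residue_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="invalid residue"):
            load_ppr(self._write(tmp_path, ["1\tP\tZ\tD\n"]))

    def test_shipped_code_table_loads(self):
        code = CodeTable.default()
        assert code.top("T", "D") == "G"
        assert code.top("N", "D") == "T"


class TestExtractWindow:
    def test_window_indices(self):
        """Site at CDS position 20: window is positions 6..16 (1-based)."""
        seq = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        assert extract_window(seq, 20) == seq[5:16]
        assert len(extract_window(seq, 20)) == 11

    def test_insufficient_upstream_context(self):
        with pytest.raises(CoordinateError, match="upstream"):
            extract_window("A" * 30, 10)

    def test_shorter_array_window(self):
        seq = "ABCDEFGHIJKLMNOPQRST"
        # 5-motif array covers -8..-4: positions 12..16 for a site at 20
        assert extract_window(seq, 20, array_length=5) == seq[11:16]

    def test_minimum_position(self):
        assert len(extract_window("A" * 20, 15)) == 11
        with pytest.raises(CoordinateError):
            extract_window("A" * 20, 14)


class TestScoreAlignment:
    def test_perfect_match(self):
        protein = make_protein([("T", "D")] * 11)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        match = score_alignment(protein, "G" * 11, code)
        assert match.score == 1.0
        assert match.label_string == "M" * 11

    def test_total_mismatch(self):
        protein = make_protein([("T", "D")] * 11)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        assert score_alignment(protein, "A" * 11, code).score == 0.0

    def test_all_pairs_absent_scores_zero(self):
        protein = make_protein([("W", "W")] * 11)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        match = score_alignment(protein, "G" * 11, code)
        assert match.score == 0.0
        assert match.label_string == "." * 11

    def test_partial_weight(self):
        protein = make_protein([("T", "D")] * 2)
        code = CodeTable({("T", "D"): {"G": 0.8, "A": 0.2}})
        match = score_alignment(protein, "GA", code)
        assert match.score == pytest.approx((1.0 + 0.5) / 2)
        assert match.label_string == "Mp"

    def test_register_c_terminal_motif_pairs_with_minus_four(self):
        """Only the last array motif predicts; it must read the -4 nucleotide."""
        pairs = [("W", "W")] * 4 + [("T", "D")]
        protein = make_protein(pairs)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        assert score_alignment(protein, "AAAAG", code).score == 1.0
        assert score_alignment(protein, "GAAAA", code).score == 0.0

    def test_length_mismatch_rejected(self):
        protein = make_protein([("T", "D")] * 5)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        with pytest.raises(ValidationError, match="length"):
            score_alignment(protein, "G" * 11, code)

    def test_motif_type_mask(self):
        protein = make_protein([("T", "D")] * 4, types=["P", "L", "P", "L"])
        code = CodeTable({("T", "D"): {"G": 1.0}})
        match = score_alignment(protein, "GAGA", code, motif_type_mask={"P"})
        assert match.label_string == "M.M."
        assert match.score == 1.0  # both predicted positions match

    def test_single_entry_table_closed_form(self):
        """With one code entry the score is the match fraction over that entry."""
        rng = np.random.default_rng(8)
        pairs = [("T", "D") if rng.random() < 0.5 else ("W", "W") for _ in range(9)]
        protein = make_protein(pairs)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        window = "".join(rng.choice(list("ACGT"), size=9))
        predicted = [i for i, p in enumerate(pairs) if p == ("T", "D")]
        expected = (
            sum(window[i] == "G" for i in predicted) / len(predicted) if predicted else 0.0
        )
        assert score_alignment(protein, window, code).score == pytest.approx(expected)


def oracle_score(pairs, window, table):
    """Independent per-position re-scoring by direct dictionary walks."""
    points, predicted = [], 0
    for (aa6, aa1p), nt in zip(pairs, window):
        prefs = table.get((aa6, aa1p), {})
        if not prefs:
            continue
        predicted += 1
        best = sorted(prefs.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if nt == best:
            points.append(1.0)
        elif nt in prefs:
            points.append(0.5)
        else:
            points.append(0.0)
    return sum(points) / predicted if predicted else 0.0


class TestEnumerationOracle:
    def test_all_windows_of_a_five_motif_array(self):
        """Exhaustive 4^5 window enumeration agrees with an independent scorer."""
        table = {
            ("T", "D"): {"G": 0.9},
            ("T", "N"): {"A": 0.7, "G": 0.2},
            ("N", "D"): {"T": 0.6, "C": 0.3},
            ("N", "S"): {"C": 0.8},
        }
        pairs = [("T", "D"), ("T", "N"), ("N", "D"), ("N", "S"), ("Q", "Q")]
        protein = make_protein(pairs)
        code = CodeTable(table)
        for window_tuple in product("ACGT", repeat=5):
            window = "".join(window_tuple)
            assert score_alignment(protein, window, code).score == pytest.approx(
                oracle_score(pairs, window, table)
            )


class TestRanking:
    def test_rank_order_and_ties(self):
        protein = make_protein([("T", "D")] * 3)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        sites = [
            (("b", 30), "GGG"),
            (("a", 20), "GAG"),
            (("c", 25), "AAA"),
            (("a", 30), "GGA"),  # ties with ("a", 20) at 2/3
        ]
        ranked = rank_candidate_sites(protein, sites, code)
        assert ranked["score"].tolist() == sorted(ranked["score"], reverse=True)
        assert ranked.iloc[0]["gene"] == "b"

    def test_tie_broken_lexicographically(self):
        protein = make_protein([("T", "D")] * 3)
        code = CodeTable({("T", "D"): {"G": 1.0}})
        sites = [(("z", 5), "GGA"), (("a", 9), "AGG"), (("a", 7), "GAG")]
        ranked = rank_candidate_sites(protein, sites, code)
        assert list(zip(ranked["gene"], ranked["position"])) == [
            ("a", 7), ("a", 9), ("z", 5)
        ]

    def test_planted_best_match_ranks_first_among_decoys(self):
        rng = np.random.default_rng(55)
        pairs = [("T", "D"), ("T", "N"), ("N", "D"), ("N", "S"), ("S", "N")]
        protein = make_protein(pairs)
        code = CodeTable(
            {
                ("T", "D"): {"G": 0.9},
                ("T", "N"): {"A": 0.8},
                ("N", "D"): {"T": 0.7},
                ("N", "S"): {"C": 0.8},
                ("S", "N"): {"A": 0.8},
            }
        )
        planted = "GATCA"  # top prediction at every position
        sites = [(("target", 100), planted)]
        for i in range(100):
            decoy = "".join(rng.choice(list("ACGT"), size=5))
            while decoy == planted:
                decoy = "".join(rng.choice(list("ACGT"), size=5))
            sites.append(((f"decoy{i:03d}", i + 20), decoy))
        ranked = rank_candidate_sites(protein, sites, code)
        assert ranked.iloc[0]["gene"] == "target"
        assert ranked.iloc[0]["score"] == 1.0
        # permuting input order never changes the ranking
        perm = [sites[i] for i in rng.permutation(len(sites))]
        assert rank_candidate_sites(protein, perm, code).equals(ranked)
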