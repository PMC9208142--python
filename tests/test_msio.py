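"""I/O, decoy generation and prefilter behaviour."""

import gzip

import numpy as np
import pytest

from proteofdr import msio
from proteofdr.msio import Psm, PsmTable

from helpers import make_table


@pytest.fixture
def fasta(tmp_path):
    def write(text, name="db.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return write


class TestReadFasta:
    def test_basic_parse(self, fasta):
        db = msio.read_fasta(fasta(">P1\nMKV\n>P2\nAAAA\n"))
        assert [(r.accession, r.sequence) for r in db] == [("P1", "MKV"), ("P2", "AAAA")]
        assert not any(r.is_decoy for r in db)

    def test_decoy_and_contaminant_prefixes(self, fasta):
        db = msio.read_fasta(fasta(">rev_P1\nVKM\n>CON_TRYP\nMKR\n"))
        assert db[0].is_decoy and not db[0].is_contaminant
        assert db[1].is_contaminant and not db[1].is_decoy

    def test_lowercase_uppercased_and_wrapping_roundtrip(self, fasta, tmp_path):
        db = msio.read_fasta(fasta(">P1\nmkv\n"))
        assert db[0].sequence == "MKV"
        long = [msio.ProteinRecord("PX", "ACDEFGHIKLMNPQRSTVWY" * 7)]
        out = tmp_path / "out.fasta"
        msio.write_fasta(long, out)
        lines = out.read_text().splitlines()
        assert max(len(l) for l in lines[1:]) == 60
        assert msio.read_fasta(out)[0].sequence == long[0].sequence

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "db.fasta.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">P1\nMKV\n")
        assert msio.read_fasta(p)[0].accession == "P1"

    def test_duplicate_accession_error(self, fasta):
        with pytest.raises(ValueError, match="P1"):
            msio.read_fasta(fasta(">P1\nMKV\n>P1\nAA\n"))

    def test_bad_residue_error_names_line(self, fasta):
        with pytest.raises(ValueError, match="line 4"):
            msio.read_fasta(fasta(">P1\nMKV\n>P2\nMK1V\n"))

    def test_empty_file_error(self, fasta):
        with pytest.raises(ValueError, match="no FASTA"):
            msio.read_fasta(fasta(""))


class TestGenerateDecoys:
    def test_reversal_palindrome_and_size(self):
        db = [
            msio.ProteinRecord("P1", "MKVR"),
            msio.ProteinRecord("P2", "ABA"),
            msio.ProteinRecord("P3", "WW"),
        ]
        decoys = msio.generate_decoys(db)
        assert [d.accession for d in decoys] == ["rev_P1", "rev_P2", "rev_P3"]
        assert decoys[0].sequence == "RVKM"
        assert decoys[1].sequence == "ABA"  # palindrome: same residues, new accession
        assert len(decoys) == len(db)

    def test_reversal_involution_and_composition(self):
        rng = np.random.default_rng(0)
        db = [
            msio.ProteinRecord(
                f"P{i}", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
            )
            for i in range(20)
        ]
        decoys = msio.generate_decoys(db)
        for t, d in zip(db, decoys):
            assert sorted(t.sequence) == sorted(d.sequence)
            assert d.sequence[::-1] == t.sequence

    def test_rejects_existing_decoys(self):
        db = [msio.ProteinRecord("rev_P1", "MKV", is_decoy=True)]
        with pytest.raises(ValueError, match="decoy"):
            msio.generate_decoys(db)


class TestPsmTable:
    def test_read_infers_decoy_from_prefix(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(
            "spectrum_id\tpeptide\tproteins\tscore\n"
            "s1\tPEPTIDEK\tP1;P2\t45.2\n"
            "s2\tKEDITPEP\trev_P1\t12.0\n"
        )
        t = msio.read_psm_table(p)
        assert t.psms[0].proteins == frozenset({"P1", "P2"})
        assert not t.psms[0].is_decoy
        assert t.psms[1].is_decoy

    def test_mixed_target_decoy_resolved_to_target(self, tmp_path):
        p = tmp_path / "psms.tsv"
        p.write_text(
            "spectrum_id\tpeptide\tproteins\tscore\ns1\tPEPTIDEK\tP1;rev_P2\t40\n"
        )
        psm = msio.read_psm_table(p).psms[0]
        assert not psm.is_decoy
        assert psm.proteins == frozenset({"P1"})

    @pytest.mark.parametrize(
        "body,match",
        [
            ("spectrum_id\tpeptide\tscore\ns1\tPEPTIDEK\t4\n", "proteins"),
            ("spectrum_id\tpeptide\tproteins\tscore\ns1\tPEPTIDEK\tP1\tbad\n", "row 1"),
            ("spectrum_id\tpeptide\tproteins\tscore\ns1\tPEPTIDEK\t\t4\n", "row 1"),
        ],
    )
    def test_malformed_input_errors(self, tmp_path, body, match):
        p = tmp_path / "psms.tsv"
        p.write_text(body)
        with pytest.raises(ValueError, match=match):
            msio.read_psm_table(p)

    def test_write_read_roundtrip(self, tmp_path):
        table = make_table([(False, 30.5), (True, 12.25), (False, 7.0)])
        out = tmp_path / "out.tsv"
        msio.write_psm_table(table, out)
        back = msio.read_psm_table(out)
        assert back.to_frame().equals(table.to_frame())


class TestPrefilters:
    def _table(self, groups):
        psms = []
        for sid, cands in groups.items():
            for i, (pep, score) in enumerate(cands):
                psms.append(
                    Psm(sid, pep, frozenset({f"P{sid}{i}"}), float(score))
                )
        return PsmTable(psms)

    def test_pretty_rank_tie_keeps_one_of_the_tied(self):
        table = self._table(
            {"q1": [("AAAAAAA", 50.00), ("CCCCCCC", 49.95), ("DDDDDDD", 30.0)]}
        )
        out = msio.apply_prefilters(table, seed=0)
        assert len(out) == 1
        assert out.psms[0].peptide in {"AAAAAAA", "CCCCCCC"}
        assert out.psms[0].rank == 1

    def test_short_peptide_drops_spectrum(self):
        table = self._table({"q1": [("AAAAAA", 40.0)]})  # length 6
        assert len(msio.apply_prefilters(table)) == 0

    def test_single_candidate_kept_unchanged(self):
        table = self._table({"q1": [("AAAAAAA", 12.0)]})
        out = msio.apply_prefilters(table)
        assert len(out) == 1 and out.psms[0].score == 12.0

    def test_boundary_tie_is_strict(self):
        # difference exactly 0.1 is NOT a tie
        table = self._table({"q1": [("AAAAAAA", 50.0), ("CCCCCCC", 49.9)]})
        out = msio.apply_prefilters(table, seed=1)
        assert out.psms[0].peptide == "AAAAAAA"

    def test_idempotent_and_unique_spectra(self):
        rng = np.random.default_rng(5)
        psms = []
        for s in range(40):
            for c in range(int(rng.integers(1, 6))):
                pep = "ACDEFGH" + "K" * int(rng.integers(0, 3))
                psms.append(
                    Psm(f"q{s}", pep, frozenset({f"P{c}"}), float(rng.normal(20, 5)))
                )
        once = msio.apply_prefilters(PsmTable(psms), seed=7)
        twice = msio.apply_prefilters(once, seed=7)
        ids = once.spectrum_ids()
        assert len(ids) == len(set(ids))
        assert twice.to_frame().equals(once.to_frame())

    def test_invalid_parameters(self):
        table = self._table({"q1": [("AAAAAAA", 1.0)]})
        with pytest.raises(ValueError):
            msio.apply_prefilters(table, tie_tolerance=-1)
        with pytest.raises(ValueError):
            msio.apply_prefilters(table, min_len=0)
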