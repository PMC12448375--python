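import numpy as np
import pytest

from corefucid.features import CIFeatureVector
from corefucid.spectra_io import (
    GlycoPSM,
    Spectrum,
    format_composition,
    parse_composition,
    read_feature_table,
    read_psm_table,
    read_spectra,
    write_feature_table,
    write_mgf,
    write_psm_table,
)

MGF_ONE_SPECTRUM = """BEGIN IONS
TITLE=scan_A
PEPMASS=812.34
CHARGE=2+
300.1 10.0
100.5 5.0
900.9 1.0
END IONS
"""


class TestSpectrum:
    def test_peaks_sorted_on_construction(self):
        s = Spectrum("s", mz=[3.0, 1.0, 2.0], intensity=[30.0, 10.0, 20.0])
        assert list(s.mz) == [1.0, 2.0, 3.0]
        assert list(s.intensity) == [10.0, 20.0, 30.0]

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Spectrum("s", mz=[1.0], intensity=[-1.0])


class TestMgf:
    def test_round_trip_fixture(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(MGF_ONE_SPECTRUM)
        spectra = list(read_spectra(path))
        assert len(spectra) == 1
        s = spectra[0]
        assert s.scan_id == "scan_A"
        assert s.n_peaks == 3
        assert s.precursor_mz == pytest.approx(812.34)
        assert s.precursor_charge == 2
        # unsorted input is sorted on load
        assert list(s.mz) == sorted(s.mz)

    def test_empty_file_empty_stream(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert list(read_spectra(path)) == []

    def test_write_then_read_is_identity(self, tmp_path):
        orig = [
            Spectrum("a", mz=[100.0, 200.0], intensity=[1.0, 2.0],
                     precursor_mz=500.0, precursor_charge=2),
            Spectrum("b", mz=[150.0], intensity=[3.0]),
        ]
        path = tmp_path / "rt.mgf"
        write_mgf(orig, path)
        back = list(read_spectra(path))
        assert [s.scan_id for s in back] == ["a", "b"]
        for o, r in zip(orig, back):
            np.testing.assert_allclose(r.mz, o.mz)
            np.testing.assert_allclose(r.intensity, o.intensity)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unsupported"):
            list(read_spectra(tmp_path / "x.raw"))


class TestComposition:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("HexNAc2Hex5Fuc1", {"HexNAc": 2, "Hex": 5, "Fuc": 1}),
            ("HexNAc2Hex3", {"HexNAc": 2, "Hex": 3}),
            ("Hex", {"Hex": 1}),
            ("", {}),
        ],
    )
    def test_parse(self, text, expected):
        assert parse_composition(text) == expected

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            parse_composition("Xyl2")

    def test_format_round_trip(self):
        comp = {"HexNAc": 2, "Hex": 5, "Fuc": 1}
        assert parse_composition(format_composition(comp)) == comp


class TestPsmTable:
    def _write(self, tmp_path, rows):
        header = "scan_id\tpeptide\tpeptide_mass\tglycan_composition\tstructure_annotation\tsource_tag"
        path = tmp_path / "psms.tsv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_basic_row(self, tmp_path):
        path = self._write(tmp_path, ["scan1\tPEPTIDE\t\tHexNAc2Hex5Fuc1\t\tFUT8_KO"])
        (psm,) = read_psm_table(path)
        assert psm.scan_id == "scan1"
        assert psm.peptide == "PEPTIDE"
        assert psm.peptide_mass is None
        assert psm.composition_count("Hex") == 5
        assert psm.composition_count("Fuc") == 1
        assert psm.source_tag == "FUT8_KO"

    def test_absent_monosaccharide_counts_zero(self, tmp_path):
        path = self._write(tmp_path, ["s\tPEP\t\tHexNAc2Hex3\t\tWILD_TYPE"])
        (psm,) = read_psm_table(path)
        assert psm.composition_count("Fuc") == 0

    def test_row_without_peptide_and_mass_skipped(self, tmp_path, caplog):
        path = self._write(
            tmp_path,
            ["ok\tPEP\t\tHex2\t\tOTHER", "bad\t\t\tHex2\t\tOTHER"],
        )
        with caplog.at_level("WARNING", logger="corefucid"):
            psms = read_psm_table(path)
        assert [p.scan_id for p in psms] == ["ok"]
        assert "skipped 1" in caplog.text

    def test_duplicate_scan_ids_both_kept_with_warning(self, tmp_path, caplog):
        path = self._write(
            tmp_path, ["dup\tPEP\t\tHex2\t\tOTHER", "dup\tPEP\t\tHex3\t\tOTHER"]
        )
        with caplog.at_level("WARNING", logger="corefucid"):
            psms = read_psm_table(path)
        assert len(psms) == 2
        assert "duplicate scan_id" in caplog.text

    def test_write_read_round_trip(self, tmp_path):
        psms = [
            GlycoPSM("s1", peptide="PEP", glycan_composition={"Hex": 5, "HexNAc": 2},
                     structure_annotation="core_fucose", source_tag="WILD_TYPE"),
            GlycoPSM("s2", peptide_mass=1234.5678, glycan_composition={"Fuc": 1},
                     source_tag="FUT8_KO", id_fdr=0.003),
        ]
        path = tmp_path / "rt.tsv"
        write_psm_table(psms, path)
        back = read_psm_table(path)
        assert [vars(p) for p in back] == [vars(p) for p in psms]


class TestFeatureTable:
    def _vectors(self):
        x1 = np.array([0.5, 0.2, 0, 0, 0, 0.05, 0, 0, 0, 0])
        x2 = np.array([0.1] * 10)
        x3 = np.zeros(10)
        x3[0] = 1.0
        vecs = []
        for i, x in enumerate([x1, x2, x3]):
            v = CIFeatureVector(scan_id=f"v{i}", x=x)
            v.X = x / x.sum()
            v.label = "nCF" if i == 0 else None
            vecs.append(v)
        return vecs

    def test_round_trip_identity(self, tmp_path):
        orig = self._vectors()
        path = tmp_path / "features.tsv"
        write_feature_table(orig, path)
        back = read_feature_table(path)
        assert len(back) == 3
        for o, r in zip(orig, back):
            assert r.scan_id == o.scan_id
            np.testing.assert_array_equal(r.x, o.x)
            np.testing.assert_array_equal(r.X, o.X)
            np.testing.assert_array_equal(r.matched_mask, o.matched_mask)
            assert r.label == o.label

    def test_empty_list_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_feature_table([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("scan_id\tx1")

    def test_nan_forbidden(self, tmp_path):
        v = self._vectors()[0]
        v.X = np.full(10, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            write_feature_table([v], tmp_path / "bad.tsv")
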