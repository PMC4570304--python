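import numpy as np
import pandas as pd
import pytest

from lcmcs.evaluation import split_report
from lcmcs.spectra_io import (
    SpectrumSet,
    TargetVector,
    load_report,
    load_spectra,
    load_targets,
    save_report,
    save_spectra,
    save_targets,
)


def _write_wide(path, wavelengths, values, ids, site=None):
    cols = {"sample_id": ids}
    if site is not None:
        cols["site"] = site
    df = pd.DataFrame(cols)
    df = pd.concat(
        [df, pd.DataFrame(values, columns=[str(int(w)) for w in wavelengths])], axis=1
    )
    df.to_csv(path, index=False)


class TestLoadSpectra:
    def test_wide_full_grid_shape(self, tmp_path, rng):
        wl = np.arange(350.0, 2501.0)
        vals = rng.uniform(0.1, 0.9, size=(3, wl.size))
        _write_wide(tmp_path / "s.csv", wl, vals, ["a", "b", "c"])
        s = load_spectra(tmp_path / "s.csv")
        assert s.values.shape == (3, 2151)
        assert s.wavelengths[0] == 350 and s.wavelengths[-1] == 2500
        assert s.sample_ids == ["a", "b", "c"]

    def test_duplicate_wavelength_column_rejected(self, tmp_path):
        (tmp_path / "dup.csv").write_text(
            "sample_id,350,351,351\na,0.5,0.5,0.5\nb,0.4,0.4,0.4\n"
        )
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            load_spectra(tmp_path / "dup.csv")

    def test_long_equals_wide(self, tmp_path, rng):
        wl = np.arange(350.0, 360.0)
        vals = rng.uniform(0.1, 0.9, size=(3, wl.size))
        ids = ["s1", "s2", "s3"]
        _write_wide(tmp_path / "w.csv", wl, vals, ids)
        rows = [
            {"sample_id": ids[i], "wavelength": wl[j], "value": vals[i, j]}
            for i in range(3)
            for j in range(wl.size)
        ]
        pd.DataFrame(rows).to_csv(tmp_path / "l.csv", index=False)
        sw = load_spectra(tmp_path / "w.csv")
        sl = load_spectra(tmp_path / "l.csv", layout="long")
        np.testing.assert_array_equal(sw.wavelengths, sl.wavelengths)
        np.testing.assert_allclose(sw.values, sl.values, rtol=0, atol=0)
        assert sw.sample_ids == sl.sample_ids

    def test_non_uniform_grid_rejected(self, tmp_path):
        (tmp_path / "g.csv").write_text("sample_id,350,351,353\na,0.5,0.5,0.5\n")
        with pytest.raises(ValueError, match="non-uniform"):
            load_spectra(tmp_path / "g.csv")

    def test_save_load_round_trip(self, tmp_path, tiny_data):
        s = tiny_data[0]
        save_spectra(s, tmp_path / "rt.csv")
        s2 = load_spectra(tmp_path / "rt.csv")
        np.testing.assert_array_equal(s.wavelengths, s2.wavelengths)
        np.testing.assert_allclose(s.values, s2.values, atol=1e-12, rtol=0)
        assert s2.site == s.site


class TestInvariants:
    def test_reflectance_range_enforced(self):
        with pytest.raises(ValueError, match="out of"):
            SpectrumSet(np.arange(3.0), [[0.5, 1.5, 0.5]], ["a"])

    def test_wavelength_count_must_match(self):
        with pytest.raises(ValueError, match="columns"):
            SpectrumSet(np.arange(4.0), [[0.5, 0.5, 0.5]], ["a"])

    def test_target_alignment_by_id_not_position(self):
        s = SpectrumSet(np.arange(3.0), [[0.5] * 3, [0.6] * 3], ["a", "b"])
        t = TargetVector([2.0, 1.0], ["b", "a"])
        np.testing.assert_array_equal(t.aligned_to(s), [1.0, 2.0])

    def test_target_mismatch_is_hard_error(self):
        s = SpectrumSet(np.arange(3.0), [[0.5] * 3], ["a"])
        t = TargetVector([1.0], ["z"])
        with pytest.raises(ValueError, match="missing"):
            t.aligned_to(s)

    def test_targets_round_trip(self, tmp_path):
        t = TargetVector([12.63, 7.89, 18.70], ["a", "b", "c"])
        save_targets(t, tmp_path / "t.csv")
        t2 = load_targets(tmp_path / "t.csv")
        np.testing.assert_allclose(t.values, t2.values, atol=1e-12)


class TestReportIO:
    def test_round_trip_and_site_blocks(self, tmp_path, rng):
        y = rng.uniform(8, 18, 30)
        yhat = y + rng.normal(0, 0.5, 30)
        sites = ["C"] * 8 + ["R"] * 6 + ["F"] * 6 + ["C"] * 4 + ["R"] * 3 + ["F"] * 3
        rep = split_report(y[:20], yhat[:20], y[20:], yhat[20:],
                           sites_cal=sites[:20], sites_val=sites[20:],
                           metadata={"method": "PLS"})
        save_report(rep, tmp_path / "rep.json")
        rep2 = load_report(tmp_path / "rep.json")
        for split in ("calibration", "validation"):
            for site in rep.splits[split]:
                for k, v in rep.splits[split][site].items():
                    assert rep2.splits[split][site][k] == pytest.approx(v, abs=1e-12)
        assert {"C", "R", "F", "overall"} <= set(rep.splits["calibration"])
        assert (tmp_path / "rep.csv").exists()

    def test_empty_validation_block_marked(self, tmp_path, rng):
        y = rng.uniform(8, 18, 10)
        rep = split_report(y, y, [], [])
        assert rep.splits["validation"]["overall"]["n"] == 0
        save_report(rep, tmp_path / "e.json")
        assert load_report(tmp_path / "e.json").splits["validation"]["overall"]["n"] == 0
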