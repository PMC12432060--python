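"""Feature ingestion, alignment, blank subtraction, MS2 linkage, matching."""

import numpy as np
import pytest
from pyteomics import mgf as pymgf

from sulfoscreen.screening import (
    Feature,
    FilteringReport,
    MS2Spectrum,
    align_replicates,
    match_mass_list,
    read_features,
    read_spectra,
    require_ms2,
    subtract_background,
)


def _feature(fid, mz, rt, area=1e6, sample="s1"):
    return Feature(feature_id=fid, mz=mz, rt=rt, areas={sample: area})


def test_read_features_csv(tmp_path):
    path = tmp_path / "features.csv"
    path.write_text(
        "feature_id,mz,rt,sampleA,sampleB\n"
        "f1,204.9811,0.61,1e6,2e6\n"
        "f2,165.0555,5.3,3e5,\n"
        "f3,300.1,4.0,0,0\n"
    )
    features = read_features(path)
    assert len(features) == 3
    assert features[0].areas == {"sampleA": 1e6, "sampleB": 2e6}
    assert features[1].areas["sampleB"] == 0.0  # NaN -> 0


def test_read_features_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("feature_id,rt,sampleA\nf1,0.61,1e6\n")
    with pytest.raises(ValueError, match="mz"):
        read_features(path)


def test_read_mgf_round_trip(tmp_path):
    path = tmp_path / "two.mgf"
    entries = [
        {
            "m/z array": np.array([147.0451, 96.9595, 165.0555]),
            "intensity array": np.array([40.0, 90.0, 100.0]),
            "params": {"title": "spec1", "pepmass": 245.0114, "rtinseconds": 294.0},
        },
        {
            "m/z array": np.array([125.0243]),
            "intensity array": np.array([100.0]),
            "params": {"title": "spec2", "pepmass": 204.9811, "rtinseconds": 36.0},
        },
    ]
    pymgf.write(entries, str(path), file_mode="w")
    spectra = read_spectra(path)
    assert [s.spectrum_id for s in spectra] == ["spec1", "spec2"]
    assert spectra[0].precursor_mz == pytest.approx(245.0114)
    assert spectra[0].rt == pytest.approx(4.9)
    assert [p[0] for p in spectra[0].peaks] == sorted(p[0] for p in spectra[0].peaks)


def _write_minimal_mzml(path, precursor_mz, rt_min, mzs, intensities):
    """Emit a minimal mzML document (one MS2 spectrum, zlib-packed intensities)."""
    import base64
    import struct
    import zlib

    def pack(values, compress=False):
        raw = struct.pack(f"<{len(values)}d", *values)
        if compress:
            raw = zlib.compress(raw)
        return base64.b64encode(raw).decode()

    compression = (
        '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
    )
    path.write_text(f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="run1">
    <spectrumList count="1">
      <spectrum index="0" id="scan=1" defaultArrayLength="{len(mzs)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time"
                     value="{rt_min * 60.0}" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z"
                         value="{precursor_mz}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
            <binary>{pack(mzs)}</binary>
          </binaryDataArray>
          <binaryDataArray>
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            {compression}
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
            <binary>{pack(intensities, compress=True)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
    </spectrumList>
  </run>
</mzML>
""")


def test_read_mzml(tmp_path):
    path = tmp_path / "one.mzml"
    _write_minimal_mzml(path, 245.0114, 4.9, [96.9601, 165.0555], [100.0, 40.0])
    (spectrum,) = read_spectra(path)
    assert spectrum.spectrum_id == "scan=1"
    assert spectrum.precursor_mz == pytest.approx(245.0114)
    assert spectrum.rt == pytest.approx(4.9)
    assert spectrum.peaks == [
        (pytest.approx(96.9601), pytest.approx(100.0)),
        (pytest.approx(165.0555), pytest.approx(40.0)),
    ]


def test_read_spectra_rejects_unknown_container(tmp_path):
    path = tmp_path / "spectra.txt"
    path.write_text("not a spectrum file\n")
    with pytest.raises(ValueError, match="unsupported"):
        read_spectra(path)


def test_align_replicates_merges_within_tolerance():
    runs = [
        [_feature("a", 204.98108, 0.60, sample="run1")],
        [_feature("b", 204.98112, 0.61, sample="run2")],
        [_feature("c", 204.98110, 0.62, sample="run3")],
    ]
    consensus = align_replicates(runs, mz_tol=5, rt_tol=0.1)
    assert len(consensus) == 1
    assert set(consensus[0].areas) == {"run1", "run2", "run3"}
    assert consensus[0].mz == pytest.approx(204.9811, abs=1e-4)


def test_align_replicates_keeps_distant_features_apart():
    runs = [[_feature("a", 204.9811, 0.6), _feature("b", 204.9811 * (1 + 50e-6), 0.6)]]
    assert len(align_replicates(runs, mz_tol=5, rt_tol=0.1)) == 2
    assert align_replicates([], 5, 0.1) == []


def test_align_same_mz_different_rt_not_merged():
    runs = [[_feature("a", 300.0, 1.0)], [_feature("b", 300.0, 5.0)]]
    assert len(align_replicates(runs)) == 2


@pytest.mark.parametrize(
    "area,blank_area,kept",
    [(1e6, 1e5, True), (4e5, 1e5, False), (1e6, 0.0, True)],
)
def test_subtract_background_fold_rule(area, blank_area, kept):
    features = [_feature("f", 300.0, 2.0, area=area)]
    blanks = [_feature("b", 300.0, 2.0, area=blank_area, sample="blank")] if blank_area else []
    survivors = subtract_background(features, blanks, ratio_threshold=5)
    assert (len(survivors) == 1) is kept


def test_require_ms2_links_and_filters():
    features = [_feature(f"f{i}", 200.0 + i, 1.0) for i in range(10)]
    spectra = [
        MS2Spectrum(f"s{i}", 200.0 + i, 1.05, [(100.0, 1.0)]) for i in range(6)
    ]
    kept = require_ms2(features, spectra, precursor_tol=5, rt_window=0.2)
    assert len(kept) == 6
    assert kept[0].ms2_ids == ["s0"]
    # outside the RT window: dropped
    late = [MS2Spectrum("s", 200.0, 3.0, [(100.0, 1.0)])]
    assert require_ms2([_feature("f", 200.0, 1.0)], late) == []


def test_match_mass_list_best_candidate(suspect_db):
    results = match_mass_list([_feature("f", 204.9811, 0.6)], suspect_db, ppm_tol=5)
    assert len(results) == 1
    best_entry, err = results[0].best
    assert best_entry.aglycone_name == "phloroglucinol"
    assert best_entry.n_sulfates == 1
    assert abs(err) < 2


def test_match_mass_list_rejects_offset_feature(suspect_db):
    assert match_mass_list([_feature("f", 204.9811 + 0.02, 0.6)], suspect_db, ppm_tol=5) == []


def test_tightening_tolerance_never_adds_candidates(suspect_db):
    features = [_feature(f"f{i}", mz, 1.0) for i, mz in enumerate((204.9811, 165.0555, 408.9540))]
    loose = {r.feature.feature_id: {c.id for c, _ in r.candidates} for r in match_mass_list(features, suspect_db, 10)}
    tight = {r.feature.feature_id: {c.id for c, _ in r.candidates} for r in match_mass_list(features, suspect_db, 2)}
    for fid, ids in tight.items():
        assert ids <= loose[fid]


def test_filtering_report():
    report = FilteringReport()
    report.record("stage1", 100, 3)
    assert report.stages[0]["percent_removed"] == pytest.approx(97.0)
    with pytest.raises(ValueError, match="contractive"):
        report.record("stage2", 3, 5)
    text = report.to_json()
    assert '"n_removed": 97' in text


def test_feature_validation():
    with pytest.raises(ValueError):
        Feature(feature_id="f", mz=-1.0, rt=0.0)
    with pytest.raises(ValueError):
        Feature(feature_id="f", mz=100.0, rt=1.0, areas={"s": -5.0})
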