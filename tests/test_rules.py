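"""MS2 rule engine: sulfate diagnostics, site localization, annotation."""

import itertools

import pytest

from sulfoscreen.chem import IonConvention
from sulfoscreen.database import conjugate, sulfate
from sulfoscreen.rules import (
    Annotation,
    SulfateEvidence,
    annotate_match,
    assign_confidence,
    assign_isomer_indices,
    check_elution_order,
    count_so3_losses,
    detect_sulfate_ions,
    hso4_reference_mz,
    localize_sulfation,
    match_aglycone_fragments,
    so3_reference_mz,
)
from sulfoscreen.screening import Feature, MS2Spectrum, match_mass_list


def _spectrum(precursor, peak_mzs, rt=1.0):
    return MS2Spectrum("s", precursor, rt, [(mz, 100.0) for mz in peak_mzs])


def _entry(registry, aglycone, n_sulfates):
    by_name = {a.name: a for a in registry}
    base = conjugate(by_name[aglycone], None)
    return sulfate(base, n_sulfates) if n_sulfates else base


def test_reference_ion_mzs_follow_convention():
    assert so3_reference_mz() == pytest.approx(79.9568, abs=0.0005)
    assert hso4_reference_mz() == pytest.approx(96.9601, abs=0.0005)
    corrected = IonConvention(electron_correction=True)
    assert so3_reference_mz(corrected) - so3_reference_mz() == pytest.approx(0.0005486)


def test_detect_sulfate_ions():
    hso4_only = detect_sulfate_ions(_spectrum(245.0114, [165.0555, 96.9594]))
    assert hso4_only.hso4_ion and not hso4_only.so3_ion
    so3_only = detect_sulfate_ions(_spectrum(261.0064, [181.0505, 79.9565]))
    assert so3_only.so3_ion and not so3_only.hso4_ion
    empty = detect_sulfate_ions(MS2Spectrum("e", 245.0, 1.0, []))
    assert not empty.so3_ion and not empty.hso4_ion and empty.n_so3_losses == 0


def test_count_so3_losses_ladders():
    assert count_so3_losses(_spectrum(488.9115, [408.9536, 328.9972]), 488.9115) == 2
    assert count_so3_losses(_spectrum(204.9811, [125.0243]), 204.9811) == 1
    assert count_so3_losses(_spectrum(204.9811, [110.0]), 204.9811) == 0
    with pytest.raises(ValueError):
        count_so3_losses(_spectrum(60.0, []), 60.0)


def test_count_so3_losses_monotone_in_tolerance():
    spectrum = _spectrum(488.9115, [408.9536, 328.9972, 249.0403])
    counts = [count_so3_losses(spectrum, 488.9115, frag_tol=t) for t in (0.0001, 0.001, 0.005, 0.01)]
    assert counts == sorted(counts)


def test_match_aglycone_fragments(rule_library):
    rule = rule_library.get("phenyllactic acid")
    matched = match_aglycone_fragments(
        _spectrum(245.0114, [165.0555, 147.0451, 119.0501, 96.9595, 72.9926]), rule
    )
    assert {m[0] for m in matched} >= {"[M-H]-", "-H2O", "-H2O -CO"}
    assert len(matched) == 4
    rule = rule_library.get("hydroxyphenyllactic acid")
    matched = match_aglycone_fragments(
        _spectrum(261.0064, [261.0064, 181.0505, 163.0399, 135.0451, 119.0501, 79.9565]), rule
    )
    assert [m[1] for m in matched] == [181.0505, 163.0399, 135.0451, 119.0501]
    assert match_aglycone_fragments(_spectrum(245.0, [50.5]), rule) == []


def test_missing_rule_is_an_explicit_error():
    with pytest.raises(LookupError):
        match_aglycone_fragments(_spectrum(245.0, [100.0]), None)


def test_localize_sulfation_branches(registry):
    mono = _entry(registry, "hydroxyphenyllactic acid", 1)
    di = _entry(registry, "hydroxyphenyllactic acid", 2)
    profile = (1, 1)
    assert localize_sulfation(SulfateEvidence(False, True, 1), mono, profile)[0] == "aliphatic"
    assert localize_sulfation(SulfateEvidence(True, False, 1), mono, profile)[0] == "aromatic"
    assert localize_sulfation(SulfateEvidence(True, True, 2), di, profile)[0] == "both"
    call, warnings = localize_sulfation(SulfateEvidence(False, False, 1), mono, profile)
    assert call == "undetermined" and not warnings


def test_localize_sulfation_downgrades_impossible_site(registry):
    # coumaric acid has no aliphatic OH: an HSO4- call cannot stand
    entry = _entry(registry, "coumaric acid", 1)
    call, warnings = localize_sulfation(SulfateEvidence(False, True, 1), entry, (1, 0))
    assert call == "undetermined"
    assert warnings


@pytest.mark.parametrize(
    "so3,hso4,losses", list(itertools.product([False, True], [False, True], [0, 1]))
)
def test_localize_never_sites_unsulfated_candidates(registry, so3, hso4, losses):
    entry = _entry(registry, "phenol", 0)
    call, _ = localize_sulfation(SulfateEvidence(so3, hso4, losses), entry, (1, 0))
    assert call == "none"


def test_assign_confidence(registry):
    entry = _entry(registry, "phenyllactic acid", 1)
    full = [("a", 1.0, 1.0), ("b", 2.0, 2.0), ("c", 3.0, 3.0)]
    consistent = SulfateEvidence(False, True, 1)
    assert assign_confidence(full, consistent, entry) == 2
    assert assign_confidence(full[:1], consistent, entry) == 3  # single diagnostic
    silent = SulfateEvidence(False, False, 0)
    assert assign_confidence(full, silent, entry) == 3  # sulfate unsupported


def _annotate_row(row, suspect_db, rule_library, moiety_deltas):
    feature = Feature(feature_id=str(row.id), mz=row.experimental_mz, rt=row.rt_min)
    (match,) = match_mass_list([feature], suspect_db, ppm_tol=5)
    spectrum = MS2Spectrum(
        spectrum_id=f"ref{row.id}",
        precursor_mz=row.experimental_mz,
        rt=row.rt_min,
        peaks=[(mz, 100.0) for mz in row.diagnostic_ions],
    )
    return annotate_match(match, spectrum, rule_library, moiety_deltas)


def test_engine_reproduces_reference_annotations(
    reference_table, suspect_db, rule_library, moiety_deltas
):
    """All 44 curated spectra recover their aglycone and sulfation state."""
    for row in reference_table.itertuples():
        annotation = _annotate_row(row, suspect_db, rule_library, moiety_deltas)
        assert annotation.rule_name == row.base_aglycone, row.name
        assert annotation.candidate.n_sulfates == row.n_sulfates, row.name


def test_engine_separates_isobaric_scaffolds(
    reference_table, suspect_db, rule_library, moiety_deltas
):
    """Phenyllactic vs phloretic acid (both C9H10O3) resolve by fragments."""
    rows = {r.id: r for r in reference_table.itertuples()}
    assert _annotate_row(rows[35], suspect_db, rule_library, moiety_deltas).rule_name == "phenyllactic acid"
    assert _annotate_row(rows[39], suspect_db, rule_library, moiety_deltas).rule_name == "phloretic acid"


def _mk_annotation(registry, aglycone, n_sulfates, rt, rule_name=None):
    entry = _entry(registry, aglycone, n_sulfates)
    return Annotation(
        feature_id=f"{aglycone}-{n_sulfates}-{rt}",
        compound_name=entry.name,
        candidate=entry,
        ppm_error=0.0,
        rt=rt,
        site_call="none" if n_sulfates == 0 else "aromatic",
        matched_diagnostics=[],
        confidence_level=3,
        evidence=SulfateEvidence(n_sulfates > 0, False, 0),
        rule_name=rule_name or aglycone,
    )


def test_elution_order_hydroxyl_trend_unflagged(registry, rule_library):
    # more free OH elutes earlier: the expected reversed-phase trend
    annotations = [
        _mk_annotation(registry, "phloroglucinol", 1, 0.6),
        _mk_annotation(registry, "catechol", 1, 0.8),
        _mk_annotation(registry, "phenol", 1, 1.5),
    ]
    assert check_elution_order(annotations, rule_library) == []


def test_elution_order_sulfate_before_parent_unflagged(registry, rule_library):
    annotations = [
        _mk_annotation(registry, "phenyllactic acid", 1, 4.9),
        _mk_annotation(registry, "phenyllactic acid", 0, 5.3),
    ]
    assert check_elution_order(annotations, rule_library) == []


def test_elution_order_flags_sulfate_after_parent(registry, rule_library):
    # a sulfate eluting after both parent isomers is anomalous and flagged
    annotations = [
        _mk_annotation(registry, "scoparone", 0, 7.2),
        _mk_annotation(registry, "scoparone", 0, 7.7),
        _mk_annotation(registry, "scoparone", 1, 8.6),
    ]
    flags = check_elution_order(annotations, rule_library)
    assert len(flags) == 2  # later than both parents
    assert all("elutes after" in f for f in flags)


def test_assign_isomer_indices(registry):
    caffeic = [
        _mk_annotation(registry, "caffeic acid", 0, 6.2),
        _mk_annotation(registry, "caffeic acid", 0, 4.2),
    ]
    singleton = [_mk_annotation(registry, "phenol", 1, 1.5)]
    phloretic = [
        _mk_annotation(registry, "phenyllactic acid", 0, 6.7),
        _mk_annotation(registry, "phenyllactic acid", 0, 6.3),
        _mk_annotation(registry, "phenyllactic acid", 0, 7.3),
    ]
    assign_isomer_indices(caffeic + singleton + phloretic)
    assert [a.isomer_index for a in sorted(caffeic, key=lambda a: a.rt)] == [1, 2]
    assert singleton[0].isomer_index is None
    assert [a.isomer_index for a in sorted(phloretic, key=lambda a: a.rt)] == [1, 2, 3]
    assert "isomer 2" in sorted(caffeic, key=lambda a: a.rt)[1].display_name
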