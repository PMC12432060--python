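"""End-to-end screening + annotation orchestration.

Chains the filter cascade (replicate alignment, blank subtraction, the
MS2-required rule, mass-list matching) and the MS2 rule engine into one call,
recording stage counts in a :class:`~sulfoscreen.screening.FilteringReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .chem import IonConvention
from .database import SuspectDatabase, build_moieties
from .rules import (
    Annotation,
    RuleLibrary,
    annotate_match,
    assign_isomer_indices,
    check_elution_order,
)
from .screening import (
    DEFAULT_BLANK_RATIO,
    DEFAULT_PPM_TOL,
    DEFAULT_RT_TOL,
    Feature,
    FilteringReport,
    MatchResult,
    MS2Spectrum,
    align_replicates,
    match_mass_list,
    require_ms2,
    subtract_background,
)

__all__ = ["ScreeningResult", "run_screening"]


@dataclass
class ScreeningResult:
    features: list[Feature]
    matches: list[MatchResult]
    annotations: list[Annotation]
    report: FilteringReport
    rt_flags: list[str]


def run_screening(
    runs: Sequence[Sequence[Feature]],
    blank: Sequence[Feature],
    spectra: Sequence[MS2Spectrum],
    db: SuspectDatabase,
    library: RuleLibrary,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    blank_ratio: float = DEFAULT_BLANK_RATIO,
    rt_window: float = 0.2,
    frag_tol: float = 0.005,
    conv: IonConvention | None = None,
) -> ScreeningResult:
    """Run the full cascade and annotate every matched feature."""
    conv = conv or IonConvention()
    report = FilteringReport()

    n_raw = sum(len(run) for run in runs)
    aligned = align_replicates(runs, mz_tol=ppm_tol, rt_tol=rt_tol)
    report.record("align_replicates", n_raw, len(aligned))

    cleaned = subtract_background(aligned, blank, blank_ratio, ppm_tol, rt_tol)
    report.record("subtract_background", len(aligned), len(cleaned))

    with_ms2 = require_ms2(cleaned, spectra, precursor_tol=ppm_tol, rt_window=rt_window)
    report.record("require_ms2", len(cleaned), len(with_ms2))

    matches = match_mass_list(with_ms2, db, ppm_tol, conv, report=report)

    spectra_by_id = {s.spectrum_id: s for s in spectra}
    moiety_deltas = {m.name: m.delta_formula for m in build_moieties()}
    annotations = []
    for match in matches:
        # annotate against the most intense linked spectrum
        linked = [spectra_by_id[sid] for sid in match.feature.ms2_ids if sid in spectra_by_id]
        if not linked:
            continue
        spectrum = max(linked, key=lambda s: s.base_peak_intensity)
        annotations.append(
            annotate_match(match, spectrum, library, moiety_deltas, frag_tol, conv=conv)
        )
    assign_isomer_indices(annotations)
    rt_flags = check_elution_order(annotations, library)
    return ScreeningResult(
        features=with_ms2,
        matches=matches,
        annotations=annotations,
        report=report,
        rt_flags=rt_flags,
    )
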