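"""Rule-based MS2 annotation of sulfated and non-sulfated phenolics.

Negative-mode spectra of sulfated phenolics carry two kinds of evidence:

* sulfate diagnostic ions — SO3(-.) at ~79.9568 and HSO4(-) at ~96.9601.
  Bond-dissociation energetics make the split informative: an aromatic
  (phenolic) sulfate cleaves the weaker O-S bond and releases SO3(-),
  whereas an aliphatic (benzylic/alkyl) sulfate cleaves the C-O bond and
  releases HSO4(-).  Observing one, the other or both localizes the
  sulfation site(s).
* aglycone diagnostic fragments — compound-specific product ions listed in
  the rule library, which identify the phenolic scaffold and separate
  isobaric candidates.

On top of these the engine counts sequential SO3 neutral losses from the
precursor (mono-/di-/tri-sulfates form a -79.9568 ladder), assigns a
Schymanski-style confidence level (2 = probable structure, 3 = tentative
candidate), numbers co-eluting isomers by RT, and flags retention-order
anomalies without ever rejecting an annotation for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .chem import (
    Formula,
    IonConvention,
    SULFATE_DELTA_MASS,
    monoisotopic_mass,
    mz_deprotonated,
    parse_formula,
)
from .database import Aglycone, CompoundEntry, SULFATE_GROUP
from .screening import MatchResult, MS2Spectrum

__all__ = [
    "DiagnosticRule",
    "SulfateEvidence",
    "Annotation",
    "RuleLibrary",
    "load_rule_library",
    "so3_reference_mz",
    "hso4_reference_mz",
    "detect_sulfate_ions",
    "count_so3_losses",
    "match_aglycone_fragments",
    "localize_sulfation",
    "assign_confidence",
    "annotate_match",
    "check_elution_order",
    "assign_isomer_indices",
]

#: Default fragment tolerance, in Da (5 mDa): inclusive at m/z < 500 for the
#: spread observed across curated diagnostic-ion lists (~1.5 mDa for SO3-).
DEFAULT_FRAG_TOL = 0.005
#: Minimum relative intensity (fraction of base peak) for a diagnostic hit.
DEFAULT_MIN_REL_INTENSITY = 0.005

SITE_CALLS = ("aromatic", "aliphatic", "both", "none", "undetermined")


@dataclass(frozen=True)
class DiagnosticRule:
    """Aglycone-level diagnostic fragments for one phenolic scaffold."""

    aglycone_name: str
    formula: Formula
    subclass: str
    diagnostic_mzs: list[tuple[str, float]]
    min_required: int = 2
    aromatic_oh: int = 0
    aliphatic_oh: int = 0
    source: str = "curated"

    def __post_init__(self) -> None:
        if not self.diagnostic_mzs:
            raise ValueError(f"rule {self.aglycone_name!r} has no diagnostic ions")
        if any(mz <= 50 for _, mz in self.diagnostic_mzs):
            raise ValueError(f"rule {self.aglycone_name!r}: diagnostic m/z must exceed 50")


@dataclass(frozen=True)
class SulfateEvidence:
    """Sulfate-related MS2 evidence extracted from one spectrum."""

    so3_ion: bool
    hso4_ion: bool
    n_so3_losses: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_so3_losses <= 3:
            raise ValueError("n_so3_losses must be within 0-3")

    def consistent_with(self, n_sulfates: int) -> bool:
        """Does the evidence agree with the candidate's sulfation level?"""
        any_sulfate = self.so3_ion or self.hso4_ion or self.n_so3_losses >= 1
        return any_sulfate if n_sulfates >= 1 else not any_sulfate


@dataclass
class Annotation:
    """Final annotation of one matched feature."""

    feature_id: str
    compound_name: str
    candidate: CompoundEntry
    ppm_error: float
    rt: float
    site_call: str
    matched_diagnostics: list[tuple[str, float, float]]
    confidence_level: int
    evidence: SulfateEvidence
    rule_name: str | None = None
    isomer_index: int | None = None
    rt_flags: list[str] = field(default_factory=list)

    @property
    def display_name(self) -> str:
        if self.isomer_index is None:
            return self.compound_name
        return f"{self.compound_name} isomer {self.isomer_index}"


class RuleLibrary:
    """Diagnostic rules indexed by aglycone name and by formula."""

    def __init__(self, rules: Sequence[DiagnosticRule]) -> None:
        self.rules: dict[str, DiagnosticRule] = {}
        for rule in rules:
            if rule.aglycone_name in self.rules:
                raise ValueError(f"duplicate rule for {rule.aglycone_name!r}")
            self.rules[rule.aglycone_name] = rule

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, name: str) -> bool:
        return name in self.rules

    def get(self, name: str) -> DiagnosticRule | None:
        return self.rules.get(name)

    def by_formula(self, formula: Formula) -> list[DiagnosticRule]:
        """All rules whose aglycone has the given composition (curated first)."""
        hits = [r for r in self.rules.values() if r.formula == formula]
        hits.sort(key=lambda r: (r.source != "curated", r.aglycone_name))
        return hits


def _generic_rule(aglycone: Aglycone, conv: IonConvention) -> DiagnosticRule:
    """Fallback rule: deprotonated aglycone plus common small neutral losses."""
    base = mz_deprotonated(monoisotopic_mass(aglycone.formula), conv)
    diagnostics = [("[M-H]-", round(base, 4))]
    for label, loss in (("-H2O", 18.0105646), ("-CO", 27.9949146), ("-CO2", 43.9898292)):
        frag = base - loss
        if frag > 50:
            diagnostics.append((label, round(frag, 4)))
    return DiagnosticRule(
        aglycone_name=aglycone.name,
        formula=aglycone.formula,
        subclass=aglycone.subclass,
        diagnostic_mzs=diagnostics,
        min_required=1,
        aromatic_oh=aglycone.aromatic_oh,
        aliphatic_oh=aglycone.aliphatic_oh,
        source="generic",
    )


def load_rule_library(
    path: str | Path | None = None,
    registry: Sequence[Aglycone] | None = None,
    conv: IonConvention | None = None,
) -> RuleLibrary:
    """Load the curated rule YAML, optionally completed with generic rules.

    When ``registry`` is given, every registry aglycone without a curated
    entry receives a generic rule ([M-H]- plus -H2O/-CO/-CO2 losses) so that
    all suspects are annotatable; curated rules always win ties.
    """
    conv = conv or IonConvention()
    if path is None:
        path = Path(str(resources.files("sulfoscreen").joinpath("data/fragment_rules.yaml")))
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    rules = [
        DiagnosticRule(
            aglycone_name=item["aglycone"],
            formula=parse_formula(item["formula"]),
            subclass=item["subclass"],
            diagnostic_mzs=[(d["label"], float(d["mz"])) for d in item["diagnostics"]],
            min_required=int(item.get("min_required", 2)),
            aromatic_oh=int(item.get("aromatic_oh", 0)),
            aliphatic_oh=int(item.get("aliphatic_oh", 0)),
            source="curated",
        )
        for item in raw["rules"]
    ]
    if registry is not None:
        curated_names = {r.aglycone_name for r in rules}
        for aglycone in registry:
            if aglycone.name not in curated_names:
                rules.append(_generic_rule(aglycone, conv))
    return RuleLibrary(rules)


def so3_reference_mz(conv: IonConvention | None = None) -> float:
    """m/z of the SO3 radical anion under the active convention."""
    conv = conv or IonConvention()
    mz = monoisotopic_mass(SULFATE_GROUP)
    if conv.electron_correction:
        mz += conv.describe()["electron_mass"]
    return mz


def hso4_reference_mz(conv: IonConvention | None = None) -> float:
    """m/z of HSO4- (deprotonated sulfuric acid) under the convention."""
    conv = conv or IonConvention()
    h2so4 = Formula({"H": 2, "S": 1, "O": 4})
    return mz_deprotonated(monoisotopic_mass(h2so4), conv)


def _has_peak(
    spectrum: MS2Spectrum,
    mz: float,
    frag_tol: float,
    min_rel_intensity: float,
) -> tuple[float, float] | None:
    """Most intense peak within ``frag_tol`` Da of ``mz``, or None."""
    base = spectrum.base_peak_intensity
    best = None
    for peak_mz, intensity in spectrum.peaks:
        if peak_mz > mz + frag_tol:
            break
        if abs(peak_mz - mz) <= frag_tol and intensity >= min_rel_intensity * base:
            if best is None or intensity > best[1]:
                best = (peak_mz, intensity)
    return best


def detect_sulfate_ions(
    spectrum: MS2Spectrum,
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
    conv: IonConvention | None = None,
    precursor_mz: float | None = None,
) -> SulfateEvidence:
    """Detect SO3-/HSO4- diagnostic ions and count SO3 neutral losses."""
    so3 = _has_peak(spectrum, so3_reference_mz(conv), frag_tol, min_rel_intensity)
    hso4 = _has_peak(spectrum, hso4_reference_mz(conv), frag_tol, min_rel_intensity)
    precursor = precursor_mz if precursor_mz is not None else spectrum.precursor_mz
    n_losses = count_so3_losses(spectrum, precursor, frag_tol, min_rel_intensity)
    return SulfateEvidence(so3_ion=so3 is not None, hso4_ion=hso4 is not None, n_so3_losses=n_losses)


def count_so3_losses(
    spectrum: MS2Spectrum,
    precursor_mz: float,
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
    max_losses: int = 3,
) -> int:
    """Length of the longest -79.9568 ladder walked down from the precursor.

    Each step must land on an observed peak within ``frag_tol``; the walk
    continues from the observed peak m/z so small errors do not accumulate.
    """
    if precursor_mz <= 80:
        raise ValueError("precursor m/z too small for an SO3 loss")
    current = precursor_mz
    losses = 0
    while losses < max_losses:
        hit = _has_peak(spectrum, current - SULFATE_DELTA_MASS, frag_tol, min_rel_intensity)
        if hit is None:
            break
        current = hit[0]
        losses += 1
    return losses


def match_aglycone_fragments(
    spectrum: MS2Spectrum,
    rule: DiagnosticRule | None,
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
) -> list[tuple[str, float, float]]:
    """Diagnostics of ``rule`` observed in the spectrum.

    Returns (label, reference m/z, observed m/z) triples.  A missing rule is
    an explicit error: silently passing would hide library gaps.
    """
    if rule is None:
        raise LookupError("no diagnostic rule available for this aglycone")
    matched = []
    for label, ref_mz in rule.diagnostic_mzs:
        hit = _has_peak(spectrum, ref_mz, frag_tol, min_rel_intensity)
        if hit is not None:
            matched.append((label, ref_mz, hit[0]))
    return matched


def localize_sulfation(
    evidence: SulfateEvidence,
    candidate: CompoundEntry,
    site_profile: tuple[int, int] | None = None,
) -> tuple[str, list[str]]:
    """Site call from the SO3-/HSO4- split, checked against the OH profile.

    Returns ``(site_call, warnings)``.  ``site_profile`` is
    (aromatic_oh, aliphatic_oh) of the aglycone; a call requiring a hydroxyl
    the scaffold does not have is downgraded to ``undetermined``.
    """
    warnings: list[str] = []
    if candidate.n_sulfates == 0:
        return "none", warnings
    if evidence.so3_ion and evidence.hso4_ion:
        call = "both"
    elif evidence.so3_ion:
        call = "aromatic"
    elif evidence.hso4_ion:
        call = "aliphatic"
    elif evidence.n_so3_losses >= 1:
        call = "undetermined"
    else:
        call = "undetermined"
        warnings.append("sulfated candidate without any sulfate MS2 evidence")
    if site_profile is not None:
        aromatic_oh, aliphatic_oh = site_profile
        if call in ("aliphatic", "both") and aliphatic_oh == 0:
            warnings.append(
                f"{candidate.name}: HSO4- evidence but aglycone has no aliphatic OH"
            )
            call = "undetermined"
        elif call in ("aromatic", "both") and aromatic_oh == 0:
            warnings.append(
                f"{candidate.name}: SO3- evidence but aglycone has no aromatic OH"
            )
            call = "undetermined"
    return call, warnings


def assign_confidence(
    matched_diagnostics: Sequence[tuple[str, float, float]],
    evidence: SulfateEvidence,
    candidate: CompoundEntry,
) -> int:
    """Confidence level 2 (probable) or 3 (tentative).

    Level 2 requires at least two matched aglycone diagnostics and sulfate
    evidence consistent with the candidate's sulfation level; anything less
    stays a tentative candidate.  This numeric criterion is a declared
    heuristic of the engine.
    """
    if len(matched_diagnostics) >= 2 and evidence.consistent_with(candidate.n_sulfates):
        return 2
    return 3


def annotate_match(
    match: MatchResult,
    spectrum: MS2Spectrum,
    library: RuleLibrary,
    moiety_deltas: Mapping[str, Formula] | None = None,
    frag_tol: float = DEFAULT_FRAG_TOL,
    min_rel_intensity: float = DEFAULT_MIN_REL_INTENSITY,
    conv: IonConvention | None = None,
) -> Annotation:
    """Annotate one mass-list match with its MS2 spectrum.

    Every candidate entry is paired with every library rule of matching
    aglycone-level composition (candidate formula minus sulfates minus the
    moiety delta), including isobaric scaffolds that are not the candidate's
    nominal aglycone.  The winner is chosen by number of matched diagnostics,
    then curated-over-generic, then smaller |ppm error| — mirroring how an
    analyst promotes the scaffold whose fragments are actually present.
    """
    evidence = detect_sulfate_ions(
        spectrum, frag_tol, min_rel_intensity, conv, precursor_mz=match.feature.mz
    )
    scored: list[tuple[tuple, CompoundEntry, float, DiagnosticRule, list]] = []
    for candidate, err in match.candidates:
        formula = candidate.formula
        try:
            formula = formula - (candidate.n_sulfates * SULFATE_GROUP)
            if candidate.moiety_name and moiety_deltas is not None:
                formula = formula - moiety_deltas[candidate.moiety_name]
        except Exception:
            continue
        for rule in library.by_formula(formula):
            matched = match_aglycone_fragments(spectrum, rule, frag_tol, min_rel_intensity)
            rank = (-len(matched), rule.source != "curated", abs(err), rule.aglycone_name)
            scored.append((rank, candidate, err, rule, matched))

    if scored:
        scored.sort(key=lambda item: item[0])
        _, candidate, err, rule, matched = scored[0]
        site_profile = (rule.aromatic_oh, rule.aliphatic_oh)
        name = rule.aglycone_name
        if candidate.moiety_name:
            name += f" {candidate.moiety_name} conjugate"
        name += {0: "", 1: " sulfate", 2: " disulfate", 3: " trisulfate"}[candidate.n_sulfates]
        rule_name = rule.aglycone_name
    else:
        candidate, err = match.best
        matched = []
        site_profile = None
        name = candidate.name
        rule_name = None

    site_call, warnings = localize_sulfation(evidence, candidate, site_profile)
    return Annotation(
        feature_id=match.feature.feature_id,
        compound_name=name,
        candidate=candidate,
        ppm_error=err,
        rt=match.feature.rt,
        site_call=site_call,
        matched_diagnostics=matched,
        confidence_level=assign_confidence(matched, evidence, candidate),
        evidence=evidence,
        rule_name=rule_name,
        rt_flags=warnings,
    )


def _free_oh(annotation: Annotation, library: RuleLibrary) -> int | None:
    rule = library.get(annotation.rule_name) if annotation.rule_name else None
    if rule is None:
        return None
    return rule.aromatic_oh + rule.aliphatic_oh - annotation.candidate.n_sulfates


def check_elution_order(
    annotations: Sequence[Annotation],
    library: RuleLibrary,
) -> list[str]:
    """Retention-order sanity warnings (never rejections).

    Two trends are checked: (a) within a homolog family (same subclass,
    moiety and sulfation level) compounds with more free hydroxyls elute
    earlier on reversed phase; (b) a sulfated compound elutes no later than
    its non-sulfated parent.  Violations are flagged on the annotations and
    returned.
    """
    flags: list[str] = []
    # (a) free-OH ordering within homolog families
    families: dict[tuple, list[Annotation]] = {}
    for ann in annotations:
        rule = library.get(ann.rule_name) if ann.rule_name else None
        if rule is None:
            continue
        key = (rule.subclass, ann.candidate.moiety_name, ann.candidate.n_sulfates)
        families.setdefault(key, []).append(ann)
    for members in families.values():
        for a in members:
            for b in members:
                oh_a, oh_b = _free_oh(a, library), _free_oh(b, library)
                if oh_a is None or oh_b is None or a is b:
                    continue
                if oh_a > oh_b and a.rt > b.rt:
                    msg = (
                        f"{a.display_name} (RT {a.rt:.1f}, {oh_a} free OH) elutes after "
                        f"{b.display_name} (RT {b.rt:.1f}, {oh_b} free OH)"
                    )
                    flags.append(msg)
                    a.rt_flags.append(msg)
    # (b) sulfated vs non-sulfated parent
    parents: dict[tuple, list[Annotation]] = {}
    for ann in annotations:
        if ann.candidate.n_sulfates == 0:
            parents.setdefault(
                (ann.rule_name or ann.candidate.aglycone_name, ann.candidate.moiety_name), []
            ).append(ann)
    for ann in annotations:
        if ann.candidate.n_sulfates == 0:
            continue
        key = (ann.rule_name or ann.candidate.aglycone_name, ann.candidate.moiety_name)
        for parent in parents.get(key, []):
            if ann.rt > parent.rt:
                msg = (
                    f"{ann.display_name} (RT {ann.rt:.1f}) elutes after its "
                    f"non-sulfated parent {parent.display_name} (RT {parent.rt:.1f})"
                )
                flags.append(msg)
                ann.rt_flags.append(msg)
    return flags


def assign_isomer_indices(annotations: Sequence[Annotation]) -> Sequence[Annotation]:
    """Number annotations sharing a formula and compound name by ascending RT.

    Singletons keep ``isomer_index=None``; groups of two or more get indices
    1..N in RT order, matching the 'isomer 1/2/...' reporting convention.
    """
    groups: dict[tuple, list[Annotation]] = {}
    for ann in annotations:
        key = (ann.candidate.formula.hill(), ann.compound_name)
        groups.setdefault(key, []).append(ann)
    for members in groups.values():
        if len(members) < 2:
            for ann in members:
                ann.isomer_index = None
            continue
        for i, ann in enumerate(sorted(members, key=lambda a: a.rt), start=1):
            ann.isomer_index = i
    return annotations
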