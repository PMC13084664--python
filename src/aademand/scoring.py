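"""Protein-quality scoring against demand-based reference patterns.

A scoring pattern expresses each indispensable amino acid (IAA) requirement
as mg per g of the total-protein requirement. The Digestible Indispensable
Amino Acid Score (DIAAS) of a protein source is the minimum, over the nine
IAA categories, of

    reference ratio = digestible IAA content (mg/g protein) / pattern value

The IAA attaining the minimum is first-limiting; the score is reported
untruncated (values above 1 are kept). The protein intake needed to cover
the full demand through that source is requirement / DIAAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .amino_acids import AA, IAA_KEYS
from .model import ValidationError


class ConfigurationError(ValueError):
    """Raised when a protein source cannot be scored (e.g. no resolvable
    digestibility for an amino acid)."""


@dataclass(frozen=True)
class ScoringPattern:
    """Reference vector of mg IAA per g protein.

    ``protein_requirement`` is the matching total-protein requirement in
    g/kgBW/d (0.634 for the factorial-model demand, 0.66 for the current
    FAO/WHO estimated average requirement).
    """

    label: str
    values: Mapping[AA, float]
    protein_requirement: float

    def __post_init__(self) -> None:
        if self.protein_requirement <= 0:
            raise ValidationError("protein_requirement must be > 0")
        missing = [k.value for k in IAA_KEYS if k not in self.values]
        if missing:
            raise ValidationError(f"pattern missing IAA keys: {missing}")
        for aa in IAA_KEYS:
            if self.values[aa] <= 0:
                raise ValidationError(
                    f"pattern value for {aa.value} must be > 0"
                )


@dataclass(frozen=True)
class ProteinSource:
    """A dietary protein source, either as raw composition plus true ileal
    digestibility (TID) or as precomputed reference ratios per pattern.

    TID resolution order per amino acid: the amino acid's own TID, else the
    mean of the available per-AA TIDs, else the total-protein TID, else the
    total-nitrogen TID. Tryptophan composition must be present explicitly.
    """

    name: str
    composition: Mapping[AA, float] | None = None     # mg per g protein
    tid: Mapping[AA, float] | None = None             # fraction in [0, 1]
    tid_total_protein: float | None = None
    tid_total_n: float | None = None
    reference_ratios: Mapping[str, Mapping[AA, float]] | None = None

    def __post_init__(self) -> None:
        if self.composition is not None:
            for aa, v in self.composition.items():
                if v < 0:
                    raise ValidationError(
                        f"{self.name}: composition for {aa.value} must be >= 0"
                    )
        if self.tid is not None:
            for aa, t in self.tid.items():
                if not 0.0 <= t <= 1.0:
                    raise ValidationError(
                        f"{self.name}: TID for {aa.value} must be in [0, 1]"
                    )

    def resolve_tid(self, aa: AA) -> float:
        if self.tid and aa in self.tid:
            return self.tid[aa]
        if self.tid:
            return math.fsum(self.tid.values()) / len(self.tid)
        if self.tid_total_protein is not None:
            return self.tid_total_protein
        if self.tid_total_n is not None:
            return self.tid_total_n
        raise ConfigurationError(
            f"{self.name}: no digestibility resolvable for {aa.value}"
        )


@dataclass(frozen=True)
class DIAASResult:
    reference_ratios: Mapping[AA, float]
    diaas: float
    limiting: frozenset[AA]
    required_intake: float
    pattern_label: str
    source_name: str


def build_pattern(
    per_aa_demand: Mapping[AA, float],
    protein_demand: float,
    label: str = "custom",
) -> ScoringPattern:
    """Build a scoring pattern by dividing each IAA demand (mg/kgBW/d) by
    the total-protein demand (g/kgBW/d), giving mg per g protein."""
    if protein_demand <= 0:
        raise ValidationError("protein demand must be > 0")
    missing = [k.value for k in IAA_KEYS if k not in per_aa_demand]
    if missing:
        raise ValidationError(f"demand missing IAA keys: {missing}")
    values = {aa: per_aa_demand[aa] / protein_demand for aa in IAA_KEYS}
    return ScoringPattern(label=label, values=values,
                          protein_requirement=protein_demand)


def digestible_content(source: ProteinSource) -> dict[AA, float]:
    """Digestible IAA content of a source: composition times resolved TID."""
    if source.composition is None:
        raise ConfigurationError(
            f"{source.name}: no amino-acid composition available"
        )
    missing = [k.value for k in IAA_KEYS if k not in source.composition]
    if missing:
        raise ConfigurationError(
            f"{source.name}: composition missing {missing}"
        )
    return {
        aa: source.composition[aa] * source.resolve_tid(aa)
        for aa in IAA_KEYS
    }


def _score_ratios(ratios: Mapping[AA, float], pattern: ScoringPattern,
                  source_name: str) -> DIAASResult:
    diaas = min(ratios.values())
    limiting = frozenset(aa for aa, r in ratios.items()
                         if math.isclose(r, diaas, rel_tol=0, abs_tol=1e-12))
    return DIAASResult(
        reference_ratios=dict(ratios),
        diaas=diaas,
        limiting=limiting,
        required_intake=required_intake(pattern.protein_requirement, diaas),
        pattern_label=pattern.label,
        source_name=source_name,
    )


def score(source: ProteinSource, pattern: ScoringPattern) -> DIAASResult:
    """DIAAS of a source against a pattern.

    Uses the source's precomputed reference ratios for the pattern when
    present (regression against published score tables); otherwise computes
    digestible content / pattern value per IAA. The minimum is taken at
    full precision; all amino acids tying at the minimum are reported as
    first-limiting.
    """
    if source.reference_ratios and pattern.label in source.reference_ratios:
        ratios = source.reference_ratios[pattern.label]
        missing = [k.value for k in IAA_KEYS if k not in ratios]
        if missing:
            raise ConfigurationError(
                f"{source.name}: reference ratios missing {missing}"
            )
        return _score_ratios(ratios, pattern, source.name)
    content = digestible_content(source)
    ratios = {aa: content[aa] / pattern.values[aa] for aa in IAA_KEYS}
    return _score_ratios(ratios, pattern, source.name)


def required_intake(protein_requirement: float, diaas: float) -> float:
    """Protein intake (g/kgBW/d) needed from a source to satisfy every IAA
    demand: requirement / DIAAS. The identity intake * diaas = requirement
    holds exactly."""
    if diaas <= 0:
        raise ValidationError("DIAAS must be > 0")
    if protein_requirement <= 0:
        raise ValidationError("protein requirement must be > 0")
    return protein_requirement / diaas


@dataclass(frozen=True)
class LimitingShift:
    source_name: str
    limiting_a: frozenset[AA]
    limiting_b: frozenset[AA]
    pattern_a: str
    pattern_b: str

    @property
    def shifted(self) -> bool:
        return self.limiting_a != self.limiting_b


def limiting_shift_report(
    source: ProteinSource,
    pattern_a: ScoringPattern,
    pattern_b: ScoringPattern,
) -> LimitingShift:
    """Compare first-limiting amino acids under two scoring patterns."""
    res_a = score(source, pattern_a)
    res_b = score(source, pattern_b)
    return LimitingShift(
        source_name=source.name,
        limiting_a=res_a.limiting,
        limiting_b=res_b.limiting,
        pattern_a=pattern_a.label,
        pattern_b=pattern_b.label,
    )
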