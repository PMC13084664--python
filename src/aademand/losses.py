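"""Derivation of the minor obligatory-loss components from primary data.

Three of the six non-oxidative loss components are assembled here from
primary inputs rather than taken from upstream models:

HSNM — hair, skin, nail and miscellaneous losses. A total nitrogen loss
    (5 mg N/kgBW/d) is split into a dermal part (3.2) and a miscellaneous
    part (1.8), converted to protein with the 6.25 factor, and apportioned
    to amino acids with the dermal and whole-body-protein composition
    tables respectively.

UFAAP — urinary free amino acids and peptides, combined across studies as
    subject-number-weighted means of per-kg excretion. Glutamine, absent
    from the older total (free + bound) datasets, enters via
    creatinine-normalised reference ranges.

OL — other losses from irreversible modification and functional conversion
    (e.g. tryptophan → serotonin), estimated from 24-h urinary metabolite
    excretion with mol-to-mol stoichiometry to the parent amino acid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .amino_acids import AA, ALL_KEYS, molar_mass, resolve_key
from .model import (
    DEFAULT_CONSTANTS,
    ModelConstants,
    Quantity,
    ValidationError,
    propagate_sd,
)

MG_PER_DAY = "mg_per_day"
MMOL_PER_MOL_CREATININE = "mmol_per_mol_creatinine"
MOL_PER_DAY = "mol_per_day"


@dataclass(frozen=True)
class CompositionTable:
    """Amino-acid composition of a protein pool, mg AA per g protein."""

    values: Mapping[AA, float]
    label: str = "body_protein"

    def __post_init__(self) -> None:
        for aa, v in self.values.items():
            if v < 0 or not math.isfinite(v):
                raise ValidationError(
                    f"{self.label} composition for {aa.value} must be >= 0"
                )

    def get(self, aa: AA) -> float:
        if aa not in self.values:
            warnings.warn(
                f"{self.label} composition missing {aa.value}; using 0",
                stacklevel=2,
            )
            return 0.0
        return self.values[aa]


@dataclass(frozen=True)
class NitrogenLossSpec:
    """Total integumental + miscellaneous nitrogen loss and its split."""

    total_n: float = 5.0            # mg N/kgBW/d
    miscellaneous_n: float = 1.8    # mg N/kgBW/d
    total_n_sd: float = 0.9         # mg N/kgBW/d

    @property
    def dermal_n(self) -> float:
        return self.total_n - self.miscellaneous_n

    def __post_init__(self) -> None:
        if self.dermal_n <= 0:
            raise ValidationError(
                "dermal nitrogen (total - miscellaneous) must be positive"
            )
        if self.total_n_sd < 0:
            raise ValidationError("total_n_sd must be >= 0")


@dataclass(frozen=True)
class UrinaryStudyRecord:
    """One study's mean urinary excretion of one amino acid.

    ``value`` is in mg/d (with ``body_weight`` in kg) unless ``unit`` is
    creatinine-normalised, in which case it is mmol AA per mol creatinine
    and conversion uses the reference creatinine output.
    """

    aa: str
    value: float
    sd: float
    n_subjects: int
    body_weight: float = 75.0
    unit: str = MG_PER_DAY

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.value < 0 or self.sd < 0:
            raise ValidationError("excretion value and sd must be >= 0")
        if self.unit not in (MG_PER_DAY, MMOL_PER_MOL_CREATININE):
            raise ValidationError(f"unknown unit {self.unit!r}")

    def key(self) -> AA:
        return resolve_key(self.aa)


@dataclass(frozen=True)
class MetaboliteLossRecord:
    """Urinary excretion of a metabolite standing for loss of a parent
    amino acid, mol-to-mol (times ``stoichiometry``)."""

    metabolite: str
    parent_aa: str
    excretion: float            # mol/d, or mmol/mol creatinine
    sd: float = 0.0
    stoichiometry: float = 1.0
    unit: str = MOL_PER_DAY

    def __post_init__(self) -> None:
        if self.excretion < 0 or self.sd < 0:
            raise ValidationError("excretion and sd must be >= 0")
        if self.stoichiometry <= 0:
            raise ValidationError("stoichiometry must be > 0")
        if self.unit not in (MOL_PER_DAY, MMOL_PER_MOL_CREATININE):
            raise ValidationError(f"unknown unit {self.unit!r}")

    def key(self) -> AA:
        try:
            return resolve_key(self.parent_aa)
        except KeyError as exc:
            raise ValidationError(str(exc)) from exc


def n_to_protein(n_mass: float,
                 constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a nitrogen mass to protein mass (factor 6.25)."""
    if n_mass < 0:
        raise ValidationError("nitrogen mass must be >= 0")
    return constants.n_to_protein * n_mass


def derive_hsnm(
    spec: NitrogenLossSpec,
    body: CompositionTable,
    dermal: CompositionTable,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[AA, Quantity]:
    """Apportion the HSNM nitrogen loss to amino acids.

    Per amino acid (mg/kgBW/d):

        hsnm = 6.25 * misc_n * body[aa]/1000 + 6.25 * dermal_n * dermal[aa]/1000

    The miscellaneous part follows whole-body-protein composition, the
    dermal part the hair/skin/nail composition. SDs scale each part by the
    relative uncertainty of the nitrogen total.
    """
    misc_protein = n_to_protein(spec.miscellaneous_n, constants)
    dermal_protein = n_to_protein(spec.dermal_n, constants)
    rel_sd = spec.total_n_sd / spec.total_n if spec.total_n > 0 else 0.0
    out: dict[AA, Quantity] = {}
    for aa in ALL_KEYS:
        mean = (misc_protein * body.get(aa)
                + dermal_protein * dermal.get(aa)) / 1000.0
        out[aa] = Quantity(mean, mean * rel_sd)
    return out


def weighted_ufaap(records: Sequence[UrinaryStudyRecord],
                   constants: ModelConstants = DEFAULT_CONSTANTS) -> Quantity:
    """Combine studies of one amino acid into a subject-number-weighted
    mean (and likewise-weighted SD), in mg/kgBW/d."""
    if not records:
        raise ValidationError("weighted_ufaap requires at least one record")
    keys = {r.key() for r in records}
    if len(keys) > 1:
        raise ValidationError(
            f"records mix amino acids: {sorted(k.value for k in keys)}"
        )
    values, sds, weights = [], [], []
    for r in records:
        if r.unit == MMOL_PER_MOL_CREATININE:
            mw = molar_mass(r.aa)
            values.append(creatinine_normalized_to_mass(r.value, mw, constants))
            sds.append(creatinine_normalized_to_mass(r.sd, mw, constants))
        else:
            values.append(r.value / r.body_weight)
            sds.append(r.sd / r.body_weight)
        weights.append(r.n_subjects)
    total_n = sum(weights)
    mean = math.fsum(w * v for w, v in zip(weights, values)) / total_n
    sd = math.fsum(w * s for w, s in zip(weights, sds)) / total_n
    return Quantity(mean, sd)


def derive_ufaap(
    records: Sequence[UrinaryStudyRecord],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[AA, Quantity]:
    """Full urinary free-AA-and-peptide column: weight studies per
    individual amino acid, then sum members of composite categories
    (Met + Cys -> SAA, Glu + Gln -> Glx, ...). Amino acids with no
    records get 0."""
    by_name: dict[str, list[UrinaryStudyRecord]] = {}
    for r in records:
        by_name.setdefault(r.aa.strip().lower(), []).append(r)
    by_key: dict[AA, list[Quantity]] = {}
    for name, recs in by_name.items():
        q = weighted_ufaap(recs, constants)
        by_key.setdefault(resolve_key(name), []).append(q)
    out: dict[AA, Quantity] = {}
    for aa in ALL_KEYS:
        parts = by_key.get(aa, [])
        if not parts:
            out[aa] = Quantity(0.0, 0.0)
        else:
            out[aa] = Quantity(
                math.fsum(p.mean for p in parts),
                propagate_sd(p.sd for p in parts),
            )
    return out


def creatinine_normalized_to_mass(
    value: float,
    molar_mass_g_per_mol: float,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert mmol AA per mol creatinine to mg/kgBW/d using the reference
    creatinine output (0.2 mmol/kgBW/d):

        (value/1000) mmol AA/mmol creat * 0.2 mmol creat/kgBW/d * MW mg/mmol
    """
    if value < 0:
        raise ValidationError("creatinine-normalised value must be >= 0")
    if molar_mass_g_per_mol <= 0:
        raise ValidationError("molar mass must be > 0")
    return (value / 1000.0) * constants.creatinine_excretion * molar_mass_g_per_mol


def metabolite_to_aa_loss(
    record: MetaboliteLossRecord,
    aa_molar_mass: float,
    body_weight: float = 75.0,
) -> float:
    """Convert a metabolite excretion record to parent-amino-acid loss in
    mg/kgBW/d. mol/d records: excretion * stoichiometry * MW * 1000 / BW.
    Creatinine-normalised records are converted per-kg directly."""
    if aa_molar_mass <= 0:
        raise ValidationError("molar mass must be > 0")
    record.key()  # validates parent_aa
    if record.unit == MMOL_PER_MOL_CREATININE:
        per_kg = creatinine_normalized_to_mass(
            record.excretion * record.stoichiometry, aa_molar_mass
        )
        return per_kg
    if body_weight <= 0:
        raise ValidationError("body weight must be > 0")
    return record.excretion * record.stoichiometry * aa_molar_mass * 1000.0 / body_weight


def assemble_ol(
    records: Iterable[MetaboliteLossRecord],
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> dict[AA, Quantity]:
    """Assemble the other-losses column: each metabolite pathway is
    estimated independently and summed per parent amino acid; SDs combine
    by root-sum-of-squares. Amino acids with no pathway get 0."""
    losses: dict[AA, list[tuple[float, float]]] = {}
    for r in records:
        mw = molar_mass(r.parent_aa)
        mean = metabolite_to_aa_loss(r, mw, constants.body_weight)
        sd = metabolite_to_aa_loss(
            MetaboliteLossRecord(
                metabolite=r.metabolite, parent_aa=r.parent_aa,
                excretion=r.sd, stoichiometry=r.stoichiometry, unit=r.unit,
            ),
            mw, constants.body_weight,
        )
        losses.setdefault(r.key(), []).append((mean, sd))
    out: dict[AA, Quantity] = {}
    for aa in ALL_KEYS:
        parts = losses.get(aa, [])
        out[aa] = Quantity(
            math.fsum(m for m, _ in parts),
            propagate_sd(s for _, s in parts),
        )
    return out
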