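"""Core factorial model of the minimum metabolic demand (MMD).

The MMD for an amino acid is the daily obligatory loss that dietary intake
must replace at maintenance, assembled from seven loss components:

    MMD = TOL + EGL + UFAAP + HSNM + OL
        = (PTO_PA + PTO_PP + IO) + EGL + UFAAP + HSNM + OL

where the oxidative block TOL comprises turnover-associated oxidation in the
postabsorptive (PTO_PA) and postprandial (PTO_PP) states plus inevitable
oxidation (IO) of absorbed dietary amino acids. Because the model describes
an intake that exactly meets the demand, IO is itself a fixed fraction
(default 29%) of the MMD, giving the closed-form fixed point

    MMD = (PTO_PA + PTO_PP + EGL + UFAAP + HSNM + OL) / (1 - io_rate)
    IO  = io_rate * MMD

All quantities are in mg per kg body weight per day (mg/kgBW/d).
Uncertainties are carried as standard deviations and combined by
root-sum-of-squares, treating component errors as independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .amino_acids import AA, ALL_KEYS, DAA_KEYS, IAA_KEYS


class ValidationError(ValueError):
    """Raised for invalid model inputs (negative losses, missing keys...)."""


class InfeasibleModelError(ValueError):
    """Raised when the inevitable-oxidation rate makes the fixed point
    unsolvable (io_rate >= 1)."""


@dataclass(frozen=True)
class Quantity:
    """A mean with a standard deviation, mg/kgBW/d."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean) or self.mean < 0:
            raise ValidationError(f"mean must be finite and >= 0, got {self.mean}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValidationError(f"sd must be finite and >= 0, got {self.sd}")

    def scaled(self, k: float) -> "Quantity":
        return Quantity(self.mean * k, self.sd * k)


@dataclass(frozen=True)
class ModelConstants:
    """Tunable constants of the factorial model.

    io_rate
        Fraction of each absorbed dietary amino acid lost to inevitable
        first-pass catabolism (default 0.29).
    pto_pa_fraction / pto_pp_fraction
        Fractions of postabsorptive / postprandial protein breakdown lost to
        turnover-associated oxidation (0.11 and 0.024). The packaged loss
        tables already contain the products PTO_PA and PTO_PP, so these are
        retained for scenario scaling (e.g. a 22% postabsorptive rate
        doubles PTO_PA via ``pto_pa_scale``), not applied to breakdown rates.
    n_to_protein
        Nitrogen-to-protein conversion factor (6.25 g protein per g N).
    body_weight
        Reference body weight, kg (75, young adult male).
    creatinine_excretion
        Urinary creatinine output, mmol/kgBW/d (0.2), used to convert
        creatinine-normalised excretion data.
    """

    io_rate: float = 0.29
    pto_pa_fraction: float = 0.11
    pto_pp_fraction: float = 0.024
    n_to_protein: float = 6.25
    body_weight: float = 75.0
    creatinine_excretion: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.io_rate < 1.0:
            raise InfeasibleModelError(
                f"io_rate must lie in (0, 1); got {self.io_rate}"
            )
        for name in ("n_to_protein", "body_weight", "creatinine_excretion"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


DEFAULT_CONSTANTS = ModelConstants()

#: Names of the six non-IO loss components, in reporting order.
NON_IO_COMPONENTS: tuple[str, ...] = (
    "pto_pp", "pto_pa", "egl", "ufaap", "hsnm", "ol",
)
#: All seven loss sources, reporting order (IO first, as in the demand table).
ALL_COMPONENTS: tuple[str, ...] = ("io",) + NON_IO_COMPONENTS


@dataclass(frozen=True)
class ComponentSet:
    """The six non-IO obligatory-loss components for one amino acid."""

    pto_pp: Quantity
    pto_pa: Quantity
    egl: Quantity
    ufaap: Quantity
    hsnm: Quantity
    ol: Quantity

    def __getitem__(self, name: str) -> Quantity:
        if name not in NON_IO_COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)

    def means(self) -> tuple[float, ...]:
        return tuple(self[c].mean for c in NON_IO_COMPONENTS)

    def sds(self) -> tuple[float, ...]:
        return tuple(self[c].sd for c in NON_IO_COMPONENTS)

    def scaled(self, k: float) -> "ComponentSet":
        return ComponentSet(**{c: self[c].scaled(k) for c in NON_IO_COMPONENTS})

    def with_scaled(self, name: str, k: float) -> "ComponentSet":
        """Return a copy with one component scaled by ``k``."""
        if name not in NON_IO_COMPONENTS:
            raise ValidationError(f"unknown component {name!r}")
        return replace(self, **{name: self[name].scaled(k)})


@dataclass(frozen=True)
class LossComponentTable:
    """Per-amino-acid non-IO loss components: the model's parameter core.

    ``io_sd_override`` carries externally supplied SDs for the IO term
    (the published IO uncertainties are not derivable from the component
    SDs and the propagation rule alone; when absent a scaled
    root-sum-of-squares fallback is used, see :func:`solve_mmd`).
    """

    rows: Mapping[AA, ComponentSet]
    io_sd_override: Mapping[AA, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [k.value for k in ALL_KEYS if k not in self.rows]
        if missing:
            raise ValidationError(f"component table missing keys: {missing}")
        for aa, sd in self.io_sd_override.items():
            if sd < 0 or not math.isfinite(sd):
                raise ValidationError(f"io_sd_override[{aa}] must be >= 0")

    def scaled(self, pto_pa_scale: float = 1.0, pto_pp_scale: float = 1.0
               ) -> "LossComponentTable":
        """Scenario hook: rescale the turnover-oxidation components, e.g.
        ``pto_pa_scale=2.0`` for a 22% (instead of 11%) postabsorptive
        oxidation rate."""
        rows = {
            aa: cs.with_scaled("pto_pa", pto_pa_scale)
                  .with_scaled("pto_pp", pto_pp_scale)
            for aa, cs in self.rows.items()
        }
        return LossComponentTable(rows, dict(self.io_sd_override))


@dataclass(frozen=True)
class AADemand:
    """Solved demand for one amino acid."""

    mmd: Quantity
    io: Quantity
    components: ComponentSet


@dataclass(frozen=True)
class Totals:
    total_iaa: Quantity
    total_daa: Quantity
    total_protein: Quantity


@dataclass(frozen=True)
class MMDResult:
    """Per-amino-acid and aggregate minimum metabolic demands."""

    per_aa: Mapping[AA, AADemand]
    totals: Totals
    constants: ModelConstants

    def mmd(self, aa: AA) -> float:
        return self.per_aa[aa].mmd.mean

    def iaa_share(self) -> float:
        return iaa_share(self.totals)

    def proportions(self) -> dict[AA, dict[str, float]]:
        return source_proportions(self)


def propagate_sd(component_sds: Iterable[float]) -> float:
    """Root-sum-of-squares combination of independent component SDs.

    SD(total) = sqrt(SD_1^2 + SD_2^2 + ...). Permutation-invariant and
    monotone non-decreasing in each argument.
    """
    sds = list(component_sds)
    for s in sds:
        if s < 0 or not math.isfinite(s):
            raise ValidationError(f"SDs must be finite and >= 0, got {s}")
    return math.sqrt(math.fsum(s * s for s in sds))


def solve_mmd(
    components: ComponentSet,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    io_sd_override: float | None = None,
) -> tuple[Quantity, Quantity]:
    """Solve the inevitable-oxidation fixed point for one amino acid.

    Returns ``(mmd, io)`` with

        mmd = (PTO_PP + PTO_PA + EGL + UFAAP + HSNM + OL) / (1 - io_rate)
        io  = io_rate * mmd

    The MMD SD combines the six component SDs with an IO term by
    root-sum-of-squares. The IO SD is ``io_sd_override`` when supplied;
    otherwise it falls back to io_rate/(1 - io_rate) times the
    root-sum-of-squares of the non-IO SDs (the IO mean scaled by the
    relative spread of the remainder).
    """
    non_io_sum = math.fsum(components.means())
    denom = 1.0 - constants.io_rate
    mmd_mean = non_io_sum / denom
    io_mean = constants.io_rate * mmd_mean

    non_io_rss = propagate_sd(components.sds())
    if io_sd_override is not None:
        if io_sd_override < 0:
            raise ValidationError("io_sd_override must be >= 0")
        io_sd = io_sd_override
    else:
        io_sd = constants.io_rate * non_io_rss / denom
    mmd_sd = propagate_sd([io_sd, *components.sds()])
    return Quantity(mmd_mean, mmd_sd), Quantity(io_mean, io_sd)


def solve_table(
    table: LossComponentTable,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> MMDResult:
    """Solve the factorial model for all 16 amino-acid categories and
    aggregate to IAA / DAA / total-protein demands."""
    per_aa: dict[AA, AADemand] = {}
    for aa in ALL_KEYS:
        cs = table.rows[aa]
        mmd, io = solve_mmd(cs, constants, table.io_sd_override.get(aa))
        per_aa[aa] = AADemand(mmd=mmd, io=io, components=cs)
    totals = aggregate({aa: d.mmd for aa, d in per_aa.items()})
    return MMDResult(per_aa=per_aa, totals=totals, constants=constants)


def aggregate(per_aa_mmds: Mapping[AA, Quantity]) -> Totals:
    """Sum per-amino-acid demands into IAA, DAA and total-protein demands.

    Total protein is defined as the sum over all amino acids, not derived
    from nitrogen. SDs combine by root-sum-of-squares.
    """
    missing = [k.value for k in ALL_KEYS if k not in per_aa_mmds]
    if missing:
        raise ValidationError(f"aggregate missing keys: {missing}")

    def _sum(keys: Iterable[AA]) -> Quantity:
        ks = list(keys)
        return Quantity(
            math.fsum(per_aa_mmds[k].mean for k in ks),
            propagate_sd(per_aa_mmds[k].sd for k in ks),
        )

    total_iaa = _sum(IAA_KEYS)
    total_daa = _sum(DAA_KEYS)
    total_protein = Quantity(
        total_iaa.mean + total_daa.mean,
        propagate_sd([total_iaa.sd, total_daa.sd]),
    )
    return Totals(total_iaa, total_daa, total_protein)


def source_proportions(result: MMDResult) -> dict[AA, dict[str, float]]:
    """Fractional contribution of each of the seven loss sources to each
    amino acid's MMD. Shares sum to 1; the oxidative block ``tol`` is
    reported as a convenience (io + pto_pp + pto_pa)."""
    out: dict[AA, dict[str, float]] = {}
    for aa, d in result.per_aa.items():
        if d.mmd.mean <= 0:
            raise ValidationError(
                f"proportions undefined for {aa.value}: MMD is zero"
            )
        shares = {"io": d.io.mean / d.mmd.mean}
        for c in NON_IO_COMPONENTS:
            shares[c] = d.components[c].mean / d.mmd.mean
        shares["tol"] = shares["io"] + shares["pto_pp"] + shares["pto_pa"]
        out[aa] = shares
    return out


def iaa_share(totals: Totals) -> float:
    """Indispensable-amino-acid share of the total-protein demand, percent."""
    if totals.total_protein.mean <= 0:
        raise ValidationError("iaa_share undefined: total protein is zero")
    return 100.0 * totals.total_iaa.mean / totals.total_protein.mean
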