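"""One-at-a-time sensitivity of the demand model.

Each of the seven loss parameters (IO, PTO_PP, PTO_PA, EGL, UFAAP, HSNM,
OL) is varied independently over -20%..+20% in 5% steps while the other
six are held at baseline, and the demand is recomputed at each grid point
as the simple sum of the seven component values. The slope of the fitted
line, b, is the change in demand (mg/kgBW/d) per 1% parameter variation;
because the response is exactly linear, b equals baseline_value / 100.

By default IO is treated as an independent numeric parameter held at its
baseline value while another parameter is varied (so varying EGL for
threonine gives b = 14.5/100 = 0.145). The alternative, re-solving the
inevitable-oxidation fixed point at each grid point so IO tracks the
perturbed demand, is available with ``coupled=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .amino_acids import AA
from .model import (
    ALL_COMPONENTS,
    NON_IO_COMPONENTS,
    MMDResult,
    ValidationError,
)

AGGREGATE_TARGETS = ("total_protein", "total_iaa", "total_daa")

DEFAULT_GRID: tuple[float, ...] = tuple(float(x) for x in range(-20, 25, 5))


@dataclass(frozen=True)
class SensitivityResult:
    target: str
    parameter: str
    grid: tuple[tuple[float, float], ...]   # (variation %, demand mg/kgBW/d)
    slope_b: float                          # mg/kgBW/d per 1% variation
    baseline: float                         # unperturbed parameter value


def baseline_components(result: MMDResult, target: AA | str) -> dict[str, float]:
    """Seven baseline component values (incl. IO) for a per-AA or aggregate
    target. Per-AA IO is the solved io_rate * MMD; aggregates sum the
    per-amino-acid values."""
    if isinstance(target, AA):
        d = result.per_aa[target]
        out = {"io": d.io.mean}
        out.update({c: d.components[c].mean for c in NON_IO_COMPONENTS})
        return out
    if target not in AGGREGATE_TARGETS:
        raise ValidationError(f"unknown sensitivity target {target!r}")
    if target == "total_iaa":
        keys = [aa for aa in result.per_aa if aa.aa_class.value == "IAA"]
    elif target == "total_daa":
        keys = [aa for aa in result.per_aa if aa.aa_class.value == "DAA"]
    else:
        keys = list(result.per_aa)
    out = {"io": sum(result.per_aa[k].io.mean for k in keys)}
    for c in NON_IO_COMPONENTS:
        out[c] = sum(result.per_aa[k].components[c].mean for k in keys)
    return out


def run_sensitivity(
    baseline: MMDResult | Mapping[str, float],
    target: AA | str,
    parameter: str,
    grid: Sequence[float] = DEFAULT_GRID,
    coupled: bool = False,
) -> SensitivityResult:
    """Perturb one loss parameter over a percent-variation grid and fit the
    demand response slope by ordinary least squares.

    ``baseline`` may be a solved :class:`MMDResult` (with ``target`` naming
    an amino acid or aggregate) or a prebuilt mapping of the seven component
    values. With ``coupled=False`` (default) the demand at variation x is

        sum(components) with parameter scaled by (1 + x/100),
        IO held at its baseline numeric value;

    with ``coupled=True`` the non-IO sum is re-divided by (1 - io_rate) so
    IO tracks the perturbed demand (IO variation then scales io_rate).
    """
    if parameter not in ALL_COMPONENTS:
        raise ValidationError(
            f"unknown parameter {parameter!r}; expected one of {ALL_COMPONENTS}"
        )
    if isinstance(baseline, MMDResult):
        comps = baseline_components(baseline, target)
        io_rate = baseline.constants.io_rate
    else:
        comps = dict(baseline)
        io_rate = comps.get("_io_rate", 0.29)
        missing = [c for c in ALL_COMPONENTS if c not in comps]
        if missing:
            raise ValidationError(f"baseline components missing {missing}")
    if comps[parameter] < 0:
        raise ValidationError("baseline parameter value must be >= 0")

    points: list[tuple[float, float]] = []
    for x in grid:
        scale = 1.0 + x / 100.0
        perturbed = dict(comps)
        perturbed[parameter] = comps[parameter] * scale
        if coupled:
            if parameter == "io":
                rate = io_rate * scale
                if rate >= 1.0:
                    raise ValidationError(
                        "coupled IO variation pushes io_rate past 1"
                    )
                mmd = sum(perturbed[c] for c in NON_IO_COMPONENTS) / (1.0 - rate)
            else:
                mmd = sum(perturbed[c] for c in NON_IO_COMPONENTS) / (1.0 - io_rate)
        else:
            mmd = sum(perturbed[c] for c in ALL_COMPONENTS)
        points.append((float(x), mmd))

    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    slope = float(np.polyfit(xs, ys, 1)[0])
    tname = target.value if isinstance(target, AA) else str(target)
    return SensitivityResult(
        target=tname,
        parameter=parameter,
        grid=tuple(points),
        slope_b=slope,
        baseline=comps[parameter],
    )


def run_all(
    result: MMDResult,
    targets: Sequence[AA | str] | None = None,
    parameters: Sequence[str] = ALL_COMPONENTS,
    grid: Sequence[float] = DEFAULT_GRID,
    coupled: bool = False,
) -> list[SensitivityResult]:
    """Sensitivity of every (target, parameter) pair. Default targets are
    all 16 amino acids plus the three aggregates."""
    if targets is None:
        targets = list(result.per_aa) + list(AGGREGATE_TARGETS)
    return [
        run_sensitivity(result, t, p, grid=grid, coupled=coupled)
        for t in targets
        for p in parameters
    ]
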