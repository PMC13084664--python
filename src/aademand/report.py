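"""Tabular reports mirroring the published presentation of the model.

Rounding follows the source's display conventions so tables can be diffed
against transcriptions: 1 decimal for mg/kgBW/d, integers for mg/g
patterns, 2 decimals for reference ratios. All computation upstream is at
full precision; rounding happens only here.
"""

from __future__ import annotations

import math

import pandas as pd

from .amino_acids import AA, ALL_KEYS, DAA_KEYS, IAA_KEYS
from .model import (
    NON_IO_COMPONENTS,
    MMDResult,
    Quantity,
    propagate_sd,
)
from .pack import ParameterPack
from .scoring import ScoringPattern, build_pattern, score


def _fmt1(x: float) -> str:
    # half-up at 1 decimal (the published convention; avoids 31.25 -> 31.2)
    return f"{math.floor(x * 10.0 + 0.5) / 10.0:.1f}"


def _cell(q: Quantity) -> str:
    return f"{_fmt1(q.mean)} ({_fmt1(q.sd)})"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _display_int(mean: float) -> int:
    """Integer display value for a demand via the published convention:
    round to 1 decimal first, then half-up (so 7.465 -> 7.5 -> 8)."""
    return _round_half_up(round(mean, 1))


def demand_table(result: MMDResult,
                 aggregate_hsnm: float | None = None) -> pd.DataFrame:
    """Full demand table: per-amino-acid loss components, IO and MMD as
    "mean (SD)" strings, with IAA/DAA/total-protein totals rows.

    Totals rows are recomputed from the unrounded per-amino-acid values.
    ``aggregate_hsnm`` optionally substitutes the total-protein HSNM cell
    with the nitrogen-based aggregate (6.25 x 5 mg N = 31.25 mg/kgBW/d),
    the convention used for the published total row; the per-amino-acid
    sum is used for the IAA/DAA rows either way.
    """
    rows = []

    def _aa_row(aa: AA) -> dict[str, str]:
        d = result.per_aa[aa]
        rec = {"key": aa.value, "class": aa.aa_class.value,
               "IO": _cell(d.io)}
        for c in NON_IO_COMPONENTS:
            rec[c.upper()] = _cell(d.components[c])
        rec["MMD"] = _cell(d.mmd)
        return rec

    def _total_row(label: str, keys: tuple[AA, ...],
                   total: Quantity, hsnm_override: float | None) -> dict:
        rec = {"key": label, "class": ""}
        io_mean = math.fsum(result.per_aa[k].io.mean for k in keys)
        io_sd = propagate_sd(result.per_aa[k].io.sd for k in keys)
        rec["IO"] = _cell(Quantity(io_mean, io_sd))
        for c in NON_IO_COMPONENTS:
            mean = math.fsum(result.per_aa[k].components[c].mean for k in keys)
            sd = propagate_sd(result.per_aa[k].components[c].sd for k in keys)
            if c == "hsnm" and hsnm_override is not None:
                mean = hsnm_override
            rec[c.upper()] = _cell(Quantity(mean, sd))
        rec["MMD"] = _cell(total)
        return rec

    for aa in IAA_KEYS:
        rows.append(_aa_row(aa))
    rows.append(_total_row("Total IAA", IAA_KEYS, result.totals.total_iaa, None))
    for aa in DAA_KEYS:
        rows.append(_aa_row(aa))
    rows.append(_total_row("Total DAA", DAA_KEYS, result.totals.total_daa, None))
    rows.append(_total_row("Total protein", ALL_KEYS,
                           result.totals.total_protein, aggregate_hsnm))
    return pd.DataFrame(rows).set_index("key")


def comparison_table(result: MMDResult, pack: ParameterPack) -> pd.DataFrame:
    """Demand-vs-requirement comparison: model and FAO/WHO demands
    (mg/kgBW/d), the derived scoring patterns (mg/g protein), body-protein
    composition, and the IAA:DAA split line.

    Scoring-pattern columns are computed from the integer-rounded demand
    values (the published display convention), so e.g. an unrounded demand
    of 21.41 mg/kgBW/d enters the pattern as 21/634*1000 = 33 mg/g.
    """
    model_protein = _display_int(result.totals.total_protein.mean)
    fao_protein = _display_int(pack.fao_requirements["protein"])
    rows = []
    for aa in IAA_KEYS:
        model_d = _display_int(result.per_aa[aa].mmd.mean)
        fao_d = _display_int(pack.fao_requirements[aa.value])
        rows.append({
            "key": aa.value,
            "model_demand": model_d,
            "fao_requirement": fao_d,
            "model_pattern": _round_half_up(1000.0 * model_d / model_protein),
            "fao_pattern": _round_half_up(1000.0 * fao_d / fao_protein),
            "body_protein": _round_half_up(pack.body_composition.get(aa)),
        })
    iaa_model = _display_int(result.totals.total_iaa.mean)
    iaa_fao = _display_int(sum(pack.fao_requirements[aa.value]
                               for aa in IAA_KEYS))
    rows.append({
        "key": "Total IAA",
        "model_demand": iaa_model,
        "fao_requirement": iaa_fao,
        "model_pattern": _round_half_up(1000.0 * iaa_model / model_protein),
        "fao_pattern": _round_half_up(1000.0 * iaa_fao / fao_protein),
        "body_protein": _round_half_up(sum(pack.body_composition.get(aa)
                                           for aa in IAA_KEYS)),
    })
    rows.append({
        "key": "Total protein",
        "model_demand": model_protein,
        "fao_requirement": fao_protein,
        "model_pattern": 1000,
        "fao_pattern": 1000,
        "body_protein": 1000,
    })
    df = pd.DataFrame(rows).set_index("key")

    def _split(iaa: float, protein: float) -> str:
        share = round(100.0 * iaa / protein)
        return f"{share}:{100 - share}"

    body_iaa = sum(pack.body_composition.get(aa) for aa in IAA_KEYS)
    body_total = sum(pack.body_composition.get(aa) for aa in ALL_KEYS)
    df.attrs["iaa_daa_split"] = {
        "model": _split(result.totals.total_iaa.mean,
                        result.totals.total_protein.mean),
        "fao": _split(iaa_fao, fao_protein),
        "body_protein": _split(body_iaa, body_total),
    }
    return df


def model_pattern(result: MMDResult, pack: ParameterPack) -> ScoringPattern:
    """Scoring pattern from the solved demands (label "MMD")."""
    return ScoringPattern(
        label="MMD",
        values=build_pattern(
            {aa: result.per_aa[aa].mmd.mean for aa in IAA_KEYS},
            result.totals.total_protein.mean / 1000.0,
        ).values,
        protein_requirement=pack.protein_requirement["MMD"],
    )


def fao_pattern(pack: ParameterPack) -> ScoringPattern:
    """Scoring pattern from the current FAO/WHO requirements (label "FAO")."""
    return ScoringPattern(
        label="FAO",
        values=build_pattern(
            pack.fao_iaa_demands(),
            pack.fao_requirements["protein"] / 1000.0,
        ).values,
        protein_requirement=pack.protein_requirement["FAO"],
    )


def diaas_table(pack: ParameterPack, result: MMDResult) -> pd.DataFrame:
    """Per-source protein-quality table: reference ratios per IAA (2 dp),
    DIAAS, first-limiting amino acids and required intake (g/kgBW/d),
    under both the model and FAO/WHO patterns."""
    patterns = (model_pattern(result, pack), fao_pattern(pack))
    rows = []
    for source in pack.sources:
        for pattern in patterns:
            res = score(source, pattern)
            rec = {"source": source.name, "pattern": pattern.label}
            for aa in IAA_KEYS:
                rec[aa.value] = round(res.reference_ratios[aa], 2)
            rec["DIAAS"] = round(res.diaas, 2)
            rec["limiting"] = "+".join(sorted(a.value for a in res.limiting))
            rec["required_intake"] = round(res.required_intake, 2)
            rows.append(rec)
    return pd.DataFrame(rows)


def sensitivity_table(results) -> pd.DataFrame:
    """Long-format slope table (slopes at 3 dp)."""
    return pd.DataFrame(
        [{"target": r.target, "parameter": r.parameter,
          "slope_b": round(r.slope_b, 3)} for r in results]
    )
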