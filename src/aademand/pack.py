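"""Parameter-pack loading, validation and serialization.

A parameter pack bundles everything the model needs: the per-amino-acid
loss-component table, model constants, the current FAO/WHO requirement
values, body-protein composition, and protein sources in reference-ratio
form for quality scoring. The packaged default transcribes the published
tables; user packs are CSV/JSON files validated against the same schema.

Synthetic fixture files (appendix-style primary inputs that are not
printed in the source tables: dermal composition, urinary-study and
metabolite-excretion records) carry ``_synthetic`` in their filename and
are back-constructed to reproduce the published loss columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .amino_acids import AA, ALL_KEYS, IAA_KEYS
from .losses import (
    CompositionTable,
    MetaboliteLossRecord,
    NitrogenLossSpec,
    UrinaryStudyRecord,
)
from .model import (
    ComponentSet,
    LossComponentTable,
    ModelConstants,
    Quantity,
    ValidationError,
)
from .scoring import ProteinSource

_COMPONENT_COLS = [
    "aa_code", "class",
    "pto_pp_mean", "pto_pp_sd", "pto_pa_mean", "pto_pa_sd",
    "egl_mean", "egl_sd", "ufaap_mean", "ufaap_sd",
    "hsnm_mean", "hsnm_sd", "ol_mean", "ol_sd",
]


class PackError(ValidationError):
    """Schema or parse failure while loading a parameter pack."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("aademand").joinpath("data", name)))


def _read_csv(path: Path, required: list[str], label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise PackError(f"{label}: cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PackError(f"{label}: missing columns {missing} in {path}")
    return df


def _parse_aa(code: str, label: str) -> AA:
    try:
        return AA(code)
    except ValueError as exc:
        raise PackError(f"{label}: unknown amino-acid code {code!r}") from exc


def load_components(path: Path | str) -> LossComponentTable:
    """Load a per-amino-acid loss-component CSV."""
    df = _read_csv(Path(path), _COMPONENT_COLS, "component table")
    rows: dict[AA, ComponentSet] = {}
    overrides: dict[AA, float] = {}
    for rec in df.to_dict("records"):
        aa = _parse_aa(str(rec["aa_code"]), "component table")
        try:
            rows[aa] = ComponentSet(
                pto_pp=Quantity(float(rec["pto_pp_mean"]), float(rec["pto_pp_sd"])),
                pto_pa=Quantity(float(rec["pto_pa_mean"]), float(rec["pto_pa_sd"])),
                egl=Quantity(float(rec["egl_mean"]), float(rec["egl_sd"])),
                ufaap=Quantity(float(rec["ufaap_mean"]), float(rec["ufaap_sd"])),
                hsnm=Quantity(float(rec["hsnm_mean"]), float(rec["hsnm_sd"])),
                ol=Quantity(float(rec["ol_mean"]), float(rec["ol_sd"])),
            )
        except (TypeError, ValueError) as exc:
            raise PackError(
                f"component table: bad value in row {rec['aa_code']}: {exc}"
            ) from exc
        if "io_sd_override" in rec and pd.notna(rec["io_sd_override"]):
            overrides[aa] = float(rec["io_sd_override"])
    return LossComponentTable(rows=rows, io_sd_override=overrides)


def save_components(table: LossComponentTable, path: Path | str) -> None:
    rows = []
    for aa in ALL_KEYS:
        cs = table.rows[aa]
        rec = {"aa_code": aa.value, "class": aa.aa_class.value}
        for c in ("pto_pp", "pto_pa", "egl", "ufaap", "hsnm", "ol"):
            rec[f"{c}_mean"] = repr(cs[c].mean)
            rec[f"{c}_sd"] = repr(cs[c].sd)
        if aa in table.io_sd_override:
            rec["io_sd_override"] = repr(table.io_sd_override[aa])
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_constants(path: Path | str | None = None) -> ModelConstants:
    """Model constants from a JSON file (packaged defaults when None)."""
    p = _data_path("constants.json") if path is None else Path(path)
    with open(p) as fh:
        raw = json.load(fh)
    kwargs = {
        k: float(raw[k])
        for k in ("io_rate", "pto_pa_fraction", "pto_pp_fraction",
                  "n_to_protein", "body_weight", "creatinine_excretion")
        if k in raw
    }
    return ModelConstants(**kwargs)


@dataclass(frozen=True)
class ParameterPack:
    """Everything needed to run the model and its downstream analyses."""

    components: LossComponentTable
    constants: ModelConstants
    aggregate_components: pd.DataFrame
    fao_requirements: Mapping[str, float]        # "protein" + 9 IAA codes
    body_composition: CompositionTable
    dermal_composition: CompositionTable
    nitrogen_loss: NitrogenLossSpec
    sources: tuple[ProteinSource, ...]
    protein_requirement: Mapping[str, float]     # g/kgBW/d per pattern label
    ufaap_records: tuple[UrinaryStudyRecord, ...] = ()
    metabolite_records: tuple[MetaboliteLossRecord, ...] = ()
    published_mmd: Mapping[AA, Quantity] = field(default_factory=dict)

    def fao_iaa_demands(self) -> dict[AA, float]:
        return {aa: self.fao_requirements[aa.value] for aa in IAA_KEYS}


def _load_composition(path: Path, label: str) -> CompositionTable:
    df = _read_csv(path, ["aa_code", "mg_per_g"], label)
    values = {
        _parse_aa(str(r["aa_code"]), label): float(r["mg_per_g"])
        for r in df.to_dict("records")
    }
    return CompositionTable(values=values, label=label)


def _load_sources(path: Path) -> tuple[ProteinSource, ...]:
    df = _read_csv(path, ["source", "aa_code", "mmd_ratio", "fao_ratio"],
                   "reference ratios")
    out = []
    for name, grp in df.groupby("source", sort=False):
        ratios = {"MMD": {}, "FAO": {}}
        for r in grp.to_dict("records"):
            aa = _parse_aa(str(r["aa_code"]), "reference ratios")
            ratios["MMD"][aa] = float(r["mmd_ratio"])
            ratios["FAO"][aa] = float(r["fao_ratio"])
        out.append(ProteinSource(name=str(name), reference_ratios=ratios))
    return tuple(out)


def load_pack(directory: Path | str | None = None) -> ParameterPack:
    """Load a parameter pack from a directory of CSV/JSON files; with no
    argument, load the packaged default transcription."""
    base = Path(str(resources.files("aademand").joinpath("data"))) \
        if directory is None else Path(directory)
    if not base.is_dir():
        raise PackError(f"pack directory not found: {base}")

    components = load_components(base / "loss_components.csv")
    constants = load_constants(base / "constants.json"
                               if (base / "constants.json").exists() else None)
    agg = _read_csv(base / "aggregate_components.csv",
                    ["target", "io_mean"], "aggregate components")

    fao_df = _read_csv(base / "fao_requirements.csv",
                       ["key", "requirement_mg_per_kg_d"], "FAO requirements")
    fao = {str(r["key"]): float(r["requirement_mg_per_kg_d"])
           for r in fao_df.to_dict("records")}
    missing = [k.value for k in IAA_KEYS if k.value not in fao]
    if missing or "protein" not in fao:
        raise PackError(f"FAO requirements missing keys: {missing or ['protein']}")

    body = _load_composition(base / "body_protein_composition.csv",
                             "body_protein")
    dermal = _load_composition(base / "dermal_composition_synthetic.csv",
                               "dermal")

    with open(base / "constants.json"
              if (base / "constants.json").exists()
              else _data_path("constants.json")) as fh:
        raw = json.load(fh)
    nl = raw.get("nitrogen_loss", {})
    nitrogen = NitrogenLossSpec(
        total_n=float(nl.get("total_n", 5.0)),
        miscellaneous_n=float(nl.get("miscellaneous_n", 1.8)),
        total_n_sd=float(nl.get("total_n_sd", 0.9)),
    )
    preq = {k.upper(): float(v)
            for k, v in raw.get("protein_requirement",
                                {"mmd": 0.634, "fao": 0.66}).items()}

    sources = _load_sources(base / "reference_ratios.csv")

    ufaap_path = base / "urinary_ufaap_synthetic.csv"
    ufaap_records: tuple[UrinaryStudyRecord, ...] = ()
    if ufaap_path.exists():
        df = _read_csv(ufaap_path, ["aa", "value", "sd", "n_subjects",
                                    "body_weight", "unit"], "urinary records")
        ufaap_records = tuple(
            UrinaryStudyRecord(
                aa=str(r["aa"]), value=float(r["value"]), sd=float(r["sd"]),
                n_subjects=int(r["n_subjects"]),
                body_weight=float(r["body_weight"]), unit=str(r["unit"]),
            )
            for r in df.to_dict("records")
        )

    met_path = base / "metabolite_losses_synthetic.csv"
    metabolite_records: tuple[MetaboliteLossRecord, ...] = ()
    if met_path.exists():
        df = _read_csv(met_path, ["metabolite", "parent_aa", "excretion",
                                  "stoichiometry", "unit"], "metabolite records")
        metabolite_records = tuple(
            MetaboliteLossRecord(
                metabolite=str(r["metabolite"]), parent_aa=str(r["parent_aa"]),
                excretion=float(r["excretion"]), sd=float(r.get("sd", 0.0)),
                stoichiometry=float(r["stoichiometry"]), unit=str(r["unit"]),
            )
            for r in df.to_dict("records")
        )

    comp_df = pd.read_csv(base / "loss_components.csv")
    published: dict[AA, Quantity] = {}
    if "mmd_published" in comp_df.columns:
        for r in comp_df.to_dict("records"):
            published[_parse_aa(str(r["aa_code"]), "component table")] = Quantity(
                float(r["mmd_published"]),
                float(r.get("mmd_sd_published", 0.0)),
            )

    return ParameterPack(
        components=components,
        constants=constants,
        aggregate_components=agg,
        fao_requirements=fao,
        body_composition=body,
        dermal_composition=dermal,
        nitrogen_loss=nitrogen,
        sources=sources,
        protein_requirement=preq,
        ufaap_records=ufaap_records,
        metabolite_records=metabolite_records,
        published_mmd=published,
    )


def get_source(pack: ParameterPack, name: str) -> ProteinSource:
    for s in pack.sources:
        if s.name == name:
            return s
    raise PackError(
        f"unknown protein source {name!r}; "
        f"available: {[s.name for s in pack.sources]}"
    )
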