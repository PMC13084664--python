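"""Amino-acid keys used throughout the factorial demand model.

The model works at the level of 16 amino-acid categories: nine indispensable
(IAA) groups and seven dispensable (DAA) groups. Four categories are
composites that are never decomposed — SAA (methionine + cysteine), AAA
(phenylalanine + tyrosine), Asx (aspartate + asparagine) and Glx
(glutamate + glutamine) — because the underlying loss data (gut endogenous
secretion, turnover-associated oxidation) are reported at that resolution.
"""

from __future__ import annotations

from enum import Enum


class AAClass(str, Enum):
    """Indispensable (essential) vs dispensable (nonessential)."""

    IAA = "IAA"
    DAA = "DAA"


class AA(str, Enum):
    """The 16 amino-acid categories of the factorial model."""

    HIS = "His"
    ILE = "Ile"
    LEU = "Leu"
    LYS = "Lys"
    SAA = "SAA"
    AAA = "AAA"
    THR = "Thr"
    TRP = "Trp"
    VAL = "Val"
    ALA = "Ala"
    ARG = "Arg"
    ASX = "Asx"
    GLX = "Glx"
    GLY = "Gly"
    PRO = "Pro"
    SER = "Ser"

    @property
    def aa_class(self) -> AAClass:
        return AAClass.IAA if self in IAA_KEYS else AAClass.DAA


IAA_KEYS: tuple[AA, ...] = (
    AA.HIS, AA.ILE, AA.LEU, AA.LYS, AA.SAA, AA.AAA, AA.THR, AA.TRP, AA.VAL,
)
DAA_KEYS: tuple[AA, ...] = (
    AA.ALA, AA.ARG, AA.ASX, AA.GLX, AA.GLY, AA.PRO, AA.SER,
)
ALL_KEYS: tuple[AA, ...] = IAA_KEYS + DAA_KEYS

COMPOSITE_KEYS: frozenset[AA] = frozenset({AA.SAA, AA.AAA, AA.ASX, AA.GLX})

# Individual amino acids (and common spellings) mapped onto model categories.
# Inputs keyed to e.g. methionine or cysteine aggregate under SAA.
_ALIASES: dict[str, AA] = {
    "his": AA.HIS, "histidine": AA.HIS,
    "ile": AA.ILE, "isoleucine": AA.ILE,
    "leu": AA.LEU, "leucine": AA.LEU,
    "lys": AA.LYS, "lysine": AA.LYS,
    "saa": AA.SAA, "met": AA.SAA, "methionine": AA.SAA,
    "cys": AA.SAA, "cysteine": AA.SAA, "met+cys": AA.SAA,
    "aaa": AA.AAA, "phe": AA.AAA, "phenylalanine": AA.AAA,
    "tyr": AA.AAA, "tyrosine": AA.AAA, "phe+tyr": AA.AAA,
    "thr": AA.THR, "threonine": AA.THR,
    "trp": AA.TRP, "tryptophan": AA.TRP,
    "val": AA.VAL, "valine": AA.VAL,
    "ala": AA.ALA, "alanine": AA.ALA,
    "arg": AA.ARG, "arginine": AA.ARG,
    "asx": AA.ASX, "asp": AA.ASX, "aspartate": AA.ASX, "aspartic acid": AA.ASX,
    "asn": AA.ASX, "asparagine": AA.ASX, "asp+asn": AA.ASX,
    "glx": AA.GLX, "glu": AA.GLX, "glutamate": AA.GLX, "glutamic acid": AA.GLX,
    "gln": AA.GLX, "glutamine": AA.GLX, "glu+gln": AA.GLX,
    "gly": AA.GLY, "glycine": AA.GLY,
    "pro": AA.PRO, "proline": AA.PRO,
    "ser": AA.SER, "serine": AA.SER,
}

# Average molar masses of the free amino acids, g/mol.
MOLAR_MASS: dict[str, float] = {
    "histidine": 155.15,
    "isoleucine": 131.17,
    "leucine": 131.17,
    "lysine": 146.19,
    "methionine": 149.21,
    "cysteine": 121.16,
    "phenylalanine": 165.19,
    "tyrosine": 181.19,
    "threonine": 119.12,
    "tryptophan": 204.23,
    "valine": 117.15,
    "alanine": 89.09,
    "arginine": 174.20,
    "aspartate": 133.10,
    "asparagine": 132.12,
    "glutamate": 147.13,
    "glutamine": 146.15,
    "glycine": 75.07,
    "proline": 115.13,
    "serine": 105.09,
}


def resolve_key(name: str) -> AA:
    """Map an amino-acid name or code (e.g. ``"Met"``, ``"glycine"``) to its
    model category.

    Raises ``KeyError`` for unrecognised names.
    """
    key = name.strip().lower()
    if key not in _ALIASES:
        raise KeyError(f"unknown amino acid: {name!r}")
    return _ALIASES[key]


def molar_mass(name: str) -> float:
    """Average molar mass (g/mol) of a free amino acid by name."""
    key = name.strip().lower()
    if key not in MOLAR_MASS:
        raise KeyError(f"no molar mass for amino acid: {name!r}")
    return MOLAR_MASS[key]
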