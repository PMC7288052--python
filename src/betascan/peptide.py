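"""Peptide sequences, backbone homologation scans and exact-mass bookkeeping.

A backbone homologation replaces an α-amino-acid residue by its β²- or
β³-homologue, inserting one methylene unit into the backbone.  For a β²-homo
residue the side chain sits on the carbon adjacent to the carbonyl, so the
"same" spatial arrangement of substituents usually carries the opposite
CIP descriptor relative to the α-residue.  Compositionally the two classes
are identical: each adds exactly one CH2 to the residue formula.

Molecular formulas are computed from free-amino-acid compositions with the
condensation water removed centrally (−(n−1)·H2O for n residues) and a
C-terminal amide correction (−O, +N, +H).  Monoisotopic masses use the
principal-isotope masses of C/H/N/O/S; protonated ions add one proton mass.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "BackboneClass",
    "Stereo",
    "CTerminus",
    "MolecularFormula",
    "Residue",
    "PeptideSequence",
    "ScanSpec",
    "Analogue",
    "UnknownSideChainError",
    "HomologationError",
    "TAPP",
    "tapp_scan_spec",
    "homologate",
    "enumerate_scan",
    "molecular_formula",
    "monoisotopic_mass",
    "PROTON_MASS",
    "CH2_MASS",
]

# Monoisotopic (principal isotope) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.97207117,
}

PROTON_MASS = 1.00727646  # Da, mass of H+ ([M+H]+ adduct increment)


class BackboneClass(str, Enum):
    ALPHA = "alpha"
    BETA2H = "beta2h"
    BETA3H = "beta3h"


class Stereo(str, Enum):
    R = "R"
    S = "S"
    D = "D"
    L = "L"
    ACHIRAL = "achiral"


class CTerminus(str, Enum):
    AMIDE = "amide"
    ACID = "acid"


class UnknownSideChainError(KeyError):
    """Side-chain id absent from the built-in composition table."""


class HomologationError(ValueError):
    """Invalid homologation request (bad position or already-β residue)."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map with element-wise arithmetic; counts never negative."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in cleaned.items():
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a plain Hill-style string like ``C30H35N5O5``."""
        import re

        counts: Counter[str] = Counter()
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if m.start() != pos or not m.group(0):
                break
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.update(other.counts)
        return MolecularFormula(c)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.subtract(other.counts)
        return MolecularFormula(c)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(
            f"{el}{self.counts[el]}" if self.counts[el] != 1 else el for el in order
        )


_F = MolecularFormula.parse

WATER = _F("H2O")
CH2 = _F("CH2")
CH2_MASS = MONOISOTOPIC_MASS["C"] + 2 * MONOISOTOPIC_MASS["H"]  # 14.01565 Da

# Free (unbound) amino-acid formulas; the condensation water is removed
# centrally when a chain is assembled.  "mTyr" is the meta-hydroxyphenyl
# positional isomer of tyrosine and shares Tyr's composition.
FREE_AA_FORMULA: dict[str, MolecularFormula] = {
    "Gly": _F("C2H5NO2"),
    "Ala": _F("C3H7NO2"),
    "Ser": _F("C3H7NO3"),
    "Pro": _F("C5H9NO2"),
    "Val": _F("C5H11NO2"),
    "Thr": _F("C4H9NO3"),
    "Leu": _F("C6H13NO2"),
    "Ile": _F("C6H13NO2"),
    "Met": _F("C5H11NO2S"),
    "Phe": _F("C9H11NO2"),
    "Tyr": _F("C9H11NO3"),
    "mTyr": _F("C9H11NO3"),
    "Trp": _F("C11H12N2O2"),
}

_CHIRAL_SIDE_CHAINS = frozenset(FREE_AA_FORMULA) - {"Gly"}


@dataclass(frozen=True)
class Residue:
    """One residue: side-chain identity, backbone class and stereo label.

    ``tentative_assignment`` marks configurations assigned indirectly (by
    HPLC retention order rather than synthesis from a resolved enantiomer);
    such names conventionally carry a trailing asterisk.
    """

    side_chain_id: str
    backbone_class: BackboneClass = BackboneClass.ALPHA
    stereo: Stereo = Stereo.L
    tentative_assignment: bool = False

    def __post_init__(self) -> None:
        if self.stereo in (Stereo.R, Stereo.S) and not self.is_chiral:
            raise ValueError(
                f"R/S stereo label on achiral residue {self.side_chain_id}"
            )

    @property
    def is_chiral(self) -> bool:
        return self.side_chain_id in _CHIRAL_SIDE_CHAINS

    @property
    def formula(self) -> MolecularFormula:
        try:
            base = FREE_AA_FORMULA[self.side_chain_id]
        except KeyError:
            raise UnknownSideChainError(self.side_chain_id) from None
        if self.backbone_class is BackboneClass.ALPHA:
            return base
        return base + CH2  # one extra backbone methylene for β²h / β³h

    @property
    def label(self) -> str:
        """Short residue label, e.g. ``D-Ala`` or ``(R)-β2hPhe``."""
        sc = "m-Tyr" if self.side_chain_id == "mTyr" else self.side_chain_id
        if self.backbone_class is BackboneClass.ALPHA:
            prefix = {Stereo.D: "D-", Stereo.R: "(R)-", Stereo.S: "(S)-"}.get(
                self.stereo, ""
            )
            return f"{prefix}{sc}"
        beta = "β2h" if self.backbone_class is BackboneClass.BETA2H else "β3h"
        joiner = "-" if sc.startswith("m-") else ""
        stereo = f"({self.stereo.value})-" if self.stereo in (Stereo.R, Stereo.S) else ""
        return f"{stereo}{beta}{joiner}{sc}"


@dataclass(frozen=True)
class PeptideSequence:
    """Ordered residues, 1-based from the N-terminus, plus C-terminal state."""

    residues: tuple[Residue, ...]
    c_terminus: CTerminus = CTerminus.AMIDE

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("peptide needs at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> Residue:
        if not 1 <= position <= len(self):
            raise HomologationError(
                f"position {position} outside 1..{len(self)}"
            )
        return self.residues[position - 1]

    def with_residue(self, position: int, residue: Residue) -> "PeptideSequence":
        self.residue_at(position)
        res = list(self.residues)
        res[position - 1] = residue
        return replace(self, residues=tuple(res))

    def __str__(self) -> str:
        body = "-".join(r.label for r in self.residues)
        tail = "NH2" if self.c_terminus is CTerminus.AMIDE else "OH"
        return f"H-{body}-{tail}"


@dataclass(frozen=True)
class ScanSpec:
    """Which positions to homologate, with which stereo labels and side-chain
    variants (e.g. position 1 additionally scanned with *m*-Tyr)."""

    positions: frozenset[int]
    stereo_set: frozenset[Stereo] = frozenset({Stereo.R, Stereo.S})
    side_chain_variants: Mapping[int, tuple[str, ...]] = field(default_factory=dict)
    backbone_class: BackboneClass = BackboneClass.BETA2H

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", frozenset(self.positions))
        object.__setattr__(self, "stereo_set", frozenset(self.stereo_set))
        object.__setattr__(
            self,
            "side_chain_variants",
            {int(k): tuple(v) for k, v in dict(self.side_chain_variants).items()},
        )
        if not self.stereo_set <= {Stereo.R, Stereo.S}:
            raise ValueError("stereo_set must be a subset of {R, S}")


@dataclass(frozen=True)
class Analogue:
    """A scanned peptide with its systematic name and exact masses."""

    name: str
    sequence: PeptideSequence
    formula: MolecularFormula
    mass_neutral: float
    mass_mh: float
    tentative: bool = False

    @property
    def display_name(self) -> str:
        """Name with the trailing asterisk marking HPLC-assigned configurations."""
        return self.name + ("*" if self.tentative else "")

    def name_ascii(self) -> str:
        return self.name.replace("β", "b")


def molecular_formula(seq: PeptideSequence) -> MolecularFormula:
    """Formula of the peptide: Σ free-AA formulas − (n−1)·H2O, with the
    amide C-terminus converting the terminal −OH into −NH2 (−O, +N, +H)."""
    total = seq.residues[0].formula
    for res in seq.residues[1:]:
        total = total + res.formula - WATER
    if seq.c_terminus is CTerminus.AMIDE:
        total = total - _F("O") + _F("NH")
    return total


def monoisotopic_mass(formula: MolecularFormula, adduct: str = "neutral") -> float:
    """Monoisotopic mass in Da; ``adduct`` is ``neutral`` or ``M+H``."""
    mass = 0.0
    for el, n in formula.counts.items():
        try:
            mass += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise KeyError(f"element {el} absent from the mass table") from None
    if adduct == "M+H":
        mass += PROTON_MASS
    elif adduct != "neutral":
        raise ValueError(f"unknown adduct {adduct!r}")
    return mass


def _analogue_name(residue: Residue, position: int, unicode_beta: bool = True) -> str:
    name = f"[{residue.label}{position}]-TAPP"
    return name if unicode_beta else name.replace("β", "b")


def _make_analogue(seq: PeptideSequence, name: str, tentative: bool) -> Analogue:
    formula = molecular_formula(seq)
    neutral = monoisotopic_mass(formula)
    return Analogue(
        name=name,
        sequence=seq,
        formula=formula,
        mass_neutral=neutral,
        mass_mh=neutral + PROTON_MASS,
        tentative=tentative,
    )


def homologate(
    parent: PeptideSequence,
    position: int,
    backbone_class: BackboneClass = BackboneClass.BETA2H,
    stereo: Stereo = Stereo.R,
    side_chain_override: str | None = None,
) -> Analogue:
    """Replace the α-residue at ``position`` by its β-homologue.

    The returned analogue differs from the parent only at that position;
    its formula is the parent formula plus one CH2.  Names follow the
    bracket convention, e.g. ``[(S)-β2hAla2]-TAPP``; a side-chain override
    whose configuration is only assignable indirectly (Tyr/m-Tyr here)
    yields a tentative assignment, rendered with a trailing asterisk.
    """
    old = parent.residue_at(position)
    if old.backbone_class is not BackboneClass.ALPHA:
        raise HomologationError(
            f"residue at position {position} is already {old.backbone_class.value}"
        )
    if backbone_class is BackboneClass.ALPHA:
        raise HomologationError("homologation target must be a β class")
    side_chain = side_chain_override or old.side_chain_id
    if side_chain not in FREE_AA_FORMULA:
        raise UnknownSideChainError(side_chain)
    tentative = side_chain in ("Tyr", "mTyr")
    new = Residue(
        side_chain_id=side_chain,
        backbone_class=backbone_class,
        stereo=stereo,
        tentative_assignment=tentative,
    )
    seq = parent.with_residue(position, new)
    return _make_analogue(seq, _analogue_name(new, position), tentative)


def enumerate_scan(parent: PeptideSequence, spec: ScanSpec) -> list[Analogue]:
    """Enumerate one analogue per (position × side-chain × stereo) combination.

    Deterministic order: position ascending; at each position the parent
    side chain before any variants; R before S.  The empty spec yields [].
    """
    stereo_order = [s for s in (Stereo.R, Stereo.S) if s in spec.stereo_set]
    analogues: list[Analogue] = []
    seen: set[str] = set()
    for position in sorted(spec.positions):
        base = parent.residue_at(position).side_chain_id
        side_chains = [base] + [
            sc for sc in spec.side_chain_variants.get(position, ()) if sc != base
        ]
        for side_chain, stereo in itertools.product(side_chains, stereo_order):
            override = None if side_chain == base else side_chain
            ana = homologate(parent, position, spec.backbone_class, stereo, override)
            if ana.name not in seen:
                seen.add(ana.name)
                analogues.append(ana)
    return analogues


def _tapp() -> PeptideSequence:
    return PeptideSequence(
        residues=(
            Residue("Tyr", stereo=Stereo.L),
            Residue("Ala", stereo=Stereo.D),
            Residue("Phe", stereo=Stereo.L),
            Residue("Phe", stereo=Stereo.L),
        ),
        c_terminus=CTerminus.AMIDE,
    )


#: The parent tetrapeptide H-Tyr-D-Ala-Phe-Phe-NH2.
TAPP: PeptideSequence = _tapp()


def tapp_scan_spec() -> ScanSpec:
    """The full β²-scan of TAPP: all four positions, both configurations,
    plus *m*-Tyr as an extra side chain in position 1 (10 analogues)."""
    return ScanSpec(
        positions=frozenset({1, 2, 3, 4}),
        stereo_set=frozenset({Stereo.R, Stereo.S}),
        side_chain_variants={1: ("mTyr",)},
        backbone_class=BackboneClass.BETA2H,
    )


def scan_table(analogues: Iterable[Analogue]):
    """Analogue table as a DataFrame (name, sequence, formula, masses)."""
    import pandas as pd

    analogues = list(analogues)
    return pd.DataFrame(
        {
            "name": [a.name for a in analogues],
            "sequence": [str(a.sequence) for a in analogues],
            "formula": [str(a.formula) for a in analogues],
            "mass_neutral": [round(a.mass_neutral, 4) for a in analogues],
            "mass_mh": [round(a.mass_mh, 4) for a in analogues],
        }
    )
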