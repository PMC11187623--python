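"""Monoisotopic mass arithmetic for biotransformation annotation.

Implements a small elemental-formula parser, the electrospray adduct table
used for ion-form annotation, and the phase I / phase II biotransformation
mass-shift library against which putative xenobiotic features are matched.
Every mass delta in the library is derived from its elemental formula delta
and the monoisotopic atomic masses below, never stored as a magic number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

#: Monoisotopic atomic masses (u), most abundant isotope.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727646...
#: 13C - 12C spacing between isotopologue peaks.
ISOTOPOLOGUE_SPACING = 13.0033548378 - 12.0

_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a signed elemental formula delta into element counts.

    Accepts plain formulas (``C6H8O6``), and signed segments
    (``-C6H4``, ``-C6H4+O``) for losses and gains.
    """
    counts: dict[str, int] = {}
    for sign_str, segment in re.findall(r"([+-]?)([A-Za-z0-9]+)", formula):
        sign = -1 if sign_str == "-" else 1
        pos = 0
        for m in _TOKEN.finditer(segment):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula segment {segment!r}")
            pos = m.end()
            if not m.group(0):
                break
            elem, count = m.group(1), m.group(2)
            if elem not in ATOMIC_MASS:
                raise ValueError(f"unknown element {elem!r} in {formula!r}")
            n = int(count) if count else 1
            counts[elem] = counts.get(elem, 0) + sign * n
        if pos != len(segment):
            raise ValueError(f"cannot parse formula segment {segment!r}")
    return {e: n for e, n in counts.items() if n != 0}


def formula_mass(formula: str) -> float:
    """Monoisotopic mass (u) of a signed elemental formula."""
    return sum(ATOMIC_MASS[e] * n for e, n in parse_formula(formula).items())


#: Neutral molecular formula of triphenyl phosphate, the exposure chemical of
#: the rat study this package's defaults emulate.
TPHP_FORMULA = "C18H15O4P"


@dataclass(frozen=True)
class Adduct:
    """An electrospray ion form: m/z = neutral mass + ``mass_offset``."""

    name: str
    polarity: str  # "positive" | "negative"
    mass_offset: float


ADDUCTS: tuple[Adduct, ...] = (
    Adduct("[M+H]+", "positive", PROTON_MASS),
    Adduct("[M+Na]+", "positive", ATOMIC_MASS["Na"] - ELECTRON_MASS),
    Adduct("[M+NH4]+", "positive", formula_mass("NH4") - ELECTRON_MASS),
    Adduct("[M-H]-", "negative", -PROTON_MASS),
)


def adducts_for_polarity(polarity: str) -> tuple[Adduct, ...]:
    return tuple(a for a in ADDUCTS if a.polarity == polarity)


@dataclass(frozen=True)
class MassShift:
    """A named biotransformation: parent mass + ``mass_delta`` = product mass."""

    name: str
    phase: str  # "I" | "II"
    formula_delta: str

    @property
    def mass_delta(self) -> float:
        return formula_mass(self.formula_delta)


class MassShiftLibrary:
    """Named phase I / phase II biotransformation mass deltas.

    Phase I shifts are functionalization reactions (oxidation, aryl loss);
    phase II shifts are conjugations (glucuronide, sulfate, glutathione-
    related).  Deltas are computed from formula deltas at access time.
    """

    def __init__(self, shifts: list[MassShift] | None = None) -> None:
        self.shifts: list[MassShift] = list(shifts) if shifts is not None else list(DEFAULT_SHIFTS)
        names = [s.name for s in self.shifts]
        if len(set(names)) != len(names):
            raise ValueError("shift names must be unique")

    def __iter__(self):
        return iter(self.shifts)

    def __len__(self) -> int:
        return len(self.shifts)

    def by_name(self, name: str) -> MassShift:
        for s in self.shifts:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_tsv(self, path) -> None:
        rows = [
            {"name": s.name, "phase": s.phase, "formula_delta": s.formula_delta,
             "mass_delta": s.mass_delta}
            for s in self.shifts
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MassShiftLibrary":
        df = pd.read_csv(path, sep="\t")
        shifts = [MassShift(r["name"], str(r.get("phase", "")), r["formula_delta"])
                  for _, r in df.iterrows()]
        return cls(shifts)


DEFAULT_SHIFTS: tuple[MassShift, ...] = (
    # phase I
    MassShift("aryl loss", "I", "-C6H4"),
    MassShift("hydroxylation", "I", "O"),
    MassShift("dihydroxylation", "I", "O2"),
    # phase II
    MassShift("glucuronidation", "II", "C6H8O6"),
    MassShift("sulfation", "II", "SO3"),
    MassShift("glutathione conjugation", "II", "C10H15N3O6S"),
    MassShift("cysteine conjugation", "II", "C3H5NO2S"),
    MassShift("N-acetylcysteine conjugation", "II", "C5H7NO3S"),
    MassShift("glycine conjugation", "II", "C2H3NO"),
    MassShift("taurine conjugation", "II", "C2H5NO2S"),
    MassShift("methylation", "II", "CH2"),
)


def ppm_error(observed: float, expected: float) -> float:
    return (observed - expected) / expected * 1e6
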