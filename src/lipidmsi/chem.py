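"""Lipid chemistry: shorthand parsing, molecular formulas, monoisotopic masses, adducts.

Shorthand follows the class(totalCarbons:totalDoubleBonds[;O]) convention,
e.g. ``TG(52:2)``, ``FA (18:2;O)``; individual acyl chains may be given
separated by underscores or slashes (``TG 14:0_16:0_18:1``, ``PG 17:0/17:0``)
and are summed into the species-level totals while being retained for
fragment-rule generation.  Masses are monoisotopic, built from IUPAC atomic
masses; adduct shifts are electron-mass corrected so theoretical m/z values
are sub-ppm accurate over the m/z 100-1200 acquisition range.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ATOMIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "LipidRecord",
    "AdductSpec",
    "ADDUCTS",
    "LIPID_CLASSES",
    "parse_shorthand",
    "formula_mass",
    "formula_to_string",
    "acyl_mass",
    "adduct_mz",
    "ppm_deviation",
    "normalize_adduct_name",
]

# IUPAC 2021 monoisotopic atomic masses (Da).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ATOMIC_MASS["H"] - ELECTRON_MASS  # 1.00727645...

WATER_MASS = 2 * ATOMIC_MASS["H"] + ATOMIC_MASS["O"]  # 18.0105646
CO2_MASS = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["O"]  # 43.9898292
NH3_MASS = ATOMIC_MASS["N"] + 3 * ATOMIC_MASS["H"]  # 17.0265491

# Per-class formula rules as a function of (c, d, x) = total acyl carbons,
# total double bonds, extra oxygens.  Each entry: element -> (const, c_coef,
# d_coef, x_coef) so that count = const + c_coef*c + d_coef*d + x_coef*x.
_CLASS_RULES: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "FA": {"C": (0, 1, 0, 0), "H": (0, 2, -2, 0), "O": (2, 0, 0, 1)},
    "DG": {"C": (3, 1, 0, 0), "H": (4, 2, -2, 0), "O": (5, 0, 0, 1)},
    "TG": {"C": (3, 1, 0, 0), "H": (2, 2, -2, 0), "O": (6, 0, 0, 1)},
    "PC": {"C": (8, 1, 0, 0), "H": (16, 2, -2, 0), "N": (1, 0, 0, 0), "O": (8, 0, 0, 1), "P": (1, 0, 0, 0)},
    "PE": {"C": (5, 1, 0, 0), "H": (10, 2, -2, 0), "N": (1, 0, 0, 0), "O": (8, 0, 0, 1), "P": (1, 0, 0, 0)},
    # plasmanyl (O-alkyl) ether PE
    "PEe": {"C": (5, 1, 0, 0), "H": (12, 2, -2, 0), "N": (1, 0, 0, 0), "O": (7, 0, 0, 1), "P": (1, 0, 0, 0)},
    "PI": {"C": (9, 1, 0, 0), "H": (15, 2, -2, 0), "O": (13, 0, 0, 1), "P": (1, 0, 0, 0)},
    "PG": {"C": (6, 1, 0, 0), "H": (11, 2, -2, 0), "O": (10, 0, 0, 1), "P": (1, 0, 0, 0)},
    "PA": {"C": (3, 1, 0, 0), "H": (5, 2, -2, 0), "O": (8, 0, 0, 1), "P": (1, 0, 0, 0)},
    "PS": {"C": (6, 1, 0, 0), "H": (10, 2, -2, 0), "N": (1, 0, 0, 0), "O": (10, 0, 0, 1), "P": (1, 0, 0, 0)},
    "LPC": {"C": (8, 1, 0, 0), "H": (18, 2, -2, 0), "N": (1, 0, 0, 0), "O": (7, 0, 0, 1), "P": (1, 0, 0, 0)},
    "LPE": {"C": (5, 1, 0, 0), "H": (12, 2, -2, 0), "N": (1, 0, 0, 0), "O": (7, 0, 0, 1), "P": (1, 0, 0, 0)},
    "LPG": {"C": (6, 1, 0, 0), "H": (13, 2, -2, 0), "O": (9, 0, 0, 1), "P": (1, 0, 0, 0)},
    "LPS": {"C": (6, 1, 0, 0), "H": (12, 2, -2, 0), "N": (1, 0, 0, 0), "O": (9, 0, 0, 1), "P": (1, 0, 0, 0)},
    "SM": {"C": (5, 1, 0, 0), "H": (13, 2, -2, 0), "N": (2, 0, 0, 0), "O": (4, 0, 0, 1), "P": (1, 0, 0, 0)},
    "Cer": {"C": (0, 1, 0, 0), "H": (1, 2, -2, 0), "N": (1, 0, 0, 0), "O": (1, 0, 0, 1)},
}

LIPID_CLASSES = tuple(_CLASS_RULES)


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an element->count formula."""
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown element {exc}") from exc


_HILL = ("C", "H", "Cl", "K", "N", "Na", "O", "P", "S")


def formula_to_string(formula: dict[str, int]) -> str:
    parts = []
    for el in _HILL:
        n = formula.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def acyl_mass(carbons: int, double_bonds: int, extra_o: int = 0) -> float:
    """Monoisotopic mass of a free fatty acid C_c H_{2c-2d} O_{2+x}."""
    return formula_mass(
        {"C": carbons, "H": 2 * carbons - 2 * double_bonds, "O": 2 + extra_o}
    )


@dataclass(frozen=True)
class LipidRecord:
    """A lipid species: class-level shorthand plus optional acyl composition."""

    shorthand: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    oxygen_extra: int = 0
    chains: tuple[tuple[int, int, int], ...] = ()  # (carbons, double bonds, extra O)
    formula: dict[str, int] = field(default_factory=dict, compare=False)
    monoisotopic_mass: float = field(default=0.0, compare=False)

    def __post_init__(self):
        if self.lipid_class not in _CLASS_RULES:
            raise ValueError(f"unsupported lipid class {self.lipid_class!r}")
        if self.total_carbons <= 0:
            raise ValueError("total_carbons must be positive")
        if self.total_double_bonds < 0:
            raise ValueError("total_double_bonds must be non-negative")
        if not self.formula:
            object.__setattr__(self, "formula", _class_formula(
                self.lipid_class, self.total_carbons,
                self.total_double_bonds, self.oxygen_extra))
        if self.monoisotopic_mass == 0.0:
            object.__setattr__(
                self, "monoisotopic_mass", formula_mass(self.formula))

    @property
    def species_name(self) -> str:
        """Canonical class-level name, e.g. ``TG(52:2)`` or ``FA(18:2;O)``."""
        ox = ""
        if self.oxygen_extra == 1:
            ox = ";O"
        elif self.oxygen_extra > 1:
            ox = f";O{self.oxygen_extra}"
        return f"{self.lipid_class}({self.total_carbons}:{self.total_double_bonds}{ox})"


def _class_formula(cls: str, c: int, d: int, x: int) -> dict[str, int]:
    rule = _CLASS_RULES[cls]
    out: dict[str, int] = {}
    for el, (k0, kc, kd, kx) in rule.items():
        n = k0 + kc * c + kd * d + kx * x
        if n < 0:
            raise ValueError(
                f"{cls}({c}:{d}) yields a negative {el} count; "
                "check carbons/double bonds")
        if n:
            out[el] = n
    return out


_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;(O(\d*)|\d+))?$")
# class token: longest-first so 'LPE' wins over 'PE', 'PEe' over 'PE'
_CLASS_TOKENS = sorted(_CLASS_RULES, key=len, reverse=True)


def _parse_chain(token: str) -> tuple[int, int, int]:
    m = _CHAIN_RE.match(token)
    if not m:
        raise ValueError(f"malformed carbon:double-bond token {token!r}")
    c, d = int(m.group(1)), int(m.group(2))
    ox = 0
    if m.group(3):
        tag = m.group(3)
        if tag.startswith("O"):
            ox = int(tag[1:]) if len(tag) > 1 else 1
        else:  # bare ';2' as in 'SM 18:1;2/12:0'
            ox = int(tag)
    return c, d, ox


def parse_shorthand(text: str) -> LipidRecord:
    """Parse lipid shorthand into a :class:`LipidRecord`.

    Accepts species-level forms (``DG(32:1)``, ``FA (18:2;O)``) and
    chain-resolved forms (``TG 14:0_16:0_18:1``, ``PG 17:0/17:0``,
    ``PEe-16:1_22:6``); chain compositions are summed and kept.
    """
    raw = text.strip()
    cls = None
    for tok in _CLASS_TOKENS:
        if raw.startswith(tok) and (len(raw) == len(tok)
                                    or not raw[len(tok)].isalnum()):
            cls = tok
            rest = raw[len(tok):]
            break
    if cls is None:
        raise ValueError(f"unknown lipid class prefix in {text!r}")
    rest = rest.strip().strip("-").strip()
    if rest.startswith("(") and rest.endswith(")"):
        rest = rest[1:-1]
    rest = rest.replace(" ", "")
    if not rest:
        raise ValueError(f"missing carbon:double-bond part in {text!r}")
    tokens = re.split(r"[_/]", rest)
    chains = tuple(_parse_chain(t) for t in tokens)
    c = sum(ch[0] for ch in chains)
    d = sum(ch[1] for ch in chains)
    x = sum(ch[2] for ch in chains)
    return LipidRecord(
        shorthand=raw, lipid_class=cls, total_carbons=c,
        total_double_bonds=d, oxygen_extra=x,
        chains=chains if len(tokens) > 1 else (),
    )


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ionization adduct with electron-corrected mass shift."""

    name: str
    polarity: str  # 'positive' | 'negative'
    mass_shift: float
    charge: int

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError("charge sign inconsistent with polarity")


def _neg(name, shift):
    return AdductSpec(name, "negative", shift, -1)


def _pos(name, shift):
    return AdductSpec(name, "positive", shift, +1)


ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in (
        _neg("[M-H]-", -PROTON_MASS),
        _neg("[M+Cl]-", ATOMIC_MASS["Cl"] + ELECTRON_MASS),
        _neg("[M+HCOO]-", formula_mass({"C": 1, "H": 1, "O": 2}) + ELECTRON_MASS),
        _neg("[M+OAc]-", formula_mass({"C": 2, "H": 3, "O": 2}) + ELECTRON_MASS),
        _pos("[M+H]+", PROTON_MASS),
        _pos("[M+H-H2O]+", PROTON_MASS - WATER_MASS),
        _pos("[M+Na]+", ATOMIC_MASS["Na"] - ELECTRON_MASS),
        _pos("[M+NH4]+", formula_mass({"N": 1, "H": 4}) - ELECTRON_MASS),
        _pos("[M+K]+", ATOMIC_MASS["K"] - ELECTRON_MASS),
    )
}


def normalize_adduct_name(name: str) -> str:
    """Canonicalize adduct spelling, e.g. ``[M + H-H2O]+`` -> ``[M+H-H2O]+``."""
    compact = name.replace(" ", "")
    if compact not in ADDUCTS:
        raise ValueError(f"unparseable adduct token {name!r}")
    return compact


def adduct_mz(mass: float, adduct: AdductSpec | str) -> float:
    """Theoretical m/z of a neutral monoisotopic mass under a singly charged adduct."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if isinstance(adduct, str):
        adduct = ADDUCTS[normalize_adduct_name(adduct)]
    return mass + adduct.mass_shift


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical
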