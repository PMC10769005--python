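"""Theoretical lipid mass chemistry and ppm peak annotation.

Everything downstream of peak picking that assigns a name to an m/z value goes
through this module: elemental monoisotopic masses, adduct ion m/z, carbon-13
isotopologue spacing, glycerophospholipid / sphingomyelin composition rules
expressed as ``class(total_C:total_DB)``, and nearest-match annotation of a
picked-peak list against a species table at a ppm tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_MASS_DIFF",
    "parse_formula",
    "formula_to_string",
    "monoisotopic_mass",
    "adduct_mz",
    "isotope_mz",
    "lipid_class_formula",
    "LipidSpecies",
    "Annotation",
    "expand_species_table",
    "annotate_peaks",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
    "Na": 22.9897693,
    "K": 38.9637065,
    "Cl": 34.9688527,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858
#: Mass difference between carbon-13 and carbon-12 (Da).
C13_MASS_DIFF = 1.0033548

#: Supported ionization adducts -> (mass delta, charge sign).
_ADDUCTS: dict[str, tuple[float, int]] = {
    "+H": (PROTON_MASS, +1),
    "+Na": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
    "+K": (MONOISOTOPIC_MASS["K"] - ELECTRON_MASS, +1),
    "-H": (-PROTON_MASS, -1),
    "+Cl": (MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS, -1),
}

# Accept the unicode minus sign that appears in formatted adduct labels.
_ADDUCT_ALIASES = {"−H": "-H", "[M+H]+": "+H", "[M+Na]+": "+Na",
                   "[M+K]+": "+K", "[M-H]-": "-H", "[M−H]−": "-H",
                   "[M+Cl]-": "+Cl"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | dict[str, int]) -> dict[str, int]:
    """Parse a molecular formula string (e.g. ``"C26H48NO7P"``) to counts."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            counts[match.group(1)] = counts.get(match.group(1), 0) + int(
                match.group(2) or 1
            )
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    unknown = set(counts) - set(MONOISOTOPIC_MASS)
    if unknown:
        raise ValueError(f"unsupported element(s): {sorted(unknown)}")
    return counts


def formula_to_string(formula: dict[str, int]) -> str:
    """Hill-ish rendering: C, H first, then remaining elements alphabetically."""
    order = ["C", "H"] + sorted(set(formula) - {"C", "H"})
    out = []
    for el in order:
        n = formula.get(el, 0)
        if n == 0:
            continue
        out.append(el if n == 1 else f"{el}{n}")
    return "".join(out)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (lowest-isotope) mass in Da of a neutral formula."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def normalize_adduct(adduct: str) -> str:
    adduct = adduct.strip()
    return _ADDUCT_ALIASES.get(adduct, adduct)


def adduct_polarity(adduct: str) -> str:
    """``"positive"`` or ``"negative"`` for a supported adduct."""
    adduct = normalize_adduct(adduct)
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return "positive" if _ADDUCTS[adduct][1] > 0 else "negative"


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of a neutral monoisotopic mass.

    Electron mass is accounted for: e.g. [M+Na]+ adds the sodium *cation*
    mass (Na minus one electron), and [M+Cl]- adds the chloride anion mass.
    """
    adduct = normalize_adduct(adduct)
    if adduct not in _ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return neutral_mass + _ADDUCTS[adduct][0]


def isotope_mz(mz: float, k: int) -> float:
    """m/z of the k-th carbon-13 isotopologue of a singly charged ion."""
    if k < 0:
        raise ValueError("isotopologue index must be >= 0")
    return mz + k * C13_MASS_DIFF


# Composition rules: class -> (C offset, H offset, element counts beyond C/H).
# With n total acyl carbons and d double bonds the formula is
# C(n + dC) H(2n - 2d + dH) + the fixed heteroatom complement.
_CLASS_RULES: dict[str, tuple[int, int, dict[str, int]]] = {
    "PC": (8, 16, {"N": 1, "O": 8, "P": 1}),
    "LPC": (8, 18, {"N": 1, "O": 7, "P": 1}),
    "PE": (5, 10, {"N": 1, "O": 8, "P": 1}),
    "LPE": (5, 12, {"N": 1, "O": 7, "P": 1}),
    "PE-NMe2": (7, 14, {"N": 1, "O": 8, "P": 1}),
    "PA": (3, 5, {"O": 8, "P": 1}),
    "LPA": (3, 7, {"O": 7, "P": 1}),
    "cPA": (3, 5, {"O": 6, "P": 1}),
    "PI": (9, 15, {"O": 13, "P": 1}),
    "SM": (5, 13, {"N": 2, "O": 6, "P": 1}),
}


def lipid_class_formula(lipid_class: str, total_c: int, total_db: int) -> dict[str, int]:
    """Molecular formula of a lipid named by class and total C:DB.

    ``total_c``/``total_db`` count all acyl-chain carbons and double bonds
    (for SM, sphingoid base plus acyl, matching names like "SM(42:1)").
    """
    if lipid_class not in _CLASS_RULES:
        raise ValueError(
            f"unsupported lipid class {lipid_class!r}; "
            f"supported: {sorted(_CLASS_RULES)}"
        )
    if total_c < 0 or total_db < 0:
        raise ValueError("carbon and double-bond counts must be >= 0")
    dc, dh, hetero = _CLASS_RULES[lipid_class]
    n_h = 2 * total_c - 2 * total_db + dh
    if n_h <= 0:
        raise ValueError(
            f"{lipid_class}({total_c}:{total_db}) has non-positive hydrogen count"
        )
    formula = {"C": total_c + dc, "H": n_h}
    formula.update(hetero)
    return formula


_NAME_RE = re.compile(r"^\s*([A-Za-z0-9-]+)\s*\(\s*(\d+):(\d+)\s*\)\s*$")


def species_from_name(name: str, adduct: str, n13c: int = 0) -> "LipidSpecies":
    """Build a LipidSpecies from a ``Class(C:DB)`` name and an adduct."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse lipid name {name!r}; expected 'Class(C:DB)'")
    formula = lipid_class_formula(m.group(1), int(m.group(2)), int(m.group(3)))
    return LipidSpecies(name=name, formula=formula, adduct=adduct, n13c=n13c)


@dataclass(frozen=True)
class LipidSpecies:
    """A named lipid ion: formula + adduct + isotopologue index."""

    name: str
    formula: dict[str, int] = field(hash=False)
    adduct: str
    n13c: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "formula", parse_formula(self.formula))
        object.__setattr__(self, "adduct", normalize_adduct(self.adduct))
        if self.adduct not in _ADDUCTS:
            raise ValueError(f"unsupported adduct {self.adduct!r}")
        if self.n13c < 0:
            raise ValueError("n13c must be >= 0")
        if self.n13c > 0 and self.formula.get("C", 0) < self.n13c:
            raise ValueError("more 13C substitutions than carbon atoms")

    @property
    def polarity(self) -> str:
        return adduct_polarity(self.adduct)

    @property
    def theoretical_mz(self) -> float:
        mz = adduct_mz(monoisotopic_mass(self.formula), self.adduct)
        return isotope_mz(mz, self.n13c)

    @property
    def label(self) -> str:
        iso = f" (+{self.n13c} 13C)" if self.n13c else ""
        return f"{self.name} [M{self.adduct}]{'+' if self.polarity == 'positive' else '-'}{iso}"


@dataclass(frozen=True)
class Annotation:
    """A picked feature matched (or not) to a theoretical lipid ion."""

    feature_mz: float
    species: LipidSpecies | None
    error_ppm: float | None
    tol_ppm: float

    @property
    def matched(self) -> bool:
        return self.species is not None

    @property
    def label(self) -> str:
        return self.species.label if self.species else "unknown"


def expand_species_table(
    table: pd.DataFrame, max_isotopes: int | None = None
) -> list[LipidSpecies]:
    """Expand a species CSV table into LipidSpecies incl. isotopologues.

    Expected columns: ``name`` and ``adduct``, plus either ``formula`` or the
    pair implied by a parseable ``Class(C:DB)`` name; optional ``n_isotopes``
    (number of isotopologues to emit, monoisotopic included; default 1).
    """
    species: list[LipidSpecies] = []
    for _, row in table.iterrows():
        name = str(row["name"])
        adduct = str(row["adduct"])
        if "formula" in table.columns and isinstance(row["formula"], str) and row["formula"]:
            formula = parse_formula(row["formula"])
        else:
            m = _NAME_RE.match(name)
            if not m:
                raise ValueError(f"row {name!r} has no formula and unparseable name")
            formula = lipid_class_formula(m.group(1), int(m.group(2)), int(m.group(3)))
        n_iso = int(row.get("n_isotopes", 1) or 1)
        if max_isotopes is not None:
            n_iso = min(n_iso, max_isotopes)
        for k in range(max(n_iso, 1)):
            species.append(LipidSpecies(name=name, formula=formula, adduct=adduct, n13c=k))
    return species


def annotate_peaks(
    feature_mz: "list[float]",
    species: "list[LipidSpecies]",
    tol_ppm: float = 10.0,
) -> list[Annotation]:
    """Match each picked feature to the nearest theoretical m/z within tol_ppm.

    Unmatched features are carried through with ``species=None`` ("unknown").
    Ties (two candidates at identical |ppm error|) resolve to the lower m/z.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    candidates = sorted(species, key=lambda s: s.theoretical_mz)
    cand_mz = [s.theoretical_mz for s in candidates]
    out: list[Annotation] = []
    for fmz in feature_mz:
        best: LipidSpecies | None = None
        best_err: float | None = None
        for s, smz in zip(candidates, cand_mz):
            err = (fmz - smz) / smz * 1e6
            if abs(err) > tol_ppm:
                continue
            if best_err is None or abs(err) < abs(best_err) - 1e-12:
                best, best_err = s, err
        out.append(Annotation(feature_mz=fmz, species=best, error_ppm=best_err, tol_ppm=tol_ppm))
    return out
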