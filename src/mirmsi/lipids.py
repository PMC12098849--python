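"""Lipid shorthand parsing, formula assembly and theoretical m/z.

The registry covers the sulfoglycosphingolipid (sulfatide) subclasses that
accumulate in arylsulfatase-A-deficient kidney -- SM4, SM3, SM2a, SM1a/SM1b
and bis-sulfated SB1a -- together with the ganglioside GM3, ceramide
phosphates (CerP, CerPE) and the glycerophospholipids PI, LPI, PE and
plasmalogen PE-P that appear as markers in the imaging use cases.

Masses depend only on the total composition ``n:d;Ok`` (total chain carbons,
carbon-carbon double bonds, hydroxyl oxygens), never on the sphingoid/FA
split: MS1 is split-invariant, and split annotation is the job of on-tissue
MS2, not of this registry.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .constants import ISOTOPE_ABUNDANCE, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "MolecularFormula",
    "LipidShorthand",
    "AdductIon",
    "ADDUCTS",
    "ConfigSpace",
    "parse_shorthand",
    "build_formula",
    "monoisotopic_mass",
    "monoisotopic_mz",
    "isotope_pattern",
    "enumerate_configurations",
]


# ---------------------------------------------------------------------------
# molecular formulas
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition as an immutable element->count mapping."""

    counts: Mapping[str, int]

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in clean.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unsupported element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        pos = 0
        counts: Counter = Counter()
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            if not m.group(0):
                break
            counts[m.group(1)] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(dict(counts))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.update(other.counts)
        return MolecularFormula(dict(c))

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        c = Counter(self.counts)
        c.subtract(other.counts)
        if any(v < 0 for v in c.values()):
            raise ValueError(f"subtraction yields negative counts: {dict(c)}")
        return MolecularFormula(dict(c))

    def scaled(self, k: int) -> "MolecularFormula":
        return MolecularFormula({el: n * k for el, n in self.counts.items()})

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def hill(self) -> str:
        """Hill-order string (C, H, then alphabetical)."""
        order = ["C", "H"] + sorted(e for e in self.counts if e not in ("C", "H"))
        out = []
        for el in order:
            n = self.counts.get(el, 0)
            if n:
                out.append(el + (str(n) if n > 1 else ""))
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def monoisotopic_mass(formula: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da."""
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in formula.counts.items())


# common residues (condensation residues, i.e. already minus H2O where bound)
_F = MolecularFormula.from_string
HEX = _F("C6H10O5")           # hexose residue (galactose/glucose)
HEXNAC = _F("C8H13NO5")       # N-acetylhexosamine residue
NEUAC = _F("C11H17NO8")       # N-acetylneuraminic acid residue
SULFATE = _F("SO3")           # sulfation (esterified, -H2O already folded in)
PHOSPHATE = _F("HPO3")        # phosphate residue
PETN = _F("C2H6NO3P")         # phosphoethanolamine residue
H2O = _F("H2O")
GLYCEROL = _F("C3H8O3")
INOSITOL = _F("C6H12O6")
ETHANOLAMINE = _F("C2H7NO")


# ---------------------------------------------------------------------------
# shorthand
# ---------------------------------------------------------------------------

SPHINGO_CLASSES = {
    "Cer", "SM4", "SM3", "SM2a", "SM1a", "SM1b", "SB1a", "GM3", "CerP", "CerPE",
}
GLYCERO_CLASSES = {"PI", "LPI", "PE", "PE-P"}
KNOWN_CLASSES = SPHINGO_CLASSES | GLYCERO_CLASSES

#: head-group residues added onto the ceramide (or lyso) core per class
_SPHINGO_HEAD: dict[str, list[MolecularFormula]] = {
    "Cer": [],
    "SM4": [HEX, SULFATE],
    "SM3": [HEX, HEX, SULFATE],
    "SM2a": [HEX, HEX, HEXNAC, SULFATE],
    "SM1a": [HEX, HEX, HEX, HEXNAC, SULFATE],
    "SM1b": [HEX, HEX, HEX, HEXNAC, SULFATE],
    "SB1a": [HEX, HEX, HEX, HEXNAC, SULFATE, SULFATE],
    "GM3": [HEX, HEX, NEUAC],
    "CerP": [PHOSPHATE],
    "CerPE": [PETN],
}

_SHORTHAND_RE = re.compile(
    r"^\s*(?P<lyso>lyso-)?(?P<cls>[A-Za-z][A-Za-z0-9]*(?:-[A-Z])?)"
    r"[\s(]+(?P<chain>P-)?(?P<n>\d+):(?P<d>\d+)"
    r"(?:\s*;\s*O(?P<k>\d+))?\)?\s*$"
)


@dataclass(frozen=True)
class LipidShorthand:
    """Parsed lipid identity: class, total carbons, double bonds, ;O label."""

    lipid_class: str
    n_carbons: int
    double_bonds: int
    oxygens: int | None = None  # ;Ok label, sphingolipids only
    lyso: bool = False

    def __post_init__(self):
        if self.lipid_class not in KNOWN_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.n_carbons <= 0:
            raise ValueError("carbon count must be positive")
        if self.double_bonds < 0 or self.double_bonds > 6:
            raise ValueError(f"implausible double-bond count {self.double_bonds}")
        is_sphingo = self.lipid_class in SPHINGO_CLASSES
        if is_sphingo:
            if self.oxygens not in (2, 3, 4):
                raise ValueError(
                    f"sphingolipid {self.lipid_class} requires ;O2/;O3/;O4 label"
                )
        elif self.oxygens is not None:
            raise ValueError(f"{self.lipid_class} takes no ;O label")
        if self.lyso and self.lipid_class not in SPHINGO_CLASSES:
            raise ValueError("lyso flag applies to sphingolipid classes only")

    def format(self) -> str:
        head = ("lyso-" if self.lyso else "") + self.lipid_class
        body = f"{self.n_carbons}:{self.double_bonds}"
        if self.oxygens is not None:
            body += f";O{self.oxygens}"
        return f"{head} {body}"

    def __str__(self) -> str:
        return self.format()


def parse_shorthand(text: str) -> LipidShorthand:
    """Parse shorthand such as ``"SM4 38:2;O3"`` or ``"PI 38:4"``.

    Tolerates the spacing variants seen in print (``"PE(P-36:4"`` maps to
    class PE-P). Raises ``ValueError`` with the offending position for
    malformed input or unknown classes.
    """
    if not text or not text.strip():
        raise ValueError("empty shorthand")
    m = _SHORTHAND_RE.match(text)
    if m is None:
        raise ValueError(f"malformed lipid shorthand {text!r}")
    cls = m.group("cls")
    if m.group("chain"):  # "PE(P-36:4" / "PE P-36:4"
        cls = cls + "-P"
    lyso = bool(m.group("lyso"))
    if lyso and cls == "PI":
        cls, lyso = "LPI", False
    if cls not in KNOWN_CLASSES:
        raise ValueError(f"unknown lipid class {cls!r} in {text!r}")
    k = m.group("k")
    return LipidShorthand(
        lipid_class=cls,
        n_carbons=int(m.group("n")),
        double_bonds=int(m.group("d")),
        oxygens=int(k) if k is not None else None,
        lyso=lyso,
    )


# ---------------------------------------------------------------------------
# formula assembly
# ---------------------------------------------------------------------------

def _ceramide_core(n: int, d: int, k: int) -> MolecularFormula:
    """Ceramide core C_n H_{2n+1-2d} N O_{k+1}.

    ``d`` counts C=C bonds only; the amide carbonyl contributes one extra O
    and one degree of unsaturation on top of that.
    """
    h = 2 * n + 1 - 2 * d
    if h <= 0:
        raise ValueError(f"composition {n}:{d} leaves no hydrogens")
    return MolecularFormula({"C": n, "H": h, "N": 1, "O": k + 1})


def _lyso_core(n: int, d: int, k: int) -> MolecularFormula:
    """Sphingoid base (no N-acyl): C_n H_{2n+3-2d} N O_k."""
    h = 2 * n + 3 - 2 * d
    if h <= 0:
        raise ValueError(f"composition {n}:{d} leaves no hydrogens")
    return MolecularFormula({"C": n, "H": h, "N": 1, "O": k})


def _acyl_sum(n: int, d: int, n_chains: int) -> MolecularFormula:
    """Combined free fatty acids: C_n H_{2n-2d} O_{2*n_chains}."""
    h = 2 * n - 2 * d
    if h <= 0:
        raise ValueError(f"composition {n}:{d} leaves no hydrogens")
    return MolecularFormula({"C": n, "H": h, "O": 2 * n_chains})


def build_formula(sh: LipidShorthand) -> MolecularFormula:
    """Assemble the neutral molecular formula from building blocks."""
    cls, n, d = sh.lipid_class, sh.n_carbons, sh.double_bonds
    if cls in SPHINGO_CLASSES:
        core = (_lyso_core if sh.lyso else _ceramide_core)(n, d, sh.oxygens)
        out = core
        for residue in _SPHINGO_HEAD[cls]:
            out = out + residue
        return out
    # glycerophospholipids: glycerol + phosphate + head alcohol (-H2O for the
    # phosphodiester) + acyl chains (-H2O per ester)
    if cls == "PI":
        base = GLYCEROL + PHOSPHATE + INOSITOL - H2O
        return base + _acyl_sum(n, d, 2) - H2O.scaled(2)
    if cls == "LPI":
        base = GLYCEROL + PHOSPHATE + INOSITOL - H2O
        return base + _acyl_sum(n, d, 1) - H2O
    if cls == "PE":
        base = GLYCEROL + PHOSPHATE + ETHANOLAMINE - H2O
        return base + _acyl_sum(n, d, 2) - H2O.scaled(2)
    if cls == "PE-P":
        # plasmalogen: one ester replaced by an O-alk-1-enyl ether; the vinyl
        # C=C takes the place of the carbonyl, so the formula is the diacyl
        # species minus one oxygen (d counts the non-vinyl double bonds)
        base = GLYCEROL + PHOSPHATE + ETHANOLAMINE - H2O
        diacyl = base + _acyl_sum(n, d, 2) - H2O.scaled(2)
        return diacyl - _F("O")
    raise ValueError(f"no building blocks defined for class {cls!r}")


# ---------------------------------------------------------------------------
# adducts and m/z
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductIon:
    """Ion species: label, charge and neutral-mass delta (Da)."""

    label: str
    charge: int
    mass_delta: float

    def __post_init__(self):
        if abs(self.charge) < 1:
            raise ValueError("charge must be nonzero")


_H = MONOISOTOPIC_MASS["H"]
_NA = MONOISOTOPIC_MASS["Na"]

ADDUCTS: dict[str, AdductIon] = {
    "[M-H]-": AdductIon("[M-H]-", -1, -_H),
    "[M+Na-2H]-": AdductIon("[M+Na-2H]-", -1, _NA - 2 * _H),
    "[M-2H]2-": AdductIon("[M-2H]2-", -2, -2 * _H),
}


def monoisotopic_mz(
    formula: MolecularFormula, adduct: str | AdductIon = "[M-H]-"
) -> float:
    """Theoretical m/z of the given adduct ion.

    The electron ledger is kept explicitly: a 1- anion carries one extra
    electron, so e.g. [M-H]- computes as M - m(H) + m(e) = M - m(proton).
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"undefined adduct {adduct!r}") from None
    mass = monoisotopic_mass(formula) + adduct.mass_delta
    from .constants import ELECTRON_MASS

    n_extra_e = -adduct.charge  # negative ions gain electrons
    mass += n_extra_e * ELECTRON_MASS
    if mass <= 0:
        raise ValueError("non-physical ion mass")
    return mass / abs(adduct.charge)


# ---------------------------------------------------------------------------
# isotope envelope
# ---------------------------------------------------------------------------

def isotope_pattern(formula: MolecularFormula, n_peaks: int = 4) -> list[float]:
    """Aggregated isotopologue envelope, normalised to the monoisotopic peak.

    Abundances are convolved element-by-element on the nucleon-shift grid
    (the usual unit-mass approximation, adequate for intensity thresholds).
    Returns relative abundances of M, M+1, ... with M == 1.0.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    dist = [1.0]
    for el, count in formula.counts.items():
        base = [0.0] * (max(s for s, _ in ISOTOPE_ABUNDANCE[el]) + 1)
        for shift, ab in ISOTOPE_ABUNDANCE[el]:
            base[shift] = ab
        # exponentiation by squaring on the convolution monoid
        power = base
        k = count
        while k:
            if k & 1:
                dist = _convolve_trunc(dist, power, n_peaks)
            k >>= 1
            if k:
                power = _convolve_trunc(power, power, n_peaks)
    dist = dist + [0.0] * (n_peaks - len(dist))
    mono = dist[0]
    if mono <= 0:
        return [0.0] * n_peaks
    return [v / mono for v in dist[:n_peaks]]


def _convolve_trunc(a: list[float], b: list[float], n: int) -> list[float]:
    out = [0.0] * min(n, len(a) + len(b) - 1)
    for i, av in enumerate(a):
        if i >= n or av == 0.0:
            continue
        for j, bv in enumerate(b):
            if i + j >= n:
                break
            out[i + j] += av * bv
    return out


# ---------------------------------------------------------------------------
# configuration space
# ---------------------------------------------------------------------------

#: default lyso compositions (a convention: the paper's identities are not
#: public); chosen as the common sphingoid bases.
DEFAULT_LYSO: tuple[tuple[int, int, int], ...] = (
    (18, 1, 2), (18, 0, 2), (18, 1, 3), (18, 0, 3), (18, 0, 4), (20, 1, 2),
)

SULFATIDE_SUBCLASSES = ("SM4", "SM3", "SM2a", "SM1b", "SM1a", "SB1a")


@dataclass(frozen=True)
class ConfigSpace:
    """Theoretical sulfatide composition space.

    Defaults follow the detectability window used for ARSA-/- kidney:
    chain totals 32..46, double bonds 0..3 for the ;O2 and ;O3 series,
    0..1 for ;O4, plus six lyso species per subclass -- 156 compositions
    per subclass, 936 over the six subclasses.
    """

    subclasses: tuple[str, ...] = SULFATIDE_SUBCLASSES
    chain_range: tuple[int, int] = (32, 46)
    double_bonds: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: {2: (0, 1, 2, 3), 3: (0, 1, 2, 3), 4: (0, 1)}
    )
    lyso: tuple[tuple[int, int, int], ...] = DEFAULT_LYSO

    def __post_init__(self):
        lo, hi = self.chain_range
        if hi < lo:
            raise ValueError("empty chain range")
        for cls in self.subclasses:
            if cls not in SPHINGO_CLASSES:
                raise ValueError(f"not a sphingolipid subclass: {cls!r}")


def enumerate_configurations(
    space: ConfigSpace | None = None, adduct: str = "[M-H]-"
) -> pd.DataFrame:
    """Enumerate the full theoretical composition space.

    Returns a DataFrame with columns subclass, shorthand, n, d, k, lyso,
    formula, mz, adduct, ordered by (subclass order, lyso last, n, k, d).
    """
    space = space or ConfigSpace()
    lo, hi = space.chain_range
    rows = []
    for cls in space.subclasses:
        entries: list[LipidShorthand] = []
        for n, k in itertools.product(range(lo, hi + 1), sorted(space.double_bonds)):
            for d in space.double_bonds[k]:
                entries.append(LipidShorthand(cls, n, d, k))
        for n, d, k in space.lyso:
            entries.append(LipidShorthand(cls, n, d, k, lyso=True))
        for sh in entries:
            f = build_formula(sh)
            rows.append(
                {
                    "subclass": cls,
                    "shorthand": sh.format(),
                    "n": sh.n_carbons,
                    "d": sh.double_bonds,
                    "k": sh.oxygens,
                    "lyso": sh.lyso,
                    "formula": f.hill(),
                    "mz": monoisotopic_mz(f, adduct),
                    "adduct": adduct,
                }
            )
    df = pd.DataFrame(rows)
    if df["shorthand"].duplicated().any():
        raise AssertionError("configuration space contains duplicate shorthands")
    return df
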