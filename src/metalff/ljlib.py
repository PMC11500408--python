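"""Metal Lennard-Jones parameter libraries (merz / zhang / uff).

Parameters are lookup data keyed by (element, formal charge, source tag)
and shipped as a small table; the input topology's metal L-J parameters
are never used.  sigma is returned in nm and epsilon in kJ/mol, matching
the GROMACS atomtype convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .core import LibraryError, normalize_element

__all__ = ["LJLibraryEntry", "load_lj_library", "lookup_lj", "LJ_SOURCES"]

LJ_SOURCES = ("merz", "zhang", "uff")

_KCAL_TO_KJ = 4.184
_RMIN_TO_SIGMA = 2.0 / 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class LJLibraryEntry:
    symbol: str
    formal_charge: int
    source: str
    sigma: float    # nm
    epsilon: float  # kJ/mol

    def __post_init__(self):
        if self.sigma <= 0 or self.epsilon < 0:
            raise LibraryError(
                f"invalid L-J entry for {self.symbol}{self.formal_charge}: "
                "require sigma > 0 and epsilon >= 0")


def load_lj_library() -> dict[tuple[str, int, str], LJLibraryEntry]:
    text = (resources.files("metalff") / "data" / "lj_library.dat").read_text()
    table: dict[tuple[str, int, str], LJLibraryEntry] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sym, charge, source, rmin_half, eps_kcal = line.split()
        entry = LJLibraryEntry(
            symbol=normalize_element(sym),
            formal_charge=int(charge),
            source=source.lower(),
            sigma=float(rmin_half) * _RMIN_TO_SIGMA / 10.0,
            epsilon=float(eps_kcal) * _KCAL_TO_KJ,
        )
        table[(entry.symbol, entry.formal_charge, entry.source)] = entry
    return table


def lookup_lj(symbol: str, formal_charge: int, source: str) -> LJLibraryEntry:
    table = load_lj_library()
    key = (normalize_element(symbol), int(formal_charge),
           source.strip().lower())
    if key not in table:
        available = sorted({
            src for (sym, q, src) in table
            if sym == key[0] and q == key[1]
        })
        raise LibraryError(
            f"no L-J entry for {key[0]}{key[1]:+d} in source {source!r}; "
            f"available sources for this ion: {available or 'none'}")
    return table[key]
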