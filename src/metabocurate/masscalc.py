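"""Monoisotopic masses, positive-mode adduct m/z arithmetic, and ppm errors.

The element table is frozen to IUPAC/CODATA monoisotopic values so that
computed m/z values are reproducible bit-for-bit.  All adducts handled here
are singly charged positive ions, the acquisition mode of the study design
this package targets.  For a +1 ion the electron mass is subtracted: adding
"+H" as a neutral hydrogen atom and removing one electron is exactly adding
one proton.

Published "calculated m/z" columns produced by vendor software can deviate
from first-principles values by a few 1e-5; recomputing such a column is an
audit (see :func:`audit_annotations`), not a gate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Monoisotopic atomic masses (Da), frozen.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Se": 79.9165213,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class MassError(ValueError):
    pass


def _normalise(text: str) -> str:
    return text.replace("−", "-").replace("–", "-").strip()


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula (neutral atoms as written).

    A single trailing charge sign (e.g. permanent cations written "C5H14NO+")
    is ignored for the atom count; charge bookkeeping belongs to the adduct.
    """
    f = _normalise(formula)
    f = f.strip("[]")
    if f.endswith("+") or f.endswith("-"):
        f = f[:-1]
    if not f:
        raise MassError(f"empty formula: {formula!r}")
    mass = 0.0
    n_atoms = 0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(f):
        if m.start() != pos:
            raise MassError(f"cannot parse formula {formula!r} at {f[pos:]!r}")
        if not m.group(0):
            break
        pos = m.end()
        el, count = m.group(1), int(m.group(2) or 1)
        if el not in MONOISOTOPIC_MASS:
            raise MassError(f"unknown element {el!r} in formula {formula!r}")
        if count == 0:
            raise MassError(f"zero count for element {el!r} in formula {formula!r}")
        mass += MONOISOTOPIC_MASS[el] * count
        n_atoms += count
    if pos != len(f) or n_atoms == 0:
        raise MassError(f"cannot parse formula {formula!r}")
    return mass


@dataclass(frozen=True)
class AdductSpec:
    """Parsed positive-mode adduct: n*M plus/minus neutral fragments, charge +1.

    ``intrinsic_cation`` marks "[Cat]+"-style species (e.g. quaternary
    ammonium ions) whose written formula already carries the charge: their
    m/z is the formula mass minus one electron, with no charge carrier.
    """

    multimer: int = 1
    terms: tuple[tuple[str, int], ...] = field(default=())  # (fragment formula, +1/-1)
    intrinsic_cation: bool = False
    charge: int = 1


_ADDUCT_RE = re.compile(r"^\[(\d*)(M|Cat)((?:[+-][A-Za-z0-9]+)*)\]\+?$")


def parse_adduct(text: str) -> AdductSpec:
    """Parse the adduct grammar seen in positive-mode tables.

    Examples: [M+H]+, [2M+H]+, [M+Na]+, [M+K]+, [M+NH4]+, [M+H-H2O]+,
    [M+H-C5H8O4]+, [Cat]+, [Cat-C2H3N]+, [M+H-NH3]+, [M+H-H2]+.
    """
    s = _normalise(text).replace("^", "")
    m = _ADDUCT_RE.match(s)
    if not m:
        raise MassError(f"cannot parse adduct {text!r}")
    nmer = int(m.group(1) or 1)
    intrinsic = m.group(2) == "Cat"
    terms = []
    body = m.group(3)
    for t in re.finditer(r"([+-])([A-Za-z0-9]+)", body):
        terms.append((t.group(2), 1 if t.group(1) == "+" else -1))
    return AdductSpec(multimer=nmer, terms=tuple(terms), intrinsic_cation=intrinsic)


def adduct_mz(formula: str, adduct) -> float:
    """m/z of the given neutral formula observed as ``adduct`` (charge +1).

    m/z = (n*M + sum(signed fragment masses) - z*m_e) / z.  Fragments are
    neutral formulas, so "+H" plus the electron subtraction yields exactly a
    proton; "+Na"/"+K"/"+NH4" are handled identically.
    """
    spec = parse_adduct(adduct) if isinstance(adduct, str) else adduct
    total = spec.multimer * formula_mass(formula)
    for frag, sign in spec.terms:
        total += sign * formula_mass(frag)
    total -= spec.charge * ELECTRON_MASS
    return total / spec.charge


def error_ppm(observed: float, calculated: float) -> float:
    """Relative mass error in parts per million: 1e6*(observed-calculated)/calculated."""
    if calculated <= 0:
        raise MassError("calculated m/z must be > 0")
    return 1e6 * (observed - calculated) / calculated


def audit_annotations(frame: pd.DataFrame, tol_ppm: float = 0.1) -> dict:
    """Recompute ppm errors from printed observed/calculated m/z pairs.

    Returns per-row recomputed values, the fraction matching the printed
    1-decimal figure within ``tol_ppm``, and (where the formula and adduct
    parse) the first-principles calculated m/z for comparison.
    """
    rows = []
    for idx, row in frame.iterrows():
        obs, calc = float(row["observed_mz"]), float(row["calculated_mz"])
        recomputed = round(error_ppm(obs, calc), 1)
        printed = float(row["error_ppm"])
        entry = {
            "name": row.get("name", str(idx)),
            "printed_ppm": printed,
            "recomputed_ppm": recomputed,
            "ppm_match": abs(recomputed - printed) <= tol_ppm + 1e-12,
        }
        try:
            entry["theoretical_mz"] = adduct_mz(str(row["formula"]), str(row["adduct"]))
            entry["theoretical_minus_printed_calc"] = entry["theoretical_mz"] - calc
        except MassError as exc:
            entry["theoretical_mz"] = None
            entry["parse_error"] = str(exc)
        rows.append(entry)
    n_match = sum(r["ppm_match"] for r in rows)
    return {
        "n_rows": len(rows),
        "n_ppm_match": n_match,
        "ppm_match_fraction": n_match / len(rows) if rows else float("nan"),
        "mismatches": [r for r in rows if not r["ppm_match"]],
        "rows": rows,
    }
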