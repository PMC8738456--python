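"""Material descriptors and energy-dependent X-ray attenuation.

A material is an elemental mass-fraction composition plus a bulk density.
Materials can be declared four ways, mirroring how radiography lesson files
describe tissues and implants:

* an element symbol (``"H"``),
* a compound formula (``"H2O"``),
* a percent-mixture string of alternating symbols and integer mass percents
  (``"Ti90Al6V4"`` -- 90% titanium, 6% aluminium, 4% vanadium by mass),
* a Hounsfield unit, converted to composition and density through a
  piecewise-linear table of reference tissues (air, lung, adipose, water,
  soft tissue, trabecular bone, cortical bone).

Mass attenuation coefficients come from packaged per-element tables
(``data/attenuation``) spanning 1-200 keV, combined with the standard
mixture rule  (mu/rho)_mix(E) = sum_i w_i (mu/rho)_i(E)  and log-log linear
interpolation in energy.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Material",
    "AttenuationTable",
    "ATOMIC_WEIGHTS",
    "parse_material_descriptor",
    "hounsfield_to_material",
    "load_attenuation_table",
    "mass_attenuation",
    "linear_attenuation",
]

#: standard atomic weights, g/mol (CIAAW conventional values)
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "I": 126.904,
    "Ba": 137.327, "W": 183.84, "Pb": 207.2,
}

HU_MIN, HU_MAX = -1050.0, 3000.0


class MaterialParseError(ValueError):
    """Raised when a material descriptor string cannot be interpreted."""


@dataclass(frozen=True)
class Material:
    """Elemental composition + density of one tissue or object.

    Parameters
    ----------
    name:
        Human-readable label.
    mass_fractions:
        Mapping element symbol -> mass fraction; must sum to 1.
    density:
        Bulk density in g/cm^3.
    source_descriptor:
        The original descriptor string (or the HU value) the material was
        built from, kept for provenance in run manifests.
    """

    name: str
    mass_fractions: Mapping[str, float]
    density: float
    source_descriptor: str = ""

    def __post_init__(self):
        fractions = dict(self.mass_fractions)
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions of {self.name!r} sum to {total}, not 1")
        for sym, frac in fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction of {sym} out of [0,1]: {frac}")
            if sym not in ATOMIC_WEIGHTS:
                raise ValueError(f"unknown element symbol {sym!r}")
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")
        object.__setattr__(self, "mass_fractions", fractions)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, self.mass_fractions, density, self.source_descriptor)


class AttenuationTable:
    """Per-element mass attenuation coefficients, log-log interpolated.

    Maps element symbol -> (energies keV strictly increasing,
    mu/rho cm^2/g, all positive).  The packaged table spans 1-200 keV;
    queries outside an element's tabulated span raise rather than
    extrapolate.
    """

    def __init__(self, tables: Mapping[str, np.ndarray]):
        self._tables: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for sym, arr in tables.items():
            arr = np.asarray(arr, dtype=float)
            e, mu = arr[:, 0], arr[:, 1]
            if not (np.all(np.diff(e) > 0) and np.all(mu > 0) and np.all(e > 0)):
                raise ValueError(f"invalid attenuation table for {sym}")
            if e[0] > 1.0 or e[-1] < 200.0:
                raise ValueError(f"table for {sym} must span at least 1-200 keV")
            self._tables[sym] = (np.log(e), np.log(mu))

    @property
    def elements(self) -> list[str]:
        return sorted(self._tables)

    def span(self, symbol: str) -> tuple[float, float]:
        log_e, _ = self._tables[symbol]
        return float(np.exp(log_e[0])), float(np.exp(log_e[-1]))

    def element_mu(self, symbol: str, energy_kev) -> np.ndarray:
        """mu/rho of a pure element at ``energy_kev`` (scalar or array), cm^2/g."""
        if symbol not in self._tables:
            raise KeyError(f"no attenuation data for element {symbol!r}")
        log_e, log_mu = self._tables[symbol]
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = np.exp(log_e[0]), np.exp(log_e[-1])
        if np.any(e < lo - 1e-12) or np.any(e > hi + 1e-12):
            raise ValueError(
                f"energy outside tabulated span [{lo:g}, {hi:g}] keV for {symbol}"
            )
        return np.exp(np.interp(np.log(np.clip(e, lo, hi)), log_e, log_mu))


def load_attenuation_table() -> AttenuationTable:
    """Load the packaged per-element tables (text, one file per element)."""
    root = importlib.resources.files("virtradiol") / "data" / "attenuation"
    tables = {}
    for entry in root.iterdir():
        if entry.name.endswith(".txt"):
            rows = [
                [float(tok) for tok in line.split()]
                for line in entry.read_text().splitlines()
                if line.strip() and not line.lstrip().startswith("#")
            ]
            tables[entry.name[:-4]] = np.array(rows)
    return AttenuationTable(tables)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _tokenize(descriptor: str) -> list[tuple[str, int]]:
    pos, out = 0, []
    for m in _TOKEN.finditer(descriptor):
        if m.start() != pos:
            raise MaterialParseError(f"cannot parse {descriptor!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_WEIGHTS:
            raise MaterialParseError(f"unknown element symbol {sym!r} in {descriptor!r}")
        out.append((sym, int(num) if num else 0))
        pos = m.end()
    if pos != len(descriptor) or not out:
        raise MaterialParseError(f"cannot parse material descriptor {descriptor!r}")
    return out


def parse_material_descriptor(descriptor, density: float | None = None,
                              name: str | None = None) -> Material:
    """Build a :class:`Material` from any supported descriptor.

    Numeric descriptors are Hounsfield units.  String descriptors are
    classified by their counts: a bare symbol is an element; counts that sum
    to 100 are mass percents (``"Ti90Al6V4"``); anything else is a compound
    formula whose atom counts are converted to mass fractions through
    standard atomic weights (``"H2O"``).

    ``density`` overrides the default (1 g/cm^3 for element/compound/mixture
    descriptors, which carry no intrinsic density; the table density for HU).
    """
    if isinstance(descriptor, (int, float)) and not isinstance(descriptor, bool):
        mat = hounsfield_to_material(float(descriptor))
        if density is not None:
            mat = mat.with_density(density)
        if name is not None:
            mat = Material(name, mat.mass_fractions, mat.density, mat.source_descriptor)
        return mat

    text = str(descriptor).strip()
    try:
        return parse_material_descriptor(float(text), density=density, name=name)
    except (ValueError, TypeError):
        pass
    if not text:
        raise MaterialParseError("empty material descriptor")

    tokens = _tokenize(text)
    counts = [n for _, n in tokens]
    if len(tokens) == 1 and counts[0] == 0:  # bare element
        fractions = {tokens[0][0]: 1.0}
    elif all(n > 0 for n in counts) and sum(counts) == 100:  # mass-percent mixture
        fractions = {}
        for sym, n in tokens:
            fractions[sym] = fractions.get(sym, 0.0) + n / 100.0
    elif all(n > 0 for n in counts) and 90 <= sum(counts) <= 110 and len(tokens) > 1:
        raise MaterialParseError(
            f"mixture percents in {descriptor!r} sum to {sum(counts)}, not 100 "
            f"(off by {sum(counts) - 100:+d})"
        )
    else:  # compound formula: counts are atom multiplicities (implicit 1)
        masses: dict[str, float] = {}
        for sym, n in tokens:
            masses[sym] = masses.get(sym, 0.0) + max(n, 1) * ATOMIC_WEIGHTS[sym]
        total = sum(masses.values())
        fractions = {sym: m / total for sym, m in masses.items()}

    total = sum(fractions.values())
    fractions = {sym: f / total for sym, f in fractions.items()}
    return Material(
        name=name if name is not None else text,
        mass_fractions=fractions,
        density=1.0 if density is None else density,
        source_descriptor=text,
    )


def _load_anchor_rows() -> list[tuple[str, float, float, dict[str, float]]]:
    path = importlib.resources.files("virtradiol") / "data" / "hu_anchors.txt"
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        name, hu, rho = parts[0], float(parts[1]), float(parts[2])
        comp = {}
        for tok in parts[3:]:
            sym, frac = tok.split(":")
            comp[sym] = float(frac)
        total = sum(comp.values())
        comp = {s: f / total for s, f in comp.items()}
        rows.append((name, hu, rho, comp))
    rows.sort(key=lambda r: r[1])
    return rows


_ANCHORS: list[tuple[str, float, float, dict[str, float]]] | None = None


def _anchors():
    global _ANCHORS
    if _ANCHORS is None:
        _ANCHORS = _load_anchor_rows()
    return _ANCHORS


def hounsfield_to_material(hu: float) -> Material:
    """Convert a Hounsfield unit to a material.

    Density and elemental composition are interpolated linearly in HU
    between the packaged anchor tissues; HU below the lowest anchor (air)
    clamp to it.  Supported range is [-1050, 3000] HU.
    """
    if not HU_MIN <= hu <= HU_MAX:
        raise ValueError(f"HU {hu} outside supported range [{HU_MIN}, {HU_MAX}]")
    rows = _anchors()
    hus = [r[1] for r in rows]
    hu_c = min(max(hu, hus[0]), hus[-1])
    hi = next(i for i, h in enumerate(hus) if h >= hu_c)
    if hus[hi] == hu_c:
        name, _, rho, comp = rows[hi]
        frac = dict(comp)
    else:
        lo = hi - 1
        t = (hu_c - hus[lo]) / (hus[hi] - hus[lo])
        name = f"{rows[lo][0]}/{rows[hi][0]}"
        rho = (1 - t) * rows[lo][2] + t * rows[hi][2]
        frac = {}
        for sym in set(rows[lo][3]) | set(rows[hi][3]):
            frac[sym] = (1 - t) * rows[lo][3].get(sym, 0.0) + t * rows[hi][3].get(sym, 0.0)
    total = sum(frac.values())
    frac = {s: f / total for s, f in frac.items()}
    return Material(
        name=f"HU{hu:g} ({name})",
        mass_fractions=frac,
        density=rho,
        source_descriptor=f"HU={hu:g}",
    )


def mass_attenuation(material: Material, energy_kev, table: AttenuationTable) -> np.ndarray:
    """(mu/rho)(E) of a material by the elemental mixture rule, cm^2/g."""
    e = np.asarray(energy_kev, dtype=float)
    out = np.zeros_like(e, dtype=float)
    for sym, w in material.mass_fractions.items():
        if w > 0:
            out = out + w * table.element_mu(sym, e)
    return out if out.ndim else float(out)


def linear_attenuation(material: Material, energy_kev, table: AttenuationTable) -> np.ndarray:
    """mu(E) = (mu/rho)(E) * rho, cm^-1."""
    return mass_attenuation(material, energy_kev, table) * material.density
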