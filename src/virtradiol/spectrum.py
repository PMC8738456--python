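"""Incident X-ray beam spectra.

A spectrum is a tabulated list of (photon energy keV, photon count) bins --
the same representation a clinical spectrum file would provide.  The default
generator models a tungsten-anode tube as Kramers' bremsstrahlung continuum,

    N(E) dE  proportional to  (kVp - E) / E  for 0 < E < kVp,

hardened by an aluminium-equivalent filtration of thickness d:
each bin is multiplied by exp(-mu_Al(E) * d).  Counts are then rescaled to a
requested total photon budget.  Characteristic anode lines are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import AttenuationTable, Material, linear_attenuation

__all__ = [
    "Spectrum",
    "TubeSettings",
    "monochromatic",
    "tube_spectrum",
    "total_energy_fluence",
    "load_spectrum",
    "save_spectrum",
]

#: aluminium filtration material (bulk density of Al)
_ALUMINIUM = Material("Al", {"Al": 1.0}, density=2.699, source_descriptor="Al")


@dataclass(frozen=True)
class Spectrum:
    """Tabulated beam spectrum: strictly increasing energies, counts >= 0."""

    energies_kev: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies_kev, dtype=float)
        n = np.asarray(self.counts, dtype=float)
        if e.shape != n.shape or e.ndim != 1:
            raise ValueError("energies and counts must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if not np.all(e > 0):
            raise ValueError("energies must be positive")
        if np.any(n < 0) or not np.any(n > 0):
            raise ValueError("counts must be >= 0 with at least one positive bin")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "counts", n)

    def __len__(self):
        return len(self.energies_kev)

    @property
    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.energies_kev.tolist(), self.counts.tolist()))

    def mean_energy(self) -> float:
        """Count-weighted mean photon energy, keV."""
        return float(np.sum(self.energies_kev * self.counts) / np.sum(self.counts))

    def merged(self, other: "Spectrum") -> "Spectrum":
        """Union of bins; counts at coincident energies add."""
        e = np.concatenate([self.energies_kev, other.energies_kev])
        n = np.concatenate([self.counts, other.counts])
        uniq, inv = np.unique(e, return_inverse=True)
        acc = np.zeros_like(uniq)
        np.add.at(acc, inv, n)
        return Spectrum(uniq, acc)


@dataclass(frozen=True)
class TubeSettings:
    """Tube operating point: peak voltage, Al filtration, photon budget."""

    kvp: float
    filtration_mm_al: float = 2.5
    total_photons: float = 1e6

    def __post_init__(self):
        if not 0 < self.kvp <= 300:
            raise ValueError(f"kvp must be in (0, 300], got {self.kvp}")
        if self.filtration_mm_al < 0:
            raise ValueError("filtration must be >= 0")
        if not self.total_photons > 0:
            raise ValueError("total_photons must be positive")


def monochromatic(energy_kev: float, count: float) -> Spectrum:
    """Single-bin spectrum (useful for closed-form attenuation checks)."""
    if not energy_kev > 0 or not count > 0:
        raise ValueError("energy and count must be positive")
    return Spectrum(np.array([float(energy_kev)]), np.array([float(count)]))


def tube_spectrum(settings: TubeSettings, table: AttenuationTable) -> Spectrum:
    """Kramers continuum at 1-keV bins with aluminium filtration.

    Bins run from 1 keV up to kVp; the unfiltered shape is (kVp - E)/E,
    attenuated by exp(-mu_Al(E) * d) and rescaled so total counts equal
    ``settings.total_photons``.
    """
    e = np.arange(1.0, np.floor(settings.kvp) + 1.0)
    e = e[e < settings.kvp]  # Kramers support is E < kVp
    if e.size == 0:
        raise ValueError(f"kvp {settings.kvp} too low for 1-keV binning")
    n = (settings.kvp - e) / e
    if settings.filtration_mm_al > 0:
        mu_al = linear_attenuation(_ALUMINIUM, e, table)  # cm^-1
        n = n * np.exp(-mu_al * settings.filtration_mm_al / 10.0)
    n = n * (settings.total_photons / n.sum())
    return Spectrum(e, n)


def total_energy_fluence(spectrum: Spectrum) -> float:
    """Sum of N_i * E_i over all bins, keV * photons."""
    return float(np.sum(spectrum.energies_kev * spectrum.counts))


def load_spectrum(stream) -> Spectrum:
    """Read a two-column (energy_keV, photon_count) text spectrum.

    Rows may appear in any order and are sorted; duplicate energies are an
    error.  ``stream`` is a file-like object or a path.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        with open(stream) as fh:
            text = fh.read()
    energies, counts = [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        parts = body.split()
        if len(parts) != 2:
            raise ValueError(f"spectrum line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            e, n = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"spectrum line {lineno}: {exc}") from None
        energies.append(e)
        counts.append(n)
    if not energies:
        raise ValueError("spectrum file contains no data rows")
    order = np.argsort(energies)
    e = np.asarray(energies)[order]
    n = np.asarray(counts)[order]
    if np.any(np.diff(e) == 0):
        dup = e[:-1][np.diff(e) == 0][0]
        raise ValueError(f"duplicate energy {dup:g} keV in spectrum file")
    return Spectrum(e, n)


def save_spectrum(spectrum: Spectrum, stream) -> None:
    """Write the two-column text form read back by :func:`load_spectrum`."""
    lines = ["# energy_keV photon_count"]
    lines += [f"{e:.17g} {n:.17g}" for e, n in spectrum.bins]
    text = "\n".join(lines) + "\n"
    if hasattr(stream, "write"):
        stream.write(text)
    else:
        with open(stream, "w") as fh:
            fh.write(text)
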