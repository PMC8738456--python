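"""Regenerate the packaged per-element mass-attenuation tables.

The tables ship with the package (src/virtradiol/data/attenuation/) so builds
are self-contained.  They come from a compact analytic cross-section model
(Klein-Nishina incoherent scattering plus empirical photoelectric and coherent
terms calibrated against standard water benchmark values); see
docs/methods.md for the model and its accuracy envelope.  Run from the repo
root:  python scripts/make_attenuation_tables.py
"""

import pathlib

import numpy as np

SIGMA_T = 0.66524587  # Thomson cross section, barn
MEC2 = 510.99895  # electron rest energy, keV
NA = 6.02214076e23

# calibrated once against water (mu/rho with coherent) at 20-150 keV
K_PE = 100.0  # barn * keV^P_PE
P_PE = 3.876
Q_PE = 4.6  # photoelectric Z exponent
K_COH = 11.61  # barn * keV^2
Q_COH = 2.5

# symbol -> (Z, standard atomic weight)
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "Si": (14, 28.085), "P": (15, 30.974), "S": (16, 32.06),
    "Cl": (17, 35.45), "Ar": (18, 39.948), "K": (19, 39.098),
    "Ca": (20, 40.078), "Ti": (22, 47.867), "V": (23, 50.942),
    "Fe": (26, 55.845), "Cu": (29, 63.546), "I": (53, 126.904),
    "Ba": (56, 137.327), "Pb": (82, 207.2),
}


def klein_nishina(energy_kev):
    """Total Klein-Nishina cross section per electron, barn."""
    k = np.asarray(energy_kev, dtype=float) / MEC2
    t1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
    t2 = np.log(1 + 2 * k) / (2 * k)
    t3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return 0.75 * SIGMA_T * (t1 + t2 + t3)


def mu_over_rho(symbol, energy_kev):
    """Mass attenuation coefficient (photoelectric + incoherent + coherent), cm^2/g."""
    z, a = ELEMENTS[symbol]
    e = np.asarray(energy_kev, dtype=float)
    sigma = (
        z * klein_nishina(e)
        + K_PE * z**Q_PE / e**P_PE
        + K_COH * z**Q_COH / e**2
    )
    return NA / a * sigma * 1e-24


def main():
    out_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "virtradiol" / "data" / "attenuation"
    out_dir.mkdir(parents=True, exist_ok=True)
    energies = np.geomspace(1.0, 200.0, 60)
    energies[0], energies[-1] = 1.0, 200.0
    for symbol in ELEMENTS:
        mu = mu_over_rho(symbol, energies)
        lines = ["# energy_keV  mu_over_rho_cm2_g"]
        lines += [f"{e:.6g} {m:.6g}" for e, m in zip(energies, mu)]
        (out_dir / f"{symbol}.txt").write_text("\n".join(lines) + "\n")
    print(f"wrote {len(ELEMENTS)} element tables to {out_dir}")


if __name__ == "__main__":
    main()
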