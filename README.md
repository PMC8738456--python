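# virtradiol

A deterministic virtual-radiography simulator for teaching projectional
radiography.  It does two things, as a library and a small CLI:

1. **Pose a virtual patient.**  Given closed triangle meshes of tissues and
   a labelled skeleton, a fully automatic five-stage pipeline (rigging →
   BCC volumetrisation → harmonic skinning weights from the steady-state
   diffusion equation → barycentric tissue embedding → linear-blend
   skinning) deforms *all* tissues — skin, bones, organs — to any saved
   joint pose.
2. **Synthesise the radiograph.**  A point source, a cassette with SID/SOD
   and a rectangular collimator, and a tube spectrum (Kramers continuum
   with aluminium filtration, or a tabulated file) drive a per-pixel
   evaluation of the polychromatic Beer–Lambert law

   I(p) = Σᵢ N(Eᵢ)·Eᵢ·exp(−Σₘ μₘ(Eᵢ)·Lₘ(p)),

   where path lengths Lₘ come from an L-buffer ray cast (signed
   intersection-distance accumulation over each watertight mesh) and μₘ
   from elemental mixture rules over packaged attenuation tables.
   Materials are declared as element symbols, compound formulas
   (`"H2O"`), mass-percent mixtures (`"Ti90Al6V4"`), or Hounsfield units
   (converted through reference-tissue anchors).  Tissues can be hidden,
   re-assigned an HU on the fly, or nested (an inner mesh displaces its
   parent's material — how trabecular bone lives inside a cortical shell).
   Radiographic display filters (log, gamma, brightness/contrast,
   negative, L/R side marker) and seeded Poisson noise (the mAs surrogate)
   complete the picture.

It is aimed at radiography educators and simulation developers who need
reproducible, scriptable exposures rather than a GUI: identical scene +
seed gives byte-identical raw images, and every run writes a checksummed
manifest.  No patient data ships with the package — all test anatomy is
generated programmatically (slab, nested spheres/cylinders, and a
two-bone limb with an elbow joint).

## Worked example

Library use — materials and spectra:

```python
>>> from virtradiol import *
>>> table = load_attenuation_table()
>>> ti = parse_material_descriptor("Ti90Al6V4", density=4.43)
>>> round(float(mass_attenuation(ti, 60.0, table)), 4)
0.4726
>>> spec = tube_spectrum(TubeSettings(kvp=70, filtration_mm_al=2.5), table)
>>> round(spec.mean_energy(), 2)
37.0
```

0.4726 cm²/g is the mass attenuation of the titanium implant alloy (90%
Ti, 6% Al, 4% V by mass) at 60 keV under the packaged cross-section model;
37.0 keV is the mean photon energy of a 70 kVp beam after 2.5 mm Al
filtration — hardened well above the unfiltered Kramers mean, which is why
the skin dose drops.

A complete lesson from the shell — generate the two-bone limb phantom with
its skeleton and pose files, then simulate the 90°-flexed elbow at 70 kVp
with a collimated field, gamma 0.8 and an L marker:

```sh
$ virtradiol phantom two_bone_limb lesson --kvp 70
wrote lesson/scene.yaml
$ virtradiol run lesson/scene_flexed.yaml
wrote lesson/run_manifest_flexed.json
  radiograph_flexed.vxr
  radiograph_flexed.png
```

`radiograph_flexed.vxr` is the raw 256×256 energy-fluence image (here
0 keV·photons inside the collimator shadow up to 3.70×10⁷ keV·photons in
the open field, i.e. the full fluence of the 10⁶-photon beam);
`radiograph_flexed.png` is the display rendering, negative convention
applied, with the flexed lower limb projected over the elbow — the bone
overlap students must learn to avoid.  The logged warning about clamped
path lengths is the documented containment clamp where linear-blend
skinning folds the bone slightly through the skin at 90° flexion.  Editing
`scene_flexed.yaml` (tissue visibility, HU overrides, kVp, collimation,
noise `photons_per_unit`, filters) and re-running is the intended teaching
loop; `virtradiol filter` re-develops a raw image without re-simulating.

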