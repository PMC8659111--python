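# nitroxkit

Tools for connecting the structure of nitroxide radicals — the stable
N–O• free radicals used as EPR spin probes and spin labels for proteins
and materials — to their spectroscopic observables. The package is the
*post-processing* half of a composite computational protocol: it consumes
numbers that electronic-structure programs produce (relaxed-scan
potentials, harmonic/anharmonic frequencies, hyperfine couplings, spin
densities) and implements the analysis layer on top of them. No quantum
chemistry is run.

## What it computes

**Geometry.** From Cartesian coordinates and explicit atom indices:
bond lengths and valence angles of the C1C2NO core, the improper
C1–C2–N–O dihedral, the out-of-plane angle θ between the N–O bond and the
C1–N–C2 plane (the pyramidalization coordinate that controls the nitrogen
hyperfine coupling), and Cremer–Pople ring-puckering coordinates
(Q, q_m, φ_m) for 5- and 6-membered rings.

**Inversion large-amplitude motion.** The nitroxide nitrogen inverts
between two mirror-image pyramidal minima over a low planar barrier
(a few hundred cm⁻¹), so a harmonic picture fails. `nitroxkit` represents
the 1D potential V(θ) as a tabulated scan or as the quartic double well
V(θ) = B((θ/θ_eq)² − 1)², rescales it to a higher-level barrier, solves
the vibrational Schrödinger equation with a Colbert–Miller sinc-DVR
(discrete variable representation), Boltzmann-populates the levels at
temperature T, and averages any property P(θ):

    ⟨P⟩_T = Σᵢ pᵢ Σₖ |ψᵢ(θₖ)|² P(θₖ),   pᵢ ∝ exp(−(Eᵢ−E₀)/k_B T).

**Hyperfine coupling.** The ¹⁴N isotropic coupling follows
a_N(θ) = a·cos²θ + b. Fitted (a, b) pairs for the dimethylnitroxide
template at the CCSD(T), B2PLYP and B3LYP levels ship as constants; their
CC−B2 difference gives the transferable correction
Δθ = 7.13·cos²θ − 6.18 MHz, applied at the target molecule's θ. The
composite estimate is

    a_N = a_N(B2, eq) + Δvib + (Δθ or ΔTM) [+ Δsolv],

plus spin-density→MHz/Gauss conversion (×323.13 / ×115.3).

**NO-stretch frequencies.** The hybrid scheme ν_H = ω_B2 + (ν_B3 − ω_B3)
combines a double-hybrid harmonic frequency with a cheaper anharmonic
shift; alternatives are empirical scaling (0.976 / 0.980) and a constant
−30 cm⁻¹ shift. Error statistics against experiment are reported overall
and per structural family, and reduced-dimensionality mode selection
retains modes with |K_iij|/ω_i above a threshold (default 0.03).

**Synthetic data.** Generators build scans, a_N(θ) samples, coupling sets
and geometries whose ground truth is known exactly by construction, plus
packaged transcriptions of the two reference tables (frequencies and the
hyperfine ledger) for molecules a–p.

## Worked example

Composite a_N for the large aromatic radical labelled `p`
(θ = 1.80°, B2 equilibrium value 20.27 MHz, vibrational correction
4.40 MHz, benzene solvent shift 0.5 MHz):

```
$ nitroxkit an-correct --theta 1.80 --base 20.27 --dvib 4.40 --dsolv 0.5
{
  "result": {
    "aN_base": 20.27,
    "composite_aN": 26.113,
    "delta_solv": 0.5,
    "delta_theta": 0.942965,
    "delta_vib": 4.4,
    ...
  }
}
```

The cos² correction at θ = 1.80° is 0.94 MHz; the assembled coupling,
26.1 MHz at printed precision, is within 0.2 MHz of the experimental
25.9 MHz. The same library calls are available in Python:

```python
from nitroxkit import hcc, synthdata, vibfreq

rec = {r.molecule: r for r in synthdata.load_fixture("table6")}["p"]
hcc.composite_an(rec, scheme="theta")        # 25.61 MHz (no solvent term)
hcc.delta_theta(12.26)                       # 0.6287 MHz for radical b

freq = {r.molecule: r for r in synthdata.load_fixture("table4")}["b"]
vibfreq.hybrid_frequency(freq)               # 1408.0 cm^-1
```

Solving the inversion motion on a synthetic scan (barrier raised to the
coupled-cluster 404 cm⁻¹, inertia 26.2 amu·Å²) and averaging the B2 cos²
coupling at 300 K:

```
$ nitroxkit synth scan --barrier 334 --theta-eq 25.7 --npts 41 --out scan.csv
$ nitroxkit lam-solve --scan scan.csv --inertia 26.2 --temp 300 \
      --correct-barrier 404 --property cos2:a=-78.78,b=108.53
```

prints the level ladder (a near-degenerate tunneling doublet at
51.83/51.84 cm⁻¹, then 149.9/150.7, …), eleven levels populated above
0.5%, and a vibrational correction of −2.08 MHz: thermal delocalization
over the inversion path samples smaller |θ|, where the cos² curve sits
lower, shrinking a_N by about 2 MHz relative to the bottom of the well.

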