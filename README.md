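# membranekit

Analysis toolkit for membrane lipid-packing studies: how does a
transmembrane sensor protein read the lipid composition of its bilayer?
The package implements the quantitative pipeline used to compare bilayer
compositions by their *local lipid-packing density* and to relate that to
the behavior of a dimeric transmembrane-helix (TMH) sensor whose bulky
tryptophan side chain probes a specific depth of the membrane — an
alternative to the classical homeoviscous (bulk-fluidity) picture.

It is aimed at membrane biophysicists and structural bioinformaticians
who have bilayer trajectories (from all-atom or coarse-grained MD) and/or
membrane-probe spectroscopy data and want reproducible, scriptable
reductions.

## What it computes

* **Local number-density maps** — lipid-atom counts per 1 Å³ voxel,
  frame-averaged; depth × lateral projections and depth profiles; signed
  difference maps between compositions; a band statistic over
  3 Å ≤ |z| ≤ 10 Å, the depth probed by the sensory tryptophan.
* **Bilayer descriptors** — area per lipid, membrane thickness, and acyl
  chain order parameters S = ⟨(3cos²θ − 1)/2⟩ per chain segment.
* **TMH-dimer rotamer analysis** — sensor-residue azimuths in the dimer,
  three-state classification (facing-facing / mixed / away-away), and
  state populations with bootstrap confidence intervals.
* **Spectroscopy reductions** — C-Laurdan generalized polarization
  GP = (I₄₀₀₋₄₆₀ − I₄₇₀₋₅₃₀)/(I₄₀₀₋₄₆₀ + I₄₇₀₋₅₃₀); ratiometric FRET
  E_rel = I_A/(I_D + I_A) at 525/614 nm with acceptor normalization;
  FCS autocorrelation fitting with the 2D + triplet model
  G(τ) = (1 + T/(1−T)e^(−τ/τ_T))·(1/N)·(1+τ/τ_D)⁻¹ and D = w²/(4τ_D);
  the cwEPR proximity index I_Lf/I_Mf.
* **Liposome acyl-chain molarity** — from vesicle geometry and lipid
  composition, the molar concentration of unsaturated acyl chains inside
  the bilayer volume.
* **Synthetic-data generators** — seeded toy bilayers, dimer rotamer
  mixtures, emission spectra, FCS curves and cwEPR spectra with known
  ground truth, so the full pipeline is testable without external data.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

The back-of-envelope liposome calculation, from the command line:

```
$ membranekit liposome --composition "dopc=0.5,popc=0.5"
{
 "lipid_count": 371500.5811161936,
 "membrane_volume_l": 4.828167141644984e-19,
 "unsaturated_chain_molarity_M": 1.916538544513957
}
```

A 200 nm vesicle with a 4 nm bilayer at 0.65 nm² per lipid contains about
3.7×10⁵ lipids in ≈4.8×10⁻¹⁹ L of membrane; a 50:50 DOPC:POPC composition
(1.5 unsaturated chains per lipid) therefore holds ≈1.9 M unsaturated
acyl chains inside the bilayer volume.  Pure POPC (`popc=1.0`) gives
≈1.3 M — the concentration window across which the saturation sensor
switches between OFF and ON.

The same from Python, plus a density-map comparison of synthetic
compositions:

```python
from membranekit import synthetic, density

sat = synthetic.BilayerGenSpec(lipids_per_leaflet=36,
                               fraction_kinked_chains=0.0,
                               thermal_noise_sd=0.4, seed=1)
cis = synthetic.BilayerGenSpec(lipids_per_leaflet=36,
                               fraction_kinked_chains=1.0,
                               thermal_noise_sd=0.4, seed=1)
maps = {}
for name, spec in {"sat": sat, "cis": cis}.items():
    traj = density.center_and_wrap(synthetic.generate_bilayer(spec, n_frames=3))
    maps[name] = density.voxel_density(traj)

diff = density.difference_map(maps["sat"], maps["cis"])
print(density.band_statistic(diff).mean)   # 0.0100 atoms/Å³ (positive:
                                           # straighter chains pack the
                                           # 3-10 Å band more densely)
```

The full synthetic demonstration pipeline (`membranekit run --seed 1`)
compares saturated-, cis- and PE-analog bilayers and reduces matching
spectroscopy fixtures; its report orders the band densities
saturated (0.0248) > PE-analog (0.0178) > cis (0.0148) atoms/Å³, with a
consistently higher GP (+0.41 vs −0.41), E_rel (0.64 vs 0.25) and EPR
proximity index (0.39 vs 0.24) for the tighter-packed composition, and
recovers a 0.50/0.30/0.20 rotamer mixture as 0.501/0.296/0.203.

Stages run on user data through the other subcommands
(`synth density props rotamer gp fret fcs epr liposome run`), e.g.
`membranekit density --traj bilayer.pdb --topology topology.csv`.

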