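# Reference material set for the nifedipine passive-loading case study:
# tabulated Hansen parameters (MPa^1/2) for the drug, the two food-grade
# loading solvents, and four commercial FDM filaments, plus the drug's
# saturation solubilities (mg/cm^3) in each solvent and nominal filament
# density (g/cm^3).
materials:
  - name: NFD
    role: drug
    delta_d: 16.6
    delta_p: 2.4
    delta_h: 7.4
    saturation_solubility:
      ethanol: 31.6
      ethyl_acetate: 71.2
  - name: ethanol
    role: solvent
    delta_d: 15.8
    delta_p: 8.8
    delta_h: 19.4
  - name: ethyl_acetate
    role: solvent
    delta_d: 15.8
    delta_p: 5.3
    delta_h: 7.2
  - name: PVA
    role: filament
    delta_d: 15.0
    delta_p: 17.2
    delta_h: 17.8
    density: 1.25
  - name: HS
    role: filament
    delta_d: 15.1
    delta_p: 16.9
    delta_h: 18.1
    density: 1.25
  - name: PLA
    role: filament
    delta_d: 18.6
    delta_p: 9.9
    delta_h: 6.0
    density: 1.25
  - name: TPU
    role: filament
    delta_d: 18.1
    delta_p: 9.3
    delta_h: 4.5
    density: 1.25
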