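# tdcsflow

Transcranial direct current stimulation (tDCS) drives milliamp-scale
currents through the brain. Where that current crosses the high-resistance
wall of a capillary, the field is amplified hundreds-fold inside the
blood–brain-barrier (BBB) tight junctions — nanometre-wide, negatively
charged slits — and drives water through them by electroosmosis. `tdcsflow`
is a desk-scale implementation of the multi-scale pipeline that turns a
brain current-density map into a map of the interstitial fluid exchange
this mechanism produces, for researchers in neurostimulation dosimetry and
brain-clearance modelling.

## The model

The chain is linear end to end. Per capillary-wall element with normal
current density J (A/m²):

1. **TJ electroosmosis.** In a slit of half-width h = 1 nm with zeta
   potential ζ = −21.1 mV and Debye length κ⁻¹ = 0.905 nm, the overlapping
   double-layer potential ψ(y) is the two-wall Gouy–Chapman superposition,
   and u(y) = −(εζE/μ)(1 − ψ(y)/ζ). Averaged over the channel:
   v ≈ 3.8×10⁻⁹ · E_TJ (m/s). Times the TJ opening (2 nm) and junction
   length per wall area (150 000 m/m²): QA ≈ 1.15×10⁻¹² · E_TJ (m³ s⁻¹ m⁻²).
2. **Field amplification.** E_TJ = C·J, with C = 2.73×10⁶ V·m/A at
   1000 Ω·cm² TEER (3.83×10⁶ at 5000), from the BBB ultrastructure model; a
   reduced-order series–parallel conductance model of the same
   ultrastructure is included for sensitivity work.
3. **Capillary network.** A seeded synthetic network matching in vivo
   morphometrics (557 mm/mm³, 8–10 μm diameters) inside a
   0.15×0.16×0.43 mm voxel; ∇·(σ∇V) = 0 is solved on a finite-difference
   grid with embedded lumen conductors and membrane conductance 1/TEER,
   under closed (locally balanced) or open (partially collected by larger
   vessels) boundary conditions, giving the signed wall current densities.
4. **Aggregation.** Net exchange = Σ|QA|·area / voxel volume (min⁻¹), and
   k = exchange / brain current density (m²·A⁻¹·min⁻¹) converts any brain
   current-density map into an exchange map: exchange = k · J_brain.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Membrane conductivities from TEER and the electroosmotic coefficients:

```
$ tdcsflow teer-convert
teer_ohm_cm2    sigma_wall_S_per_m      sigma_tj_S_per_m
1000    1e-05   0.000366667
5000    2e-06   7.33333e-05

$ tdcsflow eo-coeffs
avg_velocity_coeff_m_s_per_V_m  max_velocity_coeff_m_s_per_V_m  flux_coeff_m3_s_m2_per_V_m
3.84711e-09     6.6122e-09      1.15413e-12
```

The wall of a 1000 Ω·cm² vessel conducts 10⁻⁵ S/m; attributing all of that
resistance to the tight junction gives σ_TJ = 3.67×10⁻⁴ S/m. The average
electroosmotic velocity in the TJ is 3.85×10⁻⁹ m/s per V/m of TJ field,
and each m² of vessel wall passes 1.15×10⁻¹² m³/s of water per V/m.

Full voxel coupling (closed network, 1000 Ω·cm² TEER, 1 mA dose, i.e. an
inward 0.082 A/m² on the voxel):

```
$ tdcsflow couple --teer 1000 --boundary closed --grid 32 36 96
{
 "peak_j_norm_A_per_m2": 0.0003229566059388317,
 "peak_qa_m3_s_m2": 1.0175664266860713e-09,
 "net_exchange_per_min": 0.0002904639443832789,
 "scaling_factor_m2_per_A_min": 0.003542243224186328
}
```

The peak wall current density (3.2×10⁻⁴ A/m²) is amplified to a TJ field of
~880 V/m, producing a peak water flux of ~1.0×10⁻⁹ m³ s⁻¹ per m² of wall;
summed over the network, the voxel exchanges ~2.9×10⁻⁴ of its volume per
minute, i.e. k ≈ 3.5×10⁻³ m²/(A·min). Multiplying any brain current-density
map by k (`tdcsflow brain-map --scaling-factor 3.5e-3 ...`) gives the
voxelwise exchange map; outputs scale exactly with the applied current.

The library API mirrors the CLI (`tdcsflow.fit_coefficients`,
`tdcsflow.solve_voxel_current`, `tdcsflow.couple_solution`,
`tdcsflow.run_pipeline`, ...); `tdcsflow run --out DIR` executes all stages
and writes tables, maps and a provenance record of every constant used.

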