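# Packaged configuration for the calcium-modulated TRAIL apoptosis model.
# The reaction network itself lives in the two synthetic-model TSV tables
# (a reconstruction in the EARM lineage, calibrated in-package; see docs).
model:
  species_table: apoptosis_model_synthetic.species.tsv
  reactions_table: apoptosis_model_synthetic.reactions.tsv
  time_unit: second
  amount_unit: molecules/cell

trail:
  species: L
  reference_dose_ng_per_ml: 50.0
  reference_amount: 3000.0       # ligand molecules/cell at 50 ng/mL; other doses scale linearly

calcium:
  species: Ca
  unit: uM                       # calcium state is kept in µM; rate constants absorb the conversion
  clamped: true                  # calcium enters reactions only catalytically, so it stays constant

events:
  apoptosis:
    species: cPARP
    threshold: 5.0e+5            # molecules/cell
  momp:
    cytosolic_smac_species: [cSmac, XIAP_cSmac]
    pool_species: [mSmac, AMito_mSmac, ASmac, cSmac, XIAP_cSmac]
    fraction: 0.5                # MOMP called when cytosolic Smac reaches this fraction of the pool
  peak_smac:
    species: cSmac               # free cytosolic Smac (bound Smac excluded)

heterogeneity:
  bcl2:
    species: Bcl2c
    mean: 1.98e+6
    sd: 9.91e+5
  xiap:
    species: XIAP
    mean: 1.01e+5
    sd: 9.91e+4
  truncation: redraw             # redraw | clamp
  n_cells: 1000

solver:
  method: LSODA
  rtol: 1.0e-6
  atol: 1.0e-2
  horizon_h: 24
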