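# Default whole-body physiology for a 177Lu-labelled PSMA-targeting ligand.
#
# Representative adult population values (organ volumes, plasma flows,
# vascular/interstitial fractions) assembled from standard PBPK physiology,
# with PSMA-617-like binding kinetics and the 177Lu half-life (6.647 d).
# Units are explicit in every key; loaders convert everything to the
# internal convention (L, min, nmol).
units:
  volume: L
  flow: L/min
  time: min
  amount: nmol
  concentration: nmol/L

global:
  lambda_phys_per_min: 7.2412e-05      # ln(2) / (6.647 d * 1440 min/d)
  k_on_L_per_nmol_min: 0.04            # receptor association
  K_D_nmol_per_L: 0.5                  # receptor dissociation constant
  lambda_int_per_min: 0.001            # internalization of bound complex
  lambda_rel_per_min: 0.0002           # intracellular release/degradation
  gfr_L_per_min: 0.11                  # glomerular filtration of free ligand
  albumin_conc_nmol_per_L: 1.0e4       # effective plasma albumin binding-site pool
  k_on_alb_L_per_nmol_min: 1.0e-3      # albumin association (K_D^alb varied via k_off)
  K_D_alb_nmol_per_L: .inf             # .inf = albumin binding disabled
  tissue_density_kg_per_L: 1.04
  mean_energy_per_decay_J: 2.3694e-14  # 177Lu mean energy per decay (~147.9 keV)

blood:
  arterial_volume_L: 0.5
  venous_volume_L: 1.1

# Per-organ: total volume, plasma flow, vascular/interstitial volume fractions,
# PSMA receptor density (nmol per L of organ; 0 = non-expressing) and the
# vascular<->interstitial permeability-surface product for the free ligand.
organs:
  - {name: adipose,         volume_L: 10.0,  plasma_flow_L_per_min: 0.13,  vascular_fraction: 0.02, interstitial_fraction: 0.14, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.013}
  - {name: bone,            volume_L: 4.5,   plasma_flow_L_per_min: 0.10,  vascular_fraction: 0.04, interstitial_fraction: 0.10, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.010}
  - {name: brain,           volume_L: 1.45,  plasma_flow_L_per_min: 0.32,  vascular_fraction: 0.04, interstitial_fraction: 0.18, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.003}
  - {name: gut,             volume_L: 1.10,  plasma_flow_L_per_min: 0.45,  vascular_fraction: 0.07, interstitial_fraction: 0.28, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.045}
  - {name: heart,           volume_L: 0.33,  plasma_flow_L_per_min: 0.12,  vascular_fraction: 0.14, interstitial_fraction: 0.10, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.012}
  - {name: kidneys,         volume_L: 0.31,  plasma_flow_L_per_min: 0.55,  vascular_fraction: 0.16, interstitial_fraction: 0.25, receptor_density_nmol_per_L: 15.0, permeability_L_per_min: 0.055}
  - {name: liver,           volume_L: 1.80,  plasma_flow_L_per_min: 0.50,  vascular_fraction: 0.21, interstitial_fraction: 0.16, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.050}
  - {name: lungs,           volume_L: 0.50,  plasma_flow_L_per_min: 0.12,  vascular_fraction: 0.26, interstitial_fraction: 0.19, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.012}
  - {name: muscle,          volume_L: 29.0,  plasma_flow_L_per_min: 0.42,  vascular_fraction: 0.03, interstitial_fraction: 0.13, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.042}
  - {name: pancreas,        volume_L: 0.14,  plasma_flow_L_per_min: 0.06,  vascular_fraction: 0.10, interstitial_fraction: 0.17, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.006}
  - {name: prostate,        volume_L: 0.016, plasma_flow_L_per_min: 0.01,  vascular_fraction: 0.04, interstitial_fraction: 0.25, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.001}
  - {name: red_marrow,      volume_L: 1.10,  plasma_flow_L_per_min: 0.14,  vascular_fraction: 0.10, interstitial_fraction: 0.20, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.014}
  - {name: salivary_glands, volume_L: 0.085, plasma_flow_L_per_min: 0.03,  vascular_fraction: 0.06, interstitial_fraction: 0.22, receptor_density_nmol_per_L: 25.0, permeability_L_per_min: 0.003}
  - {name: skin,            volume_L: 3.30,  plasma_flow_L_per_min: 0.16,  vascular_fraction: 0.02, interstitial_fraction: 0.30, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.016}
  - {name: spleen,          volume_L: 0.15,  plasma_flow_L_per_min: 0.08,  vascular_fraction: 0.28, interstitial_fraction: 0.15, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.008}
  - {name: testes,          volume_L: 0.035, plasma_flow_L_per_min: 0.003, vascular_fraction: 0.04, interstitial_fraction: 0.24, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.0003}
  - {name: thyroid,         volume_L: 0.02,  plasma_flow_L_per_min: 0.03,  vascular_fraction: 0.11, interstitial_fraction: 0.15, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.003}
  - {name: rest_of_body,    volume_L: 5.0,   plasma_flow_L_per_min: 0.10,  vascular_fraction: 0.04, interstitial_fraction: 0.18, receptor_density_nmol_per_L: 0.0,  permeability_L_per_min: 0.010}

# The tumor organ is created per virtual patient; flow and permeability scale
# with tumor volume, receptor density comes from the patient definition.
tumor:
  perfusion_per_min: 0.1               # plasma flow per L of tumor
  permeability_per_min: 0.05           # PS per L of tumor
  vascular_fraction: 0.08
  interstitial_fraction: 0.30
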