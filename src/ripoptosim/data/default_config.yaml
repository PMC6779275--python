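# Default model configuration: HeLa-like study conditions.
# Units are encoded in key names: concentrations in nM, bimolecular rates in
# nM^-1 min^-1, unimolecular/catalytic rates in min^-1, masses in kDa.
# Values marked placeholder in metadata are calibrated stand-ins for
# quantities not printed in the primary sources.

geometry:
  volume_l: 2.5e-12

initial_nm:
  fadd: 50.0
  rip1: 60.0
  rip3: 8.0
  procasp8: 90.0
  cflip_l: 20.0
  cflip_s: 10.0
  procasp3: 200.0
  procasp6: 60.0
  xiap: 63.0            # mean XIAP level quantified for HeLa
  fret_substrate: 600.0

rates:
  kon_rip1_rip1: 0.05
  kon_rip3_rip1: 1.0e-5
  kon_fadd_platform: 1.0e-2
  kon_procasp8_ded: 1.5e-3
  kon_cflip_l_ded: 7.5e-4
  kon_cflip_s_ded: 7.5e-4
  kon_ded12_ded: 7.5e-4
  koff_rip1_rip1: 1.0e-4
  koff_rip3_rip1: 0.01
  koff_fadd_platform: 0.12
  koff_procasp8_ded: 0.3
  koff_cflip_l_ded: 0.3
  koff_cflip_s_ded: 0.3
  koff_ded12_ded: 0.3
  k_cis_dimer: 0.006
  k_trans_dimer: 0.0015
  k_dimer_diss: 0.2
  k_casp8_activation: 1.0
  k_casp8_casp3: 0.02
  k_casp3_auto: 0.06
  k_casp3_casp6: 0.01
  k_casp6_casp8: 1.0e-4
  k_casp8m_dimerization: 1.0e-4
  k_casp8m_deg: 0.01
  k_casp8d_diss: 0.1
  kon_xiap_casp3: 0.3
  koff_xiap_casp3: 0.05
  kcat_ub: 1.75         # XIAP-driven Casp3 ubiquitination/degradation
  k_basal_deg: 0.04     # basal ubiquitin-dependent degradation
  k_fret_cleavage: 0.0025
  cflipl_heterodimer_activity: 0.0
  xiap_recycled: 0.5

masses_kda:
  rip1: 76.0
  rip3: 57.0
  fadd: 23.0
  procasp8: 55.0
  cflip_l: 55.0
  cflip_s: 26.0
  ded12: 26.0

receptors:
  tnfr1: {count: 905, kd_nm: 1.0}
  dr4: {count: 769, kd_nm: 1.0}
  dr5: {count: 926, kd_nm: 1.0}

clustering:
  table_csv: cluster_sizes.csv

simulation:
  dt_sync_min: 0.1
  record_grid_min: 1.0
  t_max_min: 1440.0
  rk_substep_min: 0.02
  death_threshold_rate_nm_min: 0.0394
  ligand_mass_kda: 19.6
  cv_on: rate

metadata:
  description: HeLa-like default parameterisation
  placeholder_fields:
    # quantities not printed in the primary sources; values are calibrated
    # placeholders reproducing the documented qualitative regime
    - geometry.volume_l
    - masses_kda (canonical UniProt masses)
    - receptors.*.kd_nm
    - clustering table (placeholder distribution over sizes 1-8)
    - all rates except kcat_ub and k_basal_deg
    - initial_nm except xiap
    - simulation.death_threshold_rate_nm_min (calibrated-not-printed)
  placeholder: true
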