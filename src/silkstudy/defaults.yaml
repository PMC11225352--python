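# Structural constants of the Abeta40 transport model and study-level defaults.
# Everything here is configuration: the kinetic fit never touches this file's
# values except through KineticParameters / CohortConfig construction.

volumes:
  # Age-linear CSF compartment volumes, mL: V = f_VCSF * (a + b * age_years).
  # Coefficients chosen so ventricular + cisternal + cranial-SAS volume is
  # ~150 mL at age 70 (35 + 15 + 100), growing ~1 mL/y in total with age.
  ventricular:   {a: 14.0, b: 0.30}
  cisternal:     {a:  8.0, b: 0.10}
  cranial_sas:   {a: 58.0, b: 0.60}
  reference_age: 70.0
  reference_total_mL: 150.0

structure:
  f_ab40: 0.10        # stoichiometric fraction of APP processed to Abeta40
  tau_delay_h: 3.0    # labeling/processing delay between plasma leucine and ISF Abeta
  phi_cranial: 0.75   # fraction of CSF absorbed via the cranial SAS
  k_t_mL_per_h: 15.0  # ISF -> ventricular solute transport, equivalent flow
  v_isf_mL: 250.0     # brain interstitial fluid volume
  n_leu: 1            # leucines counted per peptide in the labeled fraction

nominal:
  # Starting / reference values for adjustable parameters (not fit results).
  k_bpd40_per_h: 0.08
  sf40: 1.0
  q_csf_mL_per_h: 20.0
  q_osc_mL_per_h: 30.0
  r_app_nmol_per_h: 1.0

units:
  ab40_pg_per_nmol: 4.3298e6   # MW 4329.8 g/mol

infusion:
  bolus_mg_per_kg: 3.0
  rate_mg_per_kg_h: 2.0
  duration_h: 9.0
  plateau_enrichment: 0.12     # steady-state plasma 13C6-leucine mole fraction
  k_leucine_per_h: 0.6667      # plasma leucine pool turnover (primes exactly at 3:2)

schedule:
  draw_volume_mL: 6.0
  times_h: [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 26, 28, 30, 32, 34, 36]
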