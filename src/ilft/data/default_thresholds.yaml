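# Default trigger thresholds and cutoffs for the reflex liver-testing engine.
# Every value can be overridden by a site-specific YAML file with the same keys.

# --- first-line triggers ------------------------------------------------
alt_trigger: 30.0        # U/L; ALT above this cascades a full screen (deliberately not sex-specific)
alt_marked: 250.0        # U/L; ALT at/above this raises the urgent marked-ALT outcome
alp_url: 130.0           # U/L; upper reference limit for ALP
alp_full_cascade: 200.0  # U/L; isolated ALP above this cascades a full screen
ggt_url: 60.0            # U/L; local upper reference limit for GGT
bili_mild_low: 22.0      # umol/L; total bilirubin at/above this is abnormal
bili_mild_high: 60.0     # umol/L; isolated total bilirubin above this cascades a full screen
crp_age_max: 45          # years; CRP (and conditionally caeruloplasmin) cascade only below this age

# --- indirect fibrosis score cutoffs ------------------------------------
fib4_low: 1.30           # FIB-4 below this rules out significant fibrosis
fib4_high: 2.67          # FIB-4 above this rules in significant fibrosis
nfs_low: -1.455          # NFS below this rules out (presumed-MASLD branches only)
nfs_high: 0.676          # NFS above this rules in

# --- ELF (direct fibrosis marker) ---------------------------------------
elf_moderate: 7.7        # unitless; at/above = at least moderate fibrosis
elf_severe: 9.8          # unitless; at/above = severe fibrosis, referral threshold
elf_cirrhosis: 11.3      # unitless; at/above = cirrhosis band
elf_urgent: 13.0         # unitless; at/above = urgent prognostic alert

# --- ELF formula coefficients (manufacturer calibration) ----------------
elf_intercept: 2.278
elf_coef_ha: 0.851       # multiplies ln(hyaluronic acid)
elf_coef_piiinp: 0.751   # multiplies ln(PIIINP)
elf_coef_timp1: 0.394    # multiplies ln(TIMP-1)

# --- aetiology screen cutoffs -------------------------------------------
a1at_deficiency: 1.0     # g/L; A1AT below this flags possible deficiency
transferrin_sat_high: 45.0  # %; transferrin saturation above this flags iron overload
crp_elevated: 5.0        # mg/L; CRP above this counts as an inflammatory state
caeruloplasmin_low: 0.20 # g/L; caeruloplasmin below this flags possible Wilson disease
conjugated_fraction: 0.20  # direct/total bilirubin below this = predominantly unconjugated
haptoglobin_low: 0.3     # g/L; haptoglobin below this suggests haemolysis

# --- malignancy alert ---------------------------------------------------
malignancy_age: 40       # years; alert requires age strictly over this
malignancy_alp: 130.0    # U/L; alert requires ALP strictly above this
malignancy_platelets: 400.0  # x10^9/L; alert requires platelets strictly above this

# --- nomenclature -------------------------------------------------------
legacy_nomenclature: false  # true restores pre-SLD names (NAFLD etc.) in outcome text
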