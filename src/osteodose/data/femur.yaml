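# Parameter registry: human femur as a hematopoietic site.
#
# Macro-parameters (cm) describe the stylized segment shapes:
#   RC - round cylinder      (h, d1)
#   EC - elliptical cylinder (h, d1, d2)
#   DC - deformed cylinder   (h, d1 round base -> d2 x d3 elliptical base)
# Each numeric pair is [mean, CV%] describing inter-individual variability.
# Micro-parameters (mm) describe the spongiosa microarchitecture; BV/TV is
# dimensionless with an inter-individual min-max range.
#
# capped_faces lists the outer walls carrying the cortical shell; faces where
# two modeled segments touch carry no cortex.
schema_version: 1
site: femur
segments:
  - name: diaphysis
    age_group: newborn
    sex: both
    shape: RC
    h: [3.78, 5]
    d1: [0.72, 11]
    ct_th: [0.17, 24]
    capped_faces: [lateral]
    micro_key: all
  - name: proximal_end
    age_group: newborn
    sex: both
    shape: DC
    h: [1.89, 5]
    d1: [0.72, 11]
    d2: [2.64, 9]
    d3: [1.16, 12]
    ct_th: [0.05, 24]
    capped_faces: [lateral, axial_top]
    micro_key: all
  - name: distal_end
    age_group: newborn
    sex: both
    shape: DC
    h: [1.89, 5]
    d1: [0.72, 11]
    d2: [2.64, 9]
    d3: [1.16, 12]
    ct_th: [0.04, 25]
    capped_faces: [lateral, axial_bottom]
    micro_key: all

  - name: diaphysis
    age_group: 1y
    sex: both
    shape: RC
    h: [7.15, 4]
    d1: [1.12, 7]
    ct_th: [0.23, 17]
    capped_faces: [lateral]
    micro_key: all
  - name: proximal_end
    age_group: 1y
    sex: both
    shape: DC
    h: [3.58, 4]
    d1: [1.12, 7]
    d2: [3.4, 12]
    d3: [1.8, 8]
    ct_th: [0.07, 17]
    capped_faces: [lateral, axial_top]
    micro_key: all
  - name: distal_end
    age_group: 1y
    sex: both
    shape: DC
    h: [3.58, 4]
    d1: [1.12, 7]
    d2: [3.4, 12]
    d3: [1.8, 8]
    ct_th: [0.06, 17]
    capped_faces: [lateral, axial_bottom]
    micro_key: all

  - name: diaphysis
    age_group: 5y
    sex: both
    shape: RC
    h: [14.8, 4]
    d1: [1.66, 6]
    ct_th: [0.37, 8]
    capped_faces: [lateral]
    micro_key: diaphysis_distal
  - name: upper_proximal_end
    age_group: 5y
    sex: both
    shape: RC
    h: [2.47, 4]
    d1: [2.3, 23]
    ct_th: [0.13, 14]
    capped_faces: [lateral, axial_top]
    micro_key: proximal
  - name: lower_proximal_end
    age_group: 5y
    sex: both
    shape: RC
    h: [2.47, 4]
    d1: [2.3, 23]
    ct_th: [0.13, 14]
    capped_faces: [lateral]
    micro_key: proximal
  - name: distal_end
    age_group: 5y
    sex: both
    shape: DC
    h: [4.94, 4]
    d1: [1.66, 6]
    d2: [6.82, 6]
    d3: [2.5, 7]
    ct_th: [0.11, 7]
    capped_faces: [lateral, axial_bottom]
    micro_key: diaphysis_distal

  - name: upper_proximal_end
    age_group: 10y
    sex: both
    shape: RC
    h: [3.46, 5]
    d1: [2.49, 7]
    ct_th: [0.18, 17]
    capped_faces: [lateral, axial_top]
    micro_key: proximal
  - name: lower_proximal_end
    age_group: 10y
    sex: both
    shape: RC
    h: [3.46, 5]
    d1: [2.49, 7]
    ct_th: [0.22, 12]
    capped_faces: [lateral, axial_bottom]
    micro_key: proximal
  - name: distal_end
    age_group: 10y
    sex: both
    shape: DC
    h: [6.92, 5]
    d1: [7.84, 7]
    d2: [3.32, 10]
    d3: [2.1, 9]
    ct_th: [0.11, 14]
    capped_faces: [lateral, axial_top, axial_bottom]
    micro_key: diaphysis_distal

  # Femoral growth is completed by age 15; the adult rows reuse the 15-y
  # macro-dimensions for the neck (male and female) while the trochanter-area
  # dimensions are shared between the 15-y and adult rows.
  - name: neck
    age_group: 15y
    sex: male
    shape: EC
    h: [2.96, 5]
    d1: [3.6, 14]
    d2: [3.2, 13]
    ct_th: [0.20, 19]
    capped_faces: [lateral, axial_top]
    micro_key: neck
  - name: trochanter_area
    age_group: 15y
    sex: male
    shape: DC
    h: [4.1, 4]
    d1: [6.6, 6]
    d2: [4.4, 6]
    d3: [3.0, 7]
    ct_th: [0.23, 15]
    capped_faces: [lateral, axial_bottom]
    micro_key: trochanter
  - name: neck
    age_group: adult
    sex: male
    shape: EC
    h: [2.96, 5]
    d1: [3.6, 14]
    d2: [3.2, 13]
    ct_th: [0.20, 19]
    capped_faces: [lateral, axial_top]
    micro_key: neck
  - name: trochanter_area
    age_group: adult
    sex: male
    shape: DC
    h: [4.1, 4]
    d1: [6.6, 6]
    d2: [4.4, 6]
    d3: [3.0, 7]
    ct_th: [0.23, 15]
    capped_faces: [lateral, axial_bottom]
    micro_key: trochanter

  - name: neck
    age_group: 15y
    sex: female
    shape: EC
    h: [3.05, 5]
    d1: [2.94, 10]
    d2: [2.39, 9]
    ct_th: [0.20, 19]
    capped_faces: [lateral, axial_top]
    micro_key: neck
  - name: trochanter_area
    age_group: 15y
    sex: female
    shape: DC
    h: [3.4, 5]
    d1: [5.8, 7]
    d2: [3.9, 7]
    d3: [2.7, 6]
    ct_th: [0.23, 15]
    capped_faces: [lateral, axial_bottom]
    micro_key: trochanter
  - name: neck
    age_group: adult
    sex: female
    shape: EC
    h: [3.05, 5]
    d1: [2.94, 10]
    d2: [2.39, 9]
    ct_th: [0.20, 19]
    capped_faces: [lateral, axial_top]
    micro_key: neck
  - name: trochanter_area
    age_group: adult
    sex: female
    shape: DC
    h: [3.4, 5]
    d1: [5.8, 7]
    d2: [3.9, 7]
    d3: [2.7, 6]
    ct_th: [0.23, 15]
    capped_faces: [lateral, axial_bottom]
    micro_key: trochanter

# Microstructure does not depend on sex; male and female data are combined.
# intra_cv_* describe within-specimen spread of trabecular thickness and
# separation (near-lognormal in histomorphometric collections) and are a
# curated default, configurable per row.
micro:
  - age_group: newborn
    key: all
    bvtv: {mean: 0.37, min: 0.096, max: 0.53}
    tb_th: [0.11, 15]
    tb_sp: [0.39, 27]
  - age_group: 1y
    key: all
    bvtv: {mean: 0.22, min: 0.15, max: 0.32}
    tb_th: [0.16, 22]
    tb_sp: [0.54, 20]
  - age_group: 5y
    key: diaphysis_distal
    bvtv: {mean: 0.26, min: 0.17, max: 0.32}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: 5y
    key: proximal
    bvtv: {mean: 0.35, min: 0.23, max: 0.43}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: 10y
    key: diaphysis_distal
    bvtv: {mean: 0.26, min: 0.17, max: 0.32}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: 10y
    key: proximal
    bvtv: {mean: 0.35, min: 0.23, max: 0.43}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: 15y
    key: neck
    bvtv: {mean: 0.35, min: 0.23, max: 0.43}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: 15y
    key: trochanter
    bvtv: {mean: 0.26, min: 0.17, max: 0.32}
    tb_th: [0.24, 22]
    tb_sp: [0.54, 14]
  - age_group: adult
    key: neck
    bvtv: {mean: 0.17, min: 0.14, max: 0.22}
    tb_th: [0.19, 11]
    tb_sp: [0.78, 13]
  - age_group: adult
    key: trochanter
    bvtv: {mean: 0.11, min: 0.08, max: 0.13}
    tb_th: [0.14, 9]
    tb_sp: [1.0, 13]
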