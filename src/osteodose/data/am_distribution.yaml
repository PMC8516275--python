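# Distribution of active (red) marrow over the hematopoietic sites of the
# skeleton, % of whole-skeleton AM mass, by age group.  Rows that the source
# compilation splits over bone parts (e.g. femoral diaphysis vs proximal vs
# distal parts) are aggregated to whole-site totals here; sites whose
# hematopoiesis has ceased at a given age carry weight 0.  Raw columns do not
# sum exactly to 100 (table granularity); weights are renormalized before
# use.  Adult values carry an SD where the source reports one.
schema_version: 1
weights:
  skull:
    newborn: 28.2
    1y: 28.7
    5y: 18.1
    10y: 12.8
    15y: 10.2
    adult: {mean: 6.2, sd: 2.3}
  ribs_scapulae_clavicles:
    newborn: 22.9
    1y: 26.6
    5y: 18.0
    10y: 18.0
    15y: 18.0
    adult: {mean: 15.3, sd: 2.6}
  cervical_vertebrae:
    newborn: 1.7
    1y: 2.1
    5y: 2.3
    10y: 2.7
    15y: 3.3
    adult: {mean: 3.5, sd: 1.0}
  thoracic_vertebrae:
    newborn: 7.2
    1y: 8.3
    5y: 9.2
    10y: 11.0
    15y: 13.8
    adult: {mean: 17.5, sd: 2.4}
  lumbar_vertebrae:
    newborn: 5.5
    1y: 6.4
    5y: 7.0
    10y: 8.5
    15y: 10.6
    adult: {mean: 15.5, sd: 2.5}
  sacrum:
    newborn: 4.4
    1y: 5.1
    5y: 5.7
    10y: 6.8
    15y: 8.5
    adult: {mean: 7.4, sd: 1.8}
  pelvis:
    newborn: 11.4
    1y: 13.1
    5y: 13.5
    10y: 15.9
    15y: 18.6
    adult: {mean: 23.2, sd: 3.0}
  femur:
    newborn: 6.7
    1y: 8.1
    5y: 13.5
    10y: 15.7
    15y: 11.3
    adult: {mean: 5.9, sd: 2.5}
  humerus:
    newborn: 4.5
    1y: 5.2
    5y: 4.8
    10y: 4.1
    15y: 3.8
    adult: {mean: 3.6, sd: 1.9}
  tibia_fibula:
    newborn: 7.1
    1y: 8.7
    5y: 9.3
    10y: 5.6
    15y: 0.0
    adult: 0.0
  radius_ulna:
    newborn: 2.4
    1y: 2.6
    5y: 2.1
    10y: 0.0
    15y: 0.0
    adult: 0.0
  hands_feet:
    newborn: 10.8
    1y: 0.0
    5y: 0.0
    10y: 0.0
    15y: 0.0
    adult: 0.0
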