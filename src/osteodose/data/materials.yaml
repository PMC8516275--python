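# Tissue densities (g/cm^3) and elemental compositions (% by mass) of
# hydrated mineralized bone and of active/inactive marrow.  Newborn bone is
# less mineralized (lower Ca/P, lower density) than adult bone; marrow
# composition is treated as age-independent.  Adult bone density is a
# representative value for the adult measurement series (1.86-1.91 g/cm^3);
# the 1.84 g/cm^3 series for ages 2-19 differs from it by < 5% and the adult
# value is used for every age group past the first year.
schema_version: 1
materials:
  mineralized_bone_newborn:
    density: 1.65
    elements: {H: 4.2, C: 16.0, N: 4.5, O: 50.2, Na: 0.0, Mg: 0.3, P: 8.0, S: 0.3, Ca: 16.5, Fe: 0.0}
  mineralized_bone_adult:
    density: 1.90
    elements: {H: 3.5, C: 16.0, N: 4.2, O: 44.5, Na: 0.3, Mg: 0.2, P: 9.5, S: 0.3, Ca: 21.5, Fe: 0.0}
  active_marrow:
    density: 1.029
    elements: {H: 10.5, C: 41.4, N: 3.4, O: 43.9, Na: 0.1, Mg: 0.2, P: 0.2, S: 0.2, Ca: 0.0, Fe: 0.1}
  inactive_marrow:
    density: 0.98
    elements: {H: 11.5, C: 64.4, N: 0.7, O: 23.1, Na: 0.1, Mg: 0.0, P: 0.1, S: 0.1, Ca: 0.0, Fe: 0.0}
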