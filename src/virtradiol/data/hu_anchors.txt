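# Piecewise-linear Hounsfield-unit -> tissue anchor table (version 1).
# One row per anchor: name  HU  density_g_cm3  element:mass_fraction ...
# Compositions follow standard ICRP/ICRU reference tissues; densities and
# nominal HU values are the conventional CT anchor points (water=0, air=-1000).
# HU below the first anchor clamp to it; interpolation is linear in HU for
# both density and composition between consecutive anchors.
air            -1000  0.0012  C:0.000124 N:0.755267 O:0.231781 Ar:0.012827
lung            -740  0.26    H:0.103 C:0.105 N:0.031 O:0.749 Na:0.002 P:0.002 S:0.003 Cl:0.003 K:0.002
adipose          -98  0.95    H:0.114 C:0.598 N:0.007 O:0.278 Na:0.001 S:0.001 Cl:0.001
water              0  1.000   H:0.111894 O:0.888106
soft_tissue       45  1.05    H:0.102 C:0.143 N:0.034 O:0.710 Na:0.001 P:0.002 S:0.003 Cl:0.001 K:0.004
trabecular_bone  260  1.18    H:0.085 C:0.404 N:0.028 O:0.367 Na:0.001 Mg:0.001 P:0.034 S:0.002 Cl:0.002 K:0.001 Ca:0.074 Fe:0.001
cortical_bone   1524  1.92    H:0.034 C:0.155 N:0.042 O:0.435 Na:0.001 Mg:0.002 P:0.103 S:0.003 Ca:0.225
dense_bone      3000  2.60    H:0.034 C:0.155 N:0.042 O:0.435 Na:0.001 Mg:0.002 P:0.103 S:0.003 Ca:0.225
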