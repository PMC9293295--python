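"""Internal unit system.

All internal quantities use a single consistent system:

====================  ========
length                cm
time                  ms
potential             mV
conductance           mS
capacitance           uF
current               uA
====================  ========

so that (mS/cm^2) * mV = uA/cm^2 and uF/cm^2 * mV / ms = uA/cm^2 hold
without conversion factors.  Configuration files accept the habitual
units of the field (um for cell dimensions, nm for cleft widths) and are
converted on load with the constants below.
"""

UM_TO_CM = 1e-4
NM_TO_CM = 1e-7
CM2_TO_UM2 = 1e8
MS_PER_S = 1e3

# current conversions (internal current unit is uA)
UA_TO_NA = 1e3
NA_TO_UA = 1e-3
US_TO_MS = 1e-3   # microsiemens -> millisiemens
NS_TO_MS = 1e-6   # nanosiemens -> millisiemens
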