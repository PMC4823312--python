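"""Unit conventions and conversions.

The public API works in the units customary for small-animal MEG modeling:

* lengths in **mm**,
* conductivities in **S/m**,
* dipole moments in **uAmm** (1 uAmm = 1e-9 A.m = 1 nA.m),
* magnetic flux density in **fT**.

The finite-element internals convert to SI (m, A.m, S/m, V, T) at module
boundaries; every conversion factor lives here.
"""

#: mu_0 / (4 pi) in T.m/A
MU0_OVER_4PI = 1.0e-7

#: millimetres -> metres
MM_TO_M = 1.0e-3

#: uAmm -> A.m  (1 uA * 1 mm = 1e-6 A * 1e-3 m)
UAMM_TO_AM = 1.0e-9

#: tesla -> femtotesla
T_TO_FT = 1.0e15
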