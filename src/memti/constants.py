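"""Physical constants shared across the package (SI units)."""

import math

#: Vacuum magnetic permeability, H/m.
MU0 = 4.0e-7 * math.pi

#: Vacuum electric permittivity, F/m.
EPS0 = 8.8541878128e-12

#: One oersted expressed in A/m (CGS -> SI conversion for magnetic field).
A_PER_M_PER_OE = 1.0e3 / (4.0 * math.pi)
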