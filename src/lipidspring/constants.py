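"""Physical constants and internal units.

All quantities in the package are expressed in pN, nm, ns and K. In these
units the Boltzmann constant is kB = 0.0138065 pN nm / K, so that at
T = 303 K the thermal energy kB*T is about 4.18 pN nm.
"""

#: Boltzmann constant in pN nm / K.
KB = 0.0138065
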