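"""Physical constants and unit conventions.

Distances are Å, charges elementary charges (e), polarizabilities Å³ and
energies eV.  With those units the Coulomb energy of two unit charges at
1 Å is ``K_E`` eV, and electrostatic potentials/fields computed as q/r and
q/r² stay in e/Å and e/Å² until an energy is formed.
"""

# Coulomb constant e²/(4πε₀) in eV·Å
K_E = 14.3996454
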