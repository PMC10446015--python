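"""Unit conversions.

Everything inside the package is in Hartree atomic units (hartree, bohr,
electron mass, hbar = 1); femtoseconds, eV and angstrom appear only at I/O
boundaries.
"""

#: atomic time units per femtosecond
FS_TO_AU = 41.341374575751

#: hartree per electron-volt
EV_TO_HARTREE = 1.0 / 27.211386245988

#: electron-volts per hartree
HARTREE_TO_EV = 27.211386245988

#: bohr per angstrom
ANGSTROM_TO_BOHR = 1.0 / 0.529177210903

#: reduced Planck constant (atomic units)
HBAR = 1.0
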