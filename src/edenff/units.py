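"""Unit conversion constants.

All internal quantities are in Hartree atomic units (bohr, hartree);
file I/O and reporting use Ångström and kJ/mol.
"""

ANGSTROM_PER_BOHR = 0.52917721067
BOHR_PER_ANGSTROM = 1.0 / ANGSTROM_PER_BOHR

KJ_PER_MOL_PER_HARTREE = 2625.4996394798
HARTREE_PER_KJ_PER_MOL = 1.0 / KJ_PER_MOL_PER_HARTREE
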