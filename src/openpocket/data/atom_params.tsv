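# Van der Waals radii and Lennard-Jones 12-6 coefficients for grid potentials.
# One row per atom class, keyed first by PDB atom name (within any residue),
# then by element as a fallback.  Columns (tab-separated):
#   key     'name:<atom name>' or 'elem:<element symbol>'
#   w_a     van der Waals radius, Angstrom (used in the atom density map)
#   A       repulsive 12-6 coefficient, kcal/mol * A^12
#   B       attractive 12-6 coefficient, kcal/mol * A^6
# The A/B values follow the pair-coefficient convention against a carbon-like
# probe: with well depth eps (kcal/mol) and minimum-energy distance
# r_min = w_a + 1.7 A, A = eps * r_min^12 and B = 2 * eps * r_min^6, so the
# single-atom potential has its minimum -eps at r_min.  These are documented
# implementation defaults in the spirit of the ECEPP force-field tables and
# may be overridden with a user-supplied table of the same format.
# 'elem:X' is the generic fallback row (carbon-like pseudo-atom).
key	w_a	A	B
elem:C	1.70	286370.48	370.7531
elem:N	1.55	222187.85	377.0945
elem:O	1.52	248485.16	445.8566
elem:S	1.80	675844.10	735.3063
elem:P	1.80	675844.10	735.3063
elem:H	1.20	7076.30	23.7929
elem:F	1.47	185346.19	365.3071
elem:CL	1.75	710835.57	843.1106
elem:BR	1.85	1201881.06	1200.9402
elem:I	1.98	2158946.44	1738.5411
elem:SE	1.90	1184595.33	1088.3912
elem:X	1.70	286370.48	370.7531
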