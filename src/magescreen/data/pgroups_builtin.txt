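# Minimal HLA-A P-group table in the IMGT/HLA hla_nom_p.txt dialect:
#   locus*;allele1/allele2/...;group
# Covers the P groups the A*02 eligibility rules distinguish plus common
# neutral HLA-A alleles seen in screening data. Alleles absent from this
# table resolve to singleton groups named after their two-field projection.
A*;02:01:01:01/02:01:01:02L/02:01:02/02:09/02:43N/02:66/02:75/02:89/02:97:01/02:132/02:134/02:140/02:642;02:01P
A*;02:02:01/02:02:02/02:02:03;02:02P
A*;02:03:01/02:03:02/02:03:03;02:03P
A*;02:05:01/02:05:02/02:05:03/02:08/02:220;02:05P
A*;02:06:01/02:06:02/02:06:03;02:06P
A*;02:07:01/02:07:02;02:07P
A*;02:17:01/02:17:02;02:17P
A*;01:01:01:01/01:01:01:02N/01:01:02/01:04N;01:01P
A*;03:01:01:01/03:01:01:02N/03:01:02;03:01P
A*;11:01:01/11:01:02;11:01P
A*;23:01:01;23:01P
A*;24:02:01:01/24:02:01:02L/24:02:03;24:02P
A*;26:01:01;26:01P
A*;29:02:01;29:02P
A*;30:01:01;30:01P
A*;31:01:02;31:01P
A*;32:01:01;32:01P
A*;33:01:01;33:01P
A*;33:03:01;33:03P
A*;68:01:01/68:01:02;68:01P
A*;68:02:01;68:02P
A*;69:01:01;69:01P
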