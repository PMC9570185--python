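# Synthetic placeholder coefficients for the MetS severity z-score
#   z = Y + a*waist - b*HDLc + c*SBP + d*log(TG) + e*glucose
# The authoritative sex/ethnicity/age-specific coefficients come from the
# external metscalc severity-score calculator and are not shipped here;
# replace this table with calculator output for real analyses.  The
# placeholder values below are scaled so that typical European adult
# control/case profiles land near -0.7 / +0.7.
sex,ethnicity,age_group,Y,a,b,c,d,e
male,default,adult,-6.8,0.02,0.03,0.01,0.9,0.012
female,default,adult,-6.8,0.02,0.03,0.01,0.9,0.012
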