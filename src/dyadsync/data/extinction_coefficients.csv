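# Molar extinction coefficients of haemoglobin, version 1 (2026-09).
# Units: cm^-1 / (mol/L), base-10 (decadic) absorbance.
# Source lineage: W.B. Gratzer (Med. Res. Council Labs) and N. Kollias
# tabulation as compiled by S. Prahl (omlc.org), the table used by the
# Homer and MNE fNIRS toolchains.
wavelength_nm,hbo,hbr
760,1486.5865,3843.707
850,2526.391,1798.643
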