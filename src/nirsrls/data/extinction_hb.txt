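# Molar extinction coefficients of hemoglobin, units 1/(mM*cm).
# Standard compiled in-vitro hemoglobin spectra (Gratzer/Kollias compilation).
# Substitute your own tabulation by pointing MBLLParameters at another file
# with the same three-column layout.
# wavelength_nm  eps_hbo2  eps_hhb
760 0.5864 1.5485
850 1.0580 0.6913
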