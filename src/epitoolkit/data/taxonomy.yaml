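# Default domain -> (family, subfamily) taxonomy covering every subfamily of
# the nine-family epigenetic-gene classification. One representative Pfam-style
# accession per subfamily; real inventories should override this map with the
# project's own curated accession lists (several subfamilies share Pfam clans
# in reality and cannot be told apart by a single accession).
domain_map:
  PF08214: {family: HAT, subfamily: CBP/P300}        # HAT_KAT11
  PF00583: {family: HAT, subfamily: GNAT}            # Acetyltransf_1
  PF01853: {family: HAT, subfamily: MYST}            # MOZ_SAS
  PF10394: {family: HAT, subfamily: Other}           # Hat1_N
  PF00850: {family: HDAC, subfamily: Class I}        # Hist_deacetyl
  PF12203: {family: HDAC, subfamily: Class II}
  PF02146: {family: HDAC, subfamily: Class III}      # SIR2
  PF12047: {family: HDAC, subfamily: Class IV}
  PF05185: {family: HMT, subfamily: PRMT}            # PRMT5
  PF00856: {family: HMT, subfamily: SET}             # SET
  PF08123: {family: HMT, subfamily: DOT1}            # DOT1
  PF05175: {family: HMT, subfamily: Other}           # MTS
  PF02373: {family: HDMT, subfamily: JMJ}            # JmjC
  PF01593: {family: HDMT, subfamily: LSD}            # Amino_oxidase
  PF00538: {family: HISTONE, subfamily: H1}          # Linker_histone
  PF16211: {family: HISTONE, subfamily: H2A}         # Histone H2A C-term
  PF00125: {family: HISTONE, subfamily: H3}          # Histone core (fallback H3)
  PF00808: {family: HISTONE, subfamily: H2B}
  PF15511: {family: HISTONE, subfamily: H4}          # CENP-T/Histone fold
  PF00145: {family: DNA_METH, subfamily: DNA methyltransferase}  # DNA_methylase
  PF13532: {family: DNA_METH, subfamily: ALKB}       # 2OG-FeII_Oxy_2
  PF05063: {family: DNA_METH, subfamily: DAMT-1}     # MT-A70
  PF03368: {family: NCRNA, subfamily: Dicer}         # Dicer_dimer
  PF05183: {family: NCRNA, subfamily: RdRP}          # RdRP
  PF00271: {family: NCRNA, subfamily: Helicases}     # Helicase_C
  PF02171: {family: NCRNA, subfamily: Argonautes}    # Piwi
  PF14622: {family: NCRNA, subfamily: Drosha}        # Ribonucleas_3_3
  PF04427: {family: NCRNA, subfamily: Microprocessor complex}  # Brix? placeholder
  PF00176: {family: REMODELER, subfamily: SWI/SNF}   # SNF2_N
  PF13892: {family: REMODELER, subfamily: ISWI}
  PF13893: {family: REMODELER, subfamily: INO80}
  PF00385: {family: REMODELER, subfamily: CHD}       # Chromo
  PF00069: {family: OTHER, subfamily: Histone kinase}          # Pkinase
  PF00481: {family: OTHER, subfamily: Histone phosphatase}     # PP2C
  PF00097: {family: OTHER, subfamily: Histone ubiquitin transferase}  # zf-C3HC4
  PF00443: {family: OTHER, subfamily: Histone deubiquitinase}  # UCH
# Reference-protein fallback map (protein id -> family/subfamily); filled in
# per analysis. Unresolvable genes fall to OTHER / "Misc.".
reference_map: {}
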