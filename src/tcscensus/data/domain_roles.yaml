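# Domain-role dictionary for two-component-system classification.
#
# Each entry maps a domain model (name, optional Pfam accession) to the
# functional role it plays in a signal-transduction protein.  Name lookup is
# case-insensitive; accession lookup is exact.  Domains absent from this file
# resolve to the role "unknown" (they are never an error: unknown segments
# are candidate novel output domains).
#
# Edit or extend freely; the pipeline reloads this file on every run.

phosphotransfer_dimerization:
  - {name: HisKA, accession: PF00512}
  - {name: HisKA_2, accession: PF07568}
  - {name: HisKA_3, accession: PF07730}
  - {name: DHp}
  - {name: HWE_HK, accession: PF07536}

phosphotransfer_atpase:
  - {name: HATPase_c, accession: PF02518}
  - {name: HATPase}

hpt:
  - {name: Hpt, accession: PF01627}

chew:
  - {name: CheW, accession: PF01584}

receiver:
  - {name: REC, accession: PF00072}
  - {name: Response_reg}
  - {name: CheY}

sensor:
  - {name: PAS, accession: PF13426}
  - {name: PAS_3}
  - {name: PAS_4}
  - {name: PAS_8}
  - {name: PAS_11}
  - {name: GAF, accession: PF13492}
  - {name: GAF_2}
  - {name: GAF_3}
  - {name: Cache_1}
  - {name: sCache}
  - {name: dCache_1}
  - {name: MEDS, accession: PF14417}
  - {name: PocR, accession: PF10114}
  - {name: HisKA_7TM, accession: PF16927}
  - {name: HisKA_4TM, accession: PF16926}
  - {name: HAMP, accession: PF00672}

output_dna_binding:
  - {name: HTH_10, accession: PF04967}
  - {name: BAT, accession: PF15915}
  - {name: HTH}
  - {name: wHTH}
  - {name: HTH_20}
  - {name: ArsR}

output_enzymatic:
  - {name: CheB, accession: PF01339}
  - {name: CheB_methylest}
  - {name: iKaiC, accession: PF06745}
  - {name: KaiC}
  - {name: DUF835, accession: PF05763}
  - {name: Glyco_transf_2_3, accession: PF13641}
  - {name: BcsA}
  - {name: GGDEF, accession: PF00990}
  - {name: EAL, accession: PF00563}
  - {name: PP2C, accession: PF00481}
  - {name: SpoIIE}
  - {name: TrxR}
  - {name: PPDK}

output_other:
  - {name: HalX, accession: PF08663}
  - {name: MCPsignal, accession: PF00015}
  - {name: TPR, accession: PF13414}
  - {name: TPR_1}
  - {name: TPR_2}
  - {name: DUF1724, accession: PF08350}
  - {name: HalOD1, accession: PF18545}
  - {name: HalOD2, accession: PF18547}
  - {name: MetOD1, accession: PF18546}
  - {name: MetOD2, accession: PF18548}
  - {name: MetOD3}
  - {name: MetOD4}
  - {name: MetOD5}
  - {name: NitrOD1, accession: PF18549}
  - {name: NitrOD2, accession: PF18550}
  - {name: NitrOD3}
  - {name: NitrOD4}
  - {name: NitrOD5, accession: PF11537}
  - {name: TackOD1, accession: PF18551}
  - {name: AcidOD1}
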