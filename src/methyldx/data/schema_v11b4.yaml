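version: v11b4
classes:
- name: GBM, RTK I
  category: tumor
- name: GBM, RTK II
  category: tumor
- name: GBM, RTK III
  category: tumor
- name: GBM, MES
  category: tumor
- name: GBM, MID
  category: tumor
- name: GBM, MYCN
  category: tumor
- name: A IDH
  category: tumor
- name: A IDH, HG
  category: tumor
- name: O IDH
  category: tumor
- name: MB, G3
  category: tumor
- name: MB, G4
  category: tumor
- name: MB, SHH CHL AD
  category: tumor
- name: MB, SHH INF
  category: tumor
- name: ATRT, MYC
  category: tumor
- name: ATRT, SHH
  category: tumor
- name: ATRT, TYR
  category: tumor
- name: PLEX, AD
  category: tumor
- name: PLEX, PED A
  category: tumor
- name: PLEX, PED B
  category: tumor
- name: PA, PF
  category: tumor
- name: PA, MID
  category: tumor
- name: PA/GG, ST
  category: tumor
- name: PITAD, STH DNS A
  category: tumor
- name: PITAD, STH DNS B
  category: tumor
- name: PITAD, STH SPA
  category: tumor
- name: DMG, K27
  category: tumor
- name: GBM, G34
  category: tumor
- name: PXA
  category: tumor
- name: ANA PA
  category: tumor
- name: LGG, MYB
  category: tumor
- name: LGG, SEGA
  category: tumor
- name: LGG, DIG/DIA
  category: tumor
- name: LGG, RGNT
  category: tumor
- name: LGG, DNT
  category: tumor
- name: LGG, GG
  category: tumor
- name: DLGNT
  category: tumor
- name: CN
  category: tumor
- name: EVN
  category: tumor
- name: LIPN
  category: tumor
- name: PGG, nC
  category: tumor
- name: ENB, A
  category: tumor
- name: ENB, B
  category: tumor
- name: PIN T, PB A
  category: tumor
- name: PIN T, PB B
  category: tumor
- name: PIN T, PPT
  category: tumor
- name: PTPR, A
  category: tumor
- name: PTPR, B
  category: tumor
- name: ETMR
  category: tumor
- name: CNS NB, FOXR2
  category: tumor
- name: HGNET, BCOR
  category: tumor
- name: HGNET, MN1
  category: tumor
- name: MB, WNT
  category: tumor
- name: EPN, MPE
  category: tumor
- name: EPN, PF A
  category: tumor
- name: EPN, PF B
  category: tumor
- name: EPN, RELA
  category: tumor
- name: EPN, SPINE
  category: tumor
- name: EPN, YAP
  category: tumor
- name: SUBEPN, PF
  category: tumor
- name: SUBEPN, SPINE
  category: tumor
- name: SUBEPN, ST
  category: tumor
- name: EFT, CIC
  category: tumor
- name: EWS
  category: tumor
- name: CHGL
  category: tumor
- name: CPH, ADM
  category: tumor
- name: CPH, PAP
  category: tumor
- name: MNG
  category: tumor
- name: SFT HMPC
  category: tumor
- name: MELAN
  category: tumor
- name: MELCYT
  category: tumor
- name: SCHW
  category: tumor
- name: SCHW, MEL
  category: tumor
- name: LYMPHO
  category: tumor
- name: PLASMA
  category: tumor
- name: HMB
  category: tumor
- name: IHG
  category: tumor
- name: CHORDM
  category: tumor
- name: PITUI
  category: tumor
- name: PITAD, ACTH
  category: tumor
- name: PITAD, FSH LH
  category: tumor
- name: PITAD, PRL
  category: tumor
- name: PITAD, TSH
  category: tumor
- name: CONTR, ADENOPIT
  category: control
- name: CONTR, CEBM
  category: control
- name: CONTR, HEMI
  category: control
- name: CONTR, HYPTHAL
  category: control
- name: CONTR, INFLAM
  category: control
- name: CONTR, PINEAL
  category: control
- name: CONTR, PONS
  category: control
- name: CONTR, REACT
  category: control
- name: CONTR, WM
  category: control
families:
- name: methylation class family glioblastoma, IDH wildtype
  members:
  - GBM, RTK I
  - GBM, RTK II
  - GBM, RTK III
  - GBM, MES
  - GBM, MID
  - GBM, MYCN
- name: methylation class family IDH glioma
  members:
  - A IDH
  - A IDH, HG
  - O IDH
- name: methylation class family medulloblastoma, group 3/4
  members:
  - MB, G3
  - MB, G4
- name: methylation class family medulloblastoma, SHH
  members:
  - MB, SHH CHL AD
  - MB, SHH INF
- name: methylation class family ATRT
  members:
  - ATRT, MYC
  - ATRT, SHH
  - ATRT, TYR
- name: methylation class family plexus tumor
  members:
  - PLEX, AD
  - PLEX, PED A
  - PLEX, PED B
- name: methylation class family pilocytic astrocytoma
  members:
  - PA, PF
  - PA, MID
  - PA/GG, ST
- name: methylation class family pituitary adenoma, STH
  members:
  - PITAD, STH DNS A
  - PITAD, STH DNS B
  - PITAD, STH SPA
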