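# Default genotype rule table: seven-genotype classification of the
# gamma-PGA gene complement in Bacillus genomes, with order/strand/
# spacing subtypes. G3 precedes G2 because it is the more specific
# rule (same gene content, distinguished by the pgdS-ywtC gap).
version: bacillus-g7-v1
default: true
genotypes:
- label: G1
  required:
  - pghB
  - pghC
  - pghL
  - pghZ
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden: []
  subtypes:
  - label: SG1.1
    order: &id001
    - pghB
    - pghC
    - pghL
    - pghZ
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: ++++*+-----
    template_strands: ++++++-----
  - label: SG1.2
    order: *id001
    strands: +++-++-----
  - label: SG1.3
    order: &id002
    - pghB
    - pghC
    - pghL
    - pghZ
    - racE
    - ggt
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: ++++++-----
  - label: SG1.4
    order: &id003
    - pghB
    - pghC
    - pghZ
    - pghL
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: ++++++-----
  - label: SG1.5
    order: *id002
    strands: +++-++-----
  - label: SG1.6
    order: *id002
    strands: +++--+-----
  - label: SG1.7
    order: *id001
    strands: +++-+------
  - label: SG1.8
    order: *id003
    strands: ++-++------
  - label: SG1.9
    order: *id001
    strands: +++--------
- label: G3
  required:
  - pghB
  - pghC
  - pghL
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden:
  - pghZ
  spacing:
  - a: ywtC
    b: pgdS
    min: 1548
    max: 64082
  subtypes:
  - label: SG3.1
    order: &id004
    - pghB
    - pghC
    - pghL
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: '----++++++'
    spacing: &id005
    - a: ywtC
      b: pgdS
      min: 1548
      max: 1892
    gap_overrides:
      ywtC..pgdS: 1720
  - label: SG3.2
    order: *id004
    strands: ++++++++++
    spacing: *id005
    gap_overrides:
      ywtC..pgdS: 1720
  - label: SG3.3
    order: &id006
    - pghB
    - pghC
    - pghL
    - racE
    - ggt
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: '---+-+++++'
    spacing: *id005
    gap_overrides:
      ywtC..pgdS: 1720
  - label: SG3.4
    order: *id004
    strands: '----++++++'
    spacing:
    - a: ywtC
      b: pgdS
      min: 52430
      max: 64082
    gap_overrides:
      ywtC..pgdS: 58256
- label: G2
  required:
  - pghB
  - pghC
  - pghL
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden:
  - pghZ
  subtypes:
  - label: SG2.1
    order: *id004
    strands: '----++++++'
  - label: SG2.2
    order: *id006
    strands: '---+-+++++'
  - label: SG2.3
    order: *id004
    strands: ++++++++++
  - label: SG2.4
    order:
    - pghB
    - pghC
    - ggt
    - pghL
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: '----++++++'
  - label: SG2.5
    order: *id006
    strands: ++++++++++
  - label: SG2.6
    order: &id007
    - pghC
    - pghB
    - pghL
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: '----++++++'
  - label: SG2.7
    order:
    - pghB
    - pghC
    - pghL
    - ggt
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    - racE
    strands: '----++++++'
  - label: SG2.8
    order: *id007
    strands: ++++++++++
- label: G4
  required:
  - pghC
  - pghL
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden:
  - pghB
  - pghZ
  order:
  - pghC
  - pghL
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  strands: '---++++++'
- label: G5
  required:
  - pghB
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden:
  - pghC
  - pghL
  - pghZ
  - ggt
  order:
  - pghB
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  strands: -++++++
- label: G6
  required:
  - pghB
  - pghC
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - ywtC
  - pgdS
  forbidden:
  - pghL
  - pghZ
  subtypes:
  - label: SG6.1
    order: &id008
    - pghB
    - pghC
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    strands: +++------
  - label: SG6.2
    order: &id009
    - pghB
    - pghC
    - racE
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    - ggt
    strands: ++------+
  - label: SG6.3
    order: *id008
    strands: ++++-----
  - label: SG6.4
    order: &id010
    - pghB
    - pghC
    - ggt
    - pgsB
    - pgsC
    - pgsA
    - ywtC
    - pgdS
    - racE
    strands: +++------
  - label: SG6.5
    order: *id008
    strands: --+------
  - label: SG6.6
    order: *id008
    strands: +++++++++
  - label: SG6.7
    order: *id008
    strands: '---++++++'
  - label: SG6.8
    order: *id008
    strands: ++-------
  - label: SG6.9
    order: *id009
    strands: ++-------
  - label: SG6.10
    order: *id010
    strands: ++-------
- label: G7
  required:
  - pghB
  - pghC
  - ggt
  - racE
  - pgsB
  - pgsC
  - pgsA
  - pgdS
  forbidden:
  - pghL
  - pghZ
  - ywtC
  subtypes:
  - label: SG7.1
    order:
    - pghB
    - pghC
    - ggt
    - racE
    - pgsB
    - pgsC
    - pgsA
    - pgdS
    strands: +++-----
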