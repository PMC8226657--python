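name: mVDS
max_total: 100.0
items:
- item_id: lip_closure
  label: Lip closure
  levels:
  - intact
  - not intact
  weights:
  - 0.0
  - 6.0
- item_id: mastication
  label: Mastication
  levels:
  - possible
  - not possible
  weights:
  - 0.0
  - 11.5
- item_id: oral_transit_time
  label: Oral transit time
  levels:
  - <=1.5 s
  - '>1.5 s'
  weights:
  - 0.0
  - 4.0
- item_id: triggering_pharyngeal_swallow
  label: Triggering of pharyngeal swallow (swallowing reflex)
  levels:
  - intact
  - delayed
  weights:
  - 0.0
  - 7.0
- item_id: epiglottis_inversion
  label: Epiglottis inversion
  levels:
  - 'yes'
  - 'no'
  weights:
  - 0.0
  - 13.0
- item_id: valleculae_residue
  label: Valleculae residue
  levels:
  - 0%
  - <10%
  - '>=10%, <50%'
  - '>=50%'
  weights:
  - 0.0
  - 3.0
  - 6.0
  - 9.0
- item_id: pyriformis_residue
  label: Pyriformis residue
  levels:
  - 0%
  - <10%
  - '>=10%, <50%'
  - '>=50%'
  weights:
  - 0.0
  - 6.5
  - 13.0
  - 19.5
- item_id: pharyngeal_wall_coating
  label: Pharyngeal wall coating
  levels:
  - 'no'
  - 'yes'
  weights:
  - 0.0
  - 13.0
- item_id: aspiration
  label: Aspiration
  levels:
  - intact
  - penetration
  - aspiration
  weights:
  - 0.0
  - 8.5
  - 17.0
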