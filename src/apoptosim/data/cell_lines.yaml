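parental:
  fields:
    bax_total: 48.0
    bcl2_total: 545.0
    bid_total: 52.0
    bik_ss: 50.0
    label: parental
    tbid0: 1.0
  kind: cell_spec
src:
  fields:
    bax_total: 100.0
    bcl2_total: 600.0
    bid_total: 40.0
    bik_ss: 9.2
    label: src
    tbid0: 1.0
  kind: cell_spec
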