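parental:
  fields:
    k_deg: 1.0
    k_m: 20.0
    k_syn: 0.1388888888888889
    k_ubi: 0.002777777777777778
    v_max: 0.0
  kind: bik_params
src:
  fields:
    k_deg: 1.0
    k_m: 20.0
    k_syn: 0.1388888888888889
    k_ubi: 0.002777777777777778
    v_max: 0.3597101449275362
  kind: bik_params
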