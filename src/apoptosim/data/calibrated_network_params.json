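{
  "note": "Calibrated network parameters: penalized least squares on the four endpoint percentages under the trajectory constraint suite, evolution-strategy minimization in log space (3 restarts), produced by analysis/03_calibrate_network.py.",
  "cost": 2.1057988417473723,
  "params": {
    "k_act": 0.005,
    "k_bik_bcl2": 0.000105,
    "k_trunc": 0.004659077815855734,
    "k_tbid_bcl2": 8.7e-05,
    "k_disp": 0.0491474462137397,
    "kcat_bax": 0.048864594242400514,
    "km_bax": 179.29201246939385,
    "k_dim": 0.0002239863018654215,
    "k_auto": 0.019021531731508886,
    "k_bax_bcl2": 9.547325936734113e-06,
    "k_back": 0.005280930718657878,
    "gamma": 10.0,
    "death_rate": 0.017692036573293546,
    "bax_star": 13.0
  }
}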