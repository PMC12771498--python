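{
  "label": "B",
  "rows": [
    {"structure": "ctv_psv", "metric_kind": "v_dose_rel", "level": 40.0, "direction": "target_coverage", "optimal": 95.0, "mandatory": 90.0, "marginal": 85.0, "can_be_unacceptable": true},
    {"structure": "ptv_psv", "metric_kind": "v_dose_rel", "level": 36.25, "direction": "target_coverage", "optimal": 95.0, "mandatory": 90.0, "marginal": 85.0, "can_be_unacceptable": true},
    {"structure": "ptv_psv", "metric_kind": "d_percent", "level": 98.0, "direction": "target_coverage", "optimal": 34.4, "mandatory": 32.38, "marginal": null, "can_be_unacceptable": true},
    {"structure": "bladder", "metric_kind": "v_dose_abs", "level": 37.0, "direction": "oar_sparing", "optimal": 5.0, "mandatory": 10.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "bladder", "metric_kind": "v_dose_rel", "level": 18.1, "direction": "oar_sparing", "optimal": null, "mandatory": 40.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "rectum", "metric_kind": "v_dose_abs", "level": 36.0, "direction": "oar_sparing", "optimal": 1.0, "mandatory": 3.04, "marginal": null, "can_be_unacceptable": true},
    {"structure": "rectum", "metric_kind": "v_dose_rel", "level": 29.0, "direction": "oar_sparing", "optimal": null, "mandatory": 20.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "rectum", "metric_kind": "v_dose_rel", "level": 18.1, "direction": "oar_sparing", "optimal": null, "mandatory": 50.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "bowel", "metric_kind": "v_dose_abs", "level": 30.0, "direction": "oar_sparing", "optimal": null, "mandatory": 1.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "bowel", "metric_kind": "v_dose_abs", "level": 18.1, "direction": "oar_sparing", "optimal": null, "mandatory": 5.0, "marginal": null, "can_be_unacceptable": true},
    {"structure": "urethra", "metric_kind": "v_dose_rel", "level": 42.0, "direction": "oar_sparing", "optimal": 50.0, "mandatory": 100.0, "marginal": null, "can_be_unacceptable": false}
  ]
}
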