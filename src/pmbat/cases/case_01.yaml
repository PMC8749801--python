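case: 1
n_arrays: 13
angular_separation_deg: 15
ctc_mm: 4.0
ptv_diameter_mm: 20
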