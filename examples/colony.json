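{
  "type": "circle",
  "centre": {"lat": 51.45, "lon": 3.7},
  "radius_m": 500.0
}
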