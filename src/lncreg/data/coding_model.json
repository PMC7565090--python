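{
 "version": "1",
 "features": [
  "fickett",
  "orf_len_nt",
  "orf_coverage",
  "orf_integrity",
  "pI"
 ],
 "means": [
  0.5392885000000002,
  484.81125,
  0.4918849174083082,
  1.0,
  9.885459056845644
 ],
 "scales": [
  0.09425717700923368,
  332.707327276448,
  0.28054736441241784,
  1.0,
  1.6199073466465108
 ],
 "weights": [
  -0.49884947574944166,
  0.9508141928614926,
  9.705492466038876,
  0.0,
  0.18928655477404963
 ],
 "intercept": 0.3455288618413169
}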