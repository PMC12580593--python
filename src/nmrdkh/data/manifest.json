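{
  "table2_geometry.tsv": "cbccf293a51e9ae8f49e63e99e6c4c0e84a4a39063d36da85b30270fb1c2c9f9",
  "table3_shifts.tsv": "9c88e505b631ea78aeec13e63c97727aff6f6b76788515a72e2043147dfe5b7c",
  "table4_external.tsv": "406eb109b50411987129bca9ffe6d774fb2c0e61e3d3ef1f6759347a47bc9e5e",
  "ti_channels.tsv": "b67f4eee01250c6dd267e0d096249823f53de455d097182dcc01ec8c40c78553"
}
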