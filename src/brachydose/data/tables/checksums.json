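{
 "alongaway_ch12.csv": "a65b2fa9586f35dce492adddc4f0ac3d7fe773fdc05323defb7ddc5056a9d8af",
 "alongaway_ch3.csv": "d69887120ba48e19f801733023ed624d026f71b07a8718a950aa75da6d665e8f",
 "anisotropy_ch12_F.csv": "4195b301e48ce7a42835d3f6e62cd601171b4c61459b4aa3c25e10554d448514",
 "anisotropy_ch12_phian.csv": "96257dfe0dcbf306b0eebbb358ee3d40b2e966a23e7b8cab921b4c595d01651c",
 "anisotropy_ch3_F.csv": "14eb48c7eae54ad1714abc73cd1d9d1c99eb26368df161c1b1bbc033ffa55ab3",
 "anisotropy_ch3_phian.csv": "427510b61033c8e4d203e3dc7506939fdc1a508e5fd9aca4ef18bab60243eda7",
 "lambda_comparison.csv": "da59d9b3ea28d37966b49aa832423986c64777be0cb2dbc9f51391da13e0054e",
 "radial_dose.csv": "b3741136b468695d225560e1d0303dc2f3b88b384546eebc194924857b1fa086"
}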