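{
 "description": "trabecular generator calibration: measured Tb.Th/Tb.S (um) over (BV/TV %, correlation length um)",
 "anisotropy": 0.5,
 "voxel_size_um": 25.0,
 "grid_shape": [
  64,
  32,
  32
 ],
 "n_reps": 4,
 "bvtv_grid": [
  40.0,
  45.0,
  50.0,
  55.0,
  60.0
 ],
 "corr_grid_um": [
  350.0,
  425.0,
  500.0,
  575.0,
  650.0,
  725.0
 ],
 "tbth_um": [
  [
   118.77680512506177,
   145.29992767580913,
   181.15468409348216,
   196.64263267089927,
   225.4648814231544,
   234.4077886012068
  ],
  [
   129.39431008777456,
   156.02177370928362,
   199.2455803553242,
   215.69961010341365,
   249.96558968147127,
   257.16062605476964
  ],
  [
   139.79840335608233,
   166.93394588170602,
   216.80815905902298,
   230.5369970757856,
   281.48740759873385,
   296.5904024027684
  ],
  [
   154.1012721523479,
   182.54997642101094,
   236.84810327159803,
   253.47578868698886,
   310.8802102408363,
   344.8898499913796
  ],
  [
   167.65821955392906,
   194.71120787675108,
   258.2161550149773,
   269.6814044382895,
   341.0693682139107,
   390.58009606854876
  ]
 ],
 "tbs_um": [
  [
   168.06448353287846,
   191.85515081755227,
   235.74959774360983,
   264.87511456165697,
   324.17315002014544,
   340.13950961270166
  ],
  [
   157.94573540999252,
   178.82692602767824,
   220.32701803700456,
   249.01259359418552,
   294.24597196029924,
   331.2146623709548
  ],
  [
   147.82070411597508,
   167.83559517900886,
   207.6341148601113,
   231.53352930996917,
   276.72245094247165,
   324.93842138499497
  ],
  [
   138.23774163033028,
   157.77229530512238,
   194.68464225473969,
   218.4206499190585,
   262.5393334831424,
   317.4799385189504
  ],
  [
   129.31606551997706,
   147.1764439164809,
   178.76690908585618,
   201.9724478331101,
   252.11081395428457,
   303.2068044666486
  ]
 ]
}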