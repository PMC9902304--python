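# South Africans of European descent: published per-sex means/SDs (mm);
# truncation bounds reuse the pooled ranges.
variables: [maxh, maxb, maxt, haf, mafb, lafb]
n_male: 50
n_female: 50
seed: 0
population: SAED
per_sex_params:
  M:
    maxh: {mean: 43.6, sd: 3.1, min: 32.49, max: 51.0}
    maxb: {mean: 45.3, sd: 3.3, min: 34.84, max: 52.0}
    maxt: {mean: 20.4, sd: 1.8, min: 15.7, max: 25.4}
    haf:  {mean: 30.8, sd: 2.6, min: 23.3, max: 37.0}
    mafb: {mean: 20.5, sd: 1.8, min: 14.9, max: 24.0}
    lafb: {mean: 28.1, sd: 2.7, min: 20.8, max: 38.0}
  F:
    maxh: {mean: 38.7, sd: 3.1, min: 31.0, max: 52.0}
    maxb: {mean: 40.3, sd: 3.3, min: 31.73, max: 51.0}
    maxt: {mean: 18.4, sd: 1.8, min: 14.5, max: 24.0}
    haf:  {mean: 27.6, sd: 3.1, min: 22.0, max: 39.0}
    mafb: {mean: 18.2, sd: 2.2, min: 12.3, max: 24.92}
    lafb: {mean: 25.0, sd: 2.5, min: 16.92, max: 32.0}
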