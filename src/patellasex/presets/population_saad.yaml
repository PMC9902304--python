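# South Africans of African descent: published per-sex means/SDs (mm);
# truncation bounds reuse the pooled ranges.
variables: [maxh, maxb, maxt, haf, mafb, lafb]
n_male: 50
n_female: 50
seed: 0
population: SAAD
per_sex_params:
  M:
    maxh: {mean: 41.2, sd: 3.1, min: 32.49, max: 51.0}
    maxb: {mean: 43.3, sd: 2.5, min: 34.84, max: 52.0}
    maxt: {mean: 20.6, sd: 1.4, min: 15.7, max: 25.4}
    haf:  {mean: 29.6, sd: 3.0, min: 23.3, max: 37.0}
    mafb: {mean: 18.4, sd: 1.9, min: 14.9, max: 24.0}
    lafb: {mean: 25.3, sd: 2.1, min: 20.8, max: 38.0}
  F:
    maxh: {mean: 36.5, sd: 2.2, min: 31.0, max: 52.0}
    maxb: {mean: 39.0, sd: 2.9, min: 31.73, max: 51.0}
    maxt: {mean: 18.2, sd: 1.7, min: 14.5, max: 24.0}
    haf:  {mean: 27.9, sd: 2.7, min: 22.0, max: 39.0}
    mafb: {mean: 16.3, sd: 1.6, min: 12.3, max: 24.92}
    lafb: {mean: 22.9, sd: 2.1, min: 16.92, max: 32.0}
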