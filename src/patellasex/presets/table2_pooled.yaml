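# Pooled study-sample generative parameters (mm): per-sex mean, SD and range
# of the six patella measurements, 130 individuals per sex. The correlation
# matrix is omitted here; the package default (max r = 0.81, maxb-lafb) is
# attached at load time and may be overridden.
variables: [maxh, maxb, maxt, haf, mafb, lafb]
n_male: 130
n_female: 130
seed: 0
population: null
per_sex_params:
  M:
    maxh: {mean: 42.07, sd: 3.14, min: 32.49, max: 51.0}
    maxb: {mean: 43.77, sd: 3.28, min: 34.84, max: 52.0}
    maxt: {mean: 20.38, sd: 1.62, min: 15.7, max: 25.4}
    haf:  {mean: 30.26, sd: 2.65, min: 23.3, max: 37.0}
    mafb: {mean: 19.70, sd: 2.02, min: 14.9, max: 24.0}
    lafb: {mean: 26.34, sd: 2.70, min: 20.8, max: 38.0}
  F:
    maxh: {mean: 37.25, sd: 2.83, min: 31.0, max: 52.0}
    maxb: {mean: 38.85, sd: 3.23, min: 31.73, max: 51.0}
    maxt: {mean: 18.13, sd: 1.75, min: 14.5, max: 24.0}
    haf:  {mean: 27.42, sd: 2.80, min: 22.0, max: 39.0}
    mafb: {mean: 17.44, sd: 2.23, min: 12.3, max: 24.92}
    lafb: {mean: 23.40, sd: 2.60, min: 16.92, max: 32.0}
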