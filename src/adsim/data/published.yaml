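# Published reference figures for the full-scale plant study used by the
# reporting module: plant validation measurements, modelled baselines, and
# the per-reactor simulation summaries for the alternative configurations.
# flux in Nm3/d, ch4 in % (dry basis), relative errors / changes in %.
validation:
  1: {experiment_flux: 12114.80, experiment_ch4: 54.06, model_flux: 11916.36, model_ch4: 55.36,
      printed_error_flux: 1.64, printed_error_ch4: 2.41}
  2: {experiment_flux: 12468.80, experiment_ch4: 54.16, model_flux: 12052.70, model_ch4: 55.34,
      printed_error_flux: 3.34, printed_error_ch4: 2.18}
  3: {experiment_flux: 11878.00, experiment_ch4: 54.30, model_flux: 11786.09, model_ch4: 56.42,
      printed_error_flux: 0.77, printed_error_ch4: 3.90}
  4: {experiment_flux: 12392.26, experiment_ch4: 54.07, model_flux: 11908.66, model_ch4: 56.36,
      printed_error_flux: 3.90, printed_error_ch4: 4.25}
alternatives:
  ahpd:
    1:
      R1: {flux: 7430.42, ch4: 79.30}
      R2: {flux: 3702.05, ch4: 19.56}
      total: {flux: 11132.47, ch4: 59.43}
    2:
      R1: {flux: 7623.87, ch4: 78.79}
      R2: {flux: 3688.94, ch4: 19.27}
      total: {flux: 11312.81, ch4: 59.38}
    3:
      R1: {flux: 7220.36, ch4: 82.13}
      R2: {flux: 3626.50, ch4: 19.57}
      total: {flux: 10846.85, ch4: 61.21}
    4:
      R1: {flux: 7378.81, ch4: 81.66}
      R2: {flux: 3626.04, ch4: 19.29}
      total: {flux: 11004.86, ch4: 61.11}
  tpad:
    1:
      R1: {flux: 10719.03, ch4: 50.26}
      R2: {flux: 2279.89, ch4: 53.21}
      total: {flux: 12998.92, ch4: 50.78}
    2:
      R1: {flux: 10830.00, ch4: 50.25}
      R2: {flux: 2314.17, ch4: 53.17}
      total: {flux: 13144.17, ch4: 50.76}
    3:
      R1: {flux: 10978.98, ch4: 51.02}
      R2: {flux: 1936.95, ch4: 54.43}
      total: {flux: 12915.92, ch4: 51.53}
    4:
      R1: {flux: 11074.63, ch4: 50.99}
      R2: {flux: 1971.15, ch4: 54.35}
      total: {flux: 13045.78, ch4: 51.50}
comparison:
  # printed relative changes vs the modelled classical baseline [%]
  ahpd:
    1: {flux: -6.58, ch4: 7.35}
    2: {flux: -6.14, ch4: 7.30}
    3: {flux: -7.97, ch4: 8.50}
    4: {flux: -7.59, ch4: 8.42}
  tpad:
    1: {flux: 9.08, ch4: -8.28}
    2: {flux: 9.06, ch4: -8.27}
    3: {flux: 9.59, ch4: -8.66}
    4: {flux: 9.55, ch4: -8.63}
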