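# Default synthetic rheumatic/autoimmune cohort configuration.
#
# Marginals (ranges, means/stds, positivity splits, per-column missing
# fractions) and class sizes follow the published cohort description.
# The class-conditional shift profiles are INVENTED: the published
# statistics are marginal only, so per-class offsets were chosen from the
# clinical meaning of each marker (rheumatoid factor / anti-CCP in RA,
# HLA-B27 in AS and ReA, anti-Ro/La in Sjogren's, anti-dsDNA/anti-Sm with
# complement consumption in SLE, seronegative inflammation in PA, quiet
# markers in healthy controls).  Numeric shifts are re-centered at
# generation time so cohort-level marginals keep their configured means.
seed: 0
features:
  - {name: Age,        kind: numeric, lo: 20,     hi: 80,     mean: 29.905, sd: 17.649, missing_rate: 0.0}
  - {name: Gender,     kind: binary,  p_positive: 0.509,  missing_rate: 0.0}
  - {name: ESR,        kind: numeric, lo: 0.0001, hi: 49.99,  mean: 24.698, sd: 14.38,  missing_rate: 0.09}
  - {name: CRP,        kind: numeric, lo: 0.1018, hi: 29.99,  mean: 13.299, sd: 10.37,  missing_rate: 0.20}
  - {name: RF,         kind: numeric, lo: 0.0043, hi: 39.99,  mean: 19.691, sd: 11.51,  missing_rate: 0.11}
  - {name: Anti-CCP,   kind: numeric, lo: 0.0002, hi: 39.99,  mean: 19.755, sd: 11.58,  missing_rate: 0.27}
  - {name: HLA-B27,    kind: binary,  p_positive: 0.6125, missing_rate: 0.16}
  - {name: ANA,        kind: binary,  p_positive: 0.6349, missing_rate: 0.31}
  - {name: Anti-Ro,    kind: binary,  p_positive: 0.5776, missing_rate: 0.24}
  - {name: Anti-La,    kind: binary,  p_positive: 0.5907, missing_rate: 0.25}
  - {name: Anti-dsDNA, kind: binary,  p_positive: 0.5538, missing_rate: 0.39}
  - {name: Anti-Sm,    kind: binary,  p_positive: 0.5421, missing_rate: 0.43}
  - {name: C3,         kind: numeric, lo: 50,     hi: 205.94, mean: 132.43, sd: 36.28,  missing_rate: 0.14}
  - {name: C4,         kind: numeric, lo: 5,      hi: 74.98,  mean: 38.80,  sd: 20.06,  missing_rate: 0.17}
classes:
  - label: RA
    n: 2848
    shifts: {ESR: 8.0, CRP: 4.0, RF: 10.0, Anti-CCP: 10.0, ANA: 0.65, HLA-B27: 0.45, Anti-Ro: 0.45}
  - label: AS
    n: 2127
    shifts: {ESR: 9.0, CRP: 3.0, RF: -8.0, Anti-CCP: -10.0, HLA-B27: 0.92, ANA: 0.40, Anti-Ro: 0.35, Anti-La: 0.35}
  - label: SS
    n: 1852
    shifts: {ESR: 4.0, CRP: 1.0, RF: -2.0, Anti-CCP: -6.0, Anti-Ro: 0.92, Anti-La: 0.88, ANA: 0.80}
  - label: PA
    n: 1783
    shifts: {ESR: 3.0, CRP: 6.0, RF: -9.0, Anti-CCP: -11.0, HLA-B27: 0.55, ANA: 0.35, Anti-Ro: 0.30, Anti-La: 0.30, Anti-dsDNA: 0.25, Anti-Sm: 0.25}
  - label: N
    n: 1604
    shifts: {ESR: -12.0, CRP: -7.0, RF: -10.0, Anti-CCP: -12.0, C3: 8.0, C4: 2.0, HLA-B27: 0.30, ANA: 0.15, Anti-Ro: 0.18, Anti-La: 0.18, Anti-dsDNA: 0.12, Anti-Sm: 0.12}
  - label: SLE
    n: 1355
    shifts: {ESR: 5.0, CRP: 2.0, RF: -4.0, Anti-CCP: -8.0, C3: -45.0, C4: -14.0, Anti-dsDNA: 0.92, Anti-Sm: 0.85, ANA: 0.92}
  - label: ReA
    n: 516
    shifts: {ESR: 4.0, CRP: 8.0, RF: -8.0, Anti-CCP: -10.0, HLA-B27: 0.85, ANA: 0.40, Anti-Ro: 0.30, Anti-La: 0.30}
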