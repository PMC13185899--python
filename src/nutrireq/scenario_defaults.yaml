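# Scenario presets for the synthetic flock-week generator, version 1.
#
# `targets` carries the published phase-specific Req95 point estimates and
# single-neuron model RMSEs (used as noise SDs) for each nutrient, and the
# per-phase sample sizes, from the commercial Ross 308 field study the
# generator emulates.  dLys noise SDs reuse the dMet values (the dMet model
# performance was reported as nearly identical to dLys).
#
# `phases.*.asymptote/plateau` and `geometry` are ASSUMED: response ceilings
# (chicks/hen/week) and curve placement are not published anywhere, so these
# are realistic values chosen once — mid-production output highest, early
# lowest — with the curve midpoint and uniform intake design range expressed
# as fractions of the target requirement so the design spans the full bend
# of every curve.
version: 1
phases:
  early: {n: 515,  age: [26, 32], asymptote: 4.2, plateau: 0.8}
  mid:   {n: 1471, age: [33, 50], asymptote: 5.6, plateau: 2.0}
  late:  {n: 699,  age: [51, 62], asymptote: 4.6, plateau: 1.2}
geometry: {x_mid_frac: 0.95, x_lo_frac: 0.85, x_hi_frac: 1.05}
targets:
  me:
    units: kcal/d
    req95:    {early: 453.4, mid: 448.9, late: 448.3}
    noise_sd: {early: 0.41,  mid: 0.12,  late: 0.20}
  dlys:
    units: g/d
    req95:    {early: 0.95,  mid: 1.03,  late: 0.89}
    noise_sd: {early: 0.41,  mid: 0.20,  late: 0.21}  # assumed = dMet
  dmet:
    units: g/d
    req95:    {early: 0.65,  mid: 0.68,  late: 0.59}
    noise_sd: {early: 0.41,  mid: 0.20,  late: 0.21}
  dthr:
    units: g/d
    req95:    {early: 0.77,  mid: 0.80,  late: 0.69}
    noise_sd: {early: 0.408, mid: 0.212, late: 0.206}
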