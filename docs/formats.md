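# Table formats

All tables are tab-delimited UTF-8 text with a single header row. Offsets
are signed and powers unsigned, both in Hz; delays in seconds; rates in
s⁻¹; shifts in ppm. Written files use `%.10g` floats and round-trip
through their paired readers to equal in-memory values.

## Decay table (`spinex simulate` output, `spinex fitdecay` input)

| column            | unit | notes                                          |
|-------------------|------|------------------------------------------------|
| residue           | –    | residue label, e.g. `G174`                     |
| power_hz          | Hz   | spin-lock power ω_SL/2π, > 0                   |
| offset_hz         | Hz   | carrier offset Ω/2π of the major state, signed |
| delay_s           | s    | relaxation delay, ≥ 0; grid must include 0     |
| intensity         | a.u. | peak intensity                                 |
| intensity_sigma   | a.u. | optional per-point uncertainty                 |

Rows group into one decay curve per (residue, power_hz, offset_hz).
Duplicate (residue, condition, delay) rows are rejected with the offending
line number.

## R₁ρ table (`spinex fitdecay` output, `spinex fitrd` input)

| column    | unit | notes                                  |
|-----------|------|----------------------------------------|
| residue   | –    |                                        |
| power_hz  | Hz   |                                        |
| offset_hz | Hz   | signed                                 |
| r1rho     | s⁻¹  | fitted monoexponential rate            |
| sigma     | s⁻¹  | Monte-Carlo uncertainty                |
| i0        | a.u. | fitted initial intensity               |

## SHAPE table (`spinex shapediff` input/output)

| column     | unit | notes                                              |
|------------|------|----------------------------------------------------|
| position   | –    | 1-based nucleotide index                           |
| reactivity | –    | raw or normalized reactivity                       |
| sem        | –    | standard error (empty/nan for raw replicates)      |
| flags      | –    | comma-joined: `reference_3prime`, `control_5prime_loop`, `rt_stop_artifact` |
| condition  | –    | condition label                                    |
| replicate  | –    | integer; keeps same-condition replicates separate  |

Differential output adds `delta`, `sigma`, `caveat_rt_stop` and the two
condition labels.

## Context-ellipse table (`spinex classify --reference`)

Columns: `context`, `base_type` (G or U), `mean_h_ppm`, `sd_h_ppm`,
`mean_n_ppm`, `sd_n_ppm`. Ellipse membership means normalized distance
≤ 1 at 2 s.d. semi-axes.

## Fit report (`spinex fitrd` output)

YAML document with `tool_version`, `shared` (p_minor, k_ex ± sigma),
`per_residue` (r1, r2, dw_ppm ± sigma per label), `chi2`, `n_points`,
`n_free_params`, `reduced_chi2`, `flags`, `seed_used` and a rendered text
`table`. Re-readable via `spinex.io.read_fit_report`.
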