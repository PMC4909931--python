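# spinex

Two-state chemical-exchange analysis of ¹⁵N R₁ρ relaxation-dispersion data
for low-populated RNA excited states, with companion tools for SHAPE
differential-reactivity analysis and imino chemical-shift interpretation.

## What problem this solves

RNA folding intermediates are often invisible to conventional NMR: they are
populated at only a few percent and exchange with the observable ground
state on the millisecond timescale. Spin-lock (R₁ρ) relaxation-dispersion
experiments detect them anyway, because exchange between states with
different chemical shifts adds a measurable, lock-power-dependent
contribution to the rotating-frame relaxation rate. `spinex` implements the
complete analysis chain for the two-state case, as used to characterize the
secondary-structure switch in the P5abc subdomain of the *Tetrahymena*
group I intron:

1. **Decay fitting** — per-residue peak intensity vs relaxation delay →
   monoexponential R₁ρ with Monte-Carlo errors (50 iterations).
2. **Global two-state fitting** — on- and off-resonance R₁ρ profiles fitted
   to the Laguerre closed form of two-site exchange, weighted 1/σ², with
   the exchange parameters (p_B, k_ex) shared across residues and
   per-residue (R₁, R₂, Δω); Monte-Carlo parameter errors; an F-test screen
   separating flat from dispersive profiles.
3. **Bloch–McConnell simulation** — the numerically exact 6×6 two-state
   forward model, used to validate the closed form and to generate
   synthetic data.
4. **Thermodynamics** — populations → free-energy ladders
   (ΔG = −RT ln(p/(1−p))), microscopic rates (k₁ = p_B·k_ex), and
   folding-equilibrium predictions for state-stabilizing mutants.
5. **SHAPE analysis** — replicate aggregation (s.e.m.), normalization to a
   3′ single-stranded reference, a 5′-hairpin internal control, and
   differential-reactivity maps with propagated errors.
6. **Chemical-shift context mapping** — ellipse-based classification of
   imino (¹H, ¹⁵N) shifts into base-pair contexts and consistency scoring
   of fitted Δω against proposed base-pairing transitions.

A synthetic-data module generates every input the pipeline needs (condition
designs, decay tables, SHAPE replicates) with known ground truth, so the
whole chain is testable end to end without any experimental data.

## The model

For a spin exchanging between a major state A (population p_A) and a minor
state B (p_B = 1 − p_A) with ¹⁵N shift difference Δω = ω_B − ω_A (rad/s),
under a spin lock of strength ω_SL applied at offset Ω from the A
resonance, the rotating-frame relaxation rate is approximated by the
Laguerre form of asymmetric two-site exchange:

```
R1ρ = R1 cos²θ + R2 sin²θ +
      sin²θ · pA pB Δω² kex /
      [ ωA² ωB² / ωeff²  +  kex²
        − sin²θ pA pB Δω² (1 + 2 kex² (pA ωA² + pB ωB²) / (ωA² ωB² + ωeff² kex²)) ]
```

with ω_A² = Ω_A² + ω_SL², ω_B² = Ω_B² + ω_SL², Ω̄ = p_A Ω_A + p_B Ω_B,
ω_eff² = Ω̄² + ω_SL² and θ = arctan(ω_SL/Ω̄). Its accuracy is pinned
against the exact Bloch–McConnell generator (eigenvalue rate of the 6×6
evolution matrix) at the ≤2% level across the exchange regime studied
here; the test suite also documents where the approximation degrades
(100 Hz off-resonance locks combined with p_B ≳ 3% in slow exchange).

## Worked example

Free-energy arithmetic from state populations (native state ~8%, excited
state ~1%, 10 °C):

```
$ spinex thermo --p-nat 0.08 --p-es 0.01
dG(Nat) = +1.374 kcal/mol (p = 0.080)
dG(ES)  = +2.586 kcal/mol (p = 0.010)
dG(Nat-ES) = -1.211 kcal/mol
K_fold = 0.0870
K_ES,Nat = 8 (ratio mode)
K_ES,Nat = 8.609 (exact mode)
```

The native state is ~1.4 kcal/mol above the alternative ground state and
the excited state ~2.6 kcal/mol, so the excited-state → native transition
is downhill; a mutation that stabilizes the excited state is predicted to
fold with K ≈ 8 instead of the wild-type 0.09.

End-to-end parameter recovery on synthetic data (5 reporter residues,
standard condition design, 2% intensity noise):

```python
from spinex.pipeline import simulate_and_fit

truth, res = simulate_and_fit("tP5abc_noMg", seed=7)
# pB  = 3.01 +/- 0.18 %      (truth 2.9 %)
# kex = 394 +/- 30 s-1       (truth 423 s-1)
# G174: dw = +4.18 +/- 0.07 ppm   (truth +4.3)
# G176: dw = -2.05 +/- 0.07 ppm   (truth -2.0)
# reduced chi2 = 1.25
```

The same chain is available from the shell: `spinex simulate` →
`spinex fitdecay` → `spinex fitrd`, each stage reading and writing
tab-delimited tables (see `docs/formats.md`).

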