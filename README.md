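# respsim

A nonlinear lumped-parameter simulator of respiratory mechanics in the
**extremely preterm infant** (~1 kg, < 28 weeks gestation), built for
computational physiologists and neonatology researchers studying why
non-invasive respiratory support fails in this population. Its core is a
breath-by-breath model of **progressive lung volume loss** (atelectasis):
the floppy, undermineralized chest wall of the preterm infant cannot hold
airspaces open, unrecruited alveoli raise the pressure cost of the next
breath, and tidal breathing degrades — slowly, then suddenly — until it
fails. The simulator reproduces that trajectory and quantifies how chest
wall stiffness, laryngeal braking (grunting) and CPAP delay it.

## The model

Four ODE states — airway flow V̇ [L/s], collapsible-airway volume V_c
[ml], lung elastic recoil P_el [cm H2O] and a Kelvin–Voigt viscoelastic
pressure P_ve [cm H2O] — evolve per breath under a sinusoidal muscle
driver P_mus = A_mus·cos(2πft) − A_mus:

```
dV̇/dt   = (P_ao − P_u − R_u·V̇)/I_u          R_u = R_u,m + K_u|V̇|   (Rohrer)
dV_c/dt = V̇ − V̇_A                           R_c = K_c(V_c,max/V_c)²
dP_el/dt = V̇_A / C_A(P_el)                   R_s = R_s,d·e^(K_s·(V_A−RV)/VC) + R_s,m
dP_ve/dt = (V̇_A − P_ve/R_ve)/C_ve
```

with nonlinear compliance curves: a sigmoid collapsible airway
V_c(P_tm), a **softplus chest wall** V_cw = RV + b_w·ln(1 + e^(P_cw/d_w))
(near-infinite compliance at positive recoil — the infant chest), and a
recruitment-weighted lung curve

```
V_A = VC·(1 − e^(−k·P_el)) · F_rec(P_el) + RV,
F_rec = α + (γ − α)/(1 + e^(−(P_el − c_F)/d_F)),   F_rec(0) = β.
```

Breath to breath, alveoli left unrecruited at end-inspiration force the
open ones to over-expand (radius ∝ volume^⅓); the resulting rise in
required distending pressure multiplies the recruitment parameters c_F
and d_F, shifting the compliance curve right each breath until tidal
volume has lost 90 % of its initial 6 ml ("failure"). Interventions:
chest-wall stiffening (d_w 0.48 → 2.4), a tenfold expiratory R_u rise
(grunting), and CPAP (P_ao 0 → 5 cm H2O) triggered at 10/5/3 %
recruitment loss.

## Worked example

```python
import respsim as r

# resting equilibrium: floppy vs stiff chest wall
for d_w in (0.48, 2.4):
    eq = r.compute_frc(r.RespiratoryParameters(d_w=d_w), r.RecruitmentState())
    print(f"d_w={d_w}: FRC={eq.FRC:.2f} ml, P_el={eq.P_el_at_FRC:.3f} cm H2O")

# untreated progressive volume loss, high chest-wall compliance
res = r.run_simulation(r.SCENARIO_REGISTRY["S3"])
print(f"failure at breath {res.failure_breath}: TTF={res.TTF_hours:.3f} h")
```

prints

```
d_w=0.48: FRC=24.84 ml, P_el=0.871 cm H2O
d_w=2.4: FRC=28.24 ml, P_el=2.038 cm H2O
failure at breath 488: TTF=0.136 h
```

The stiff chest wall rests ~3.4 ml higher — and that reserve is decisive
dynamically: the same untreated simulation under low chest-wall
compliance (`"S1"`) breathes for 3.33 h before failing, ~25× longer than
the floppy-chest 0.136 h. Earlier CPAP strictly extends survival
(`S11`/`S13`/`S14`: 0.150 → 0.221 → 0.416 h) and laryngeal braking
extends it many-fold. The `examples/` scripts walk through each
capability; a thin CLI covers the same ground from a shell:

```bash
respsim run --scenario S3 --out-dir out/   # breaths.csv, result.json
respsim stability --scenario S3 --sweep    # Jacobian eigenvalue report
respsim list-scenarios
```

Scenarios `S1`–`S14` reproduce the published simulation grid
({none, braking, CPAP} × {high, low C_w} × {0 %, 10 % permanent
closure}); custom YAML files can override any field.

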