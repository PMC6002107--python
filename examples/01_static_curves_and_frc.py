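"""Static compliance curves and the resting lung volume (FRC).

Builds the lung, chest-wall and collapsible-airway pressure-volume curves
for both chest-wall conditions and locates the resting equilibrium where
lung recoil balances chest recoil.  A floppier chest wall (high
compliance, d_w = 0.48) rests at a lower volume than a stiffer one
(d_w = 2.4): the infant's undermineralized ribcage costs functional
residual capacity.
"""

import respsim as r

rec = r.RecruitmentState()
for label, d_w in [("high C_w (floppy chest)", 0.48),
                   ("low C_w (stiff chest)", 2.4)]:
    params = r.RespiratoryParameters(d_w=d_w)
    eq = r.compute_frc(params, rec)
    print(f"{label}: FRC = {eq.FRC:.2f} ml at P_el = "
          f"{eq.P_el_at_FRC:.3f} cm H2O "
          f"(chest wall holds {eq.V_cw_at_FRC:.2f} ml incl. "
          f"{eq.V_c_at_FRC:.2f} ml dead space)")

# FRC is the alveolar volume where the recoil pressures cancel; the ~3 ml
# gap between conditions is the volume reserve a stiffer chest wall buys.
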