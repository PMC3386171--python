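# Reference parameter set for the mitochondrial quality-control simulator.
#
# Time unit: minutes.  Rates are per minute.  The quality ladder has
# n_states levels; state 0 is fully dysfunctional (non-fusogenic), state
# n_states-1 the highest quality.  The fusion-fission base rate corresponds
# to one fusion-fission cycle per 20 minutes; quality decay and mitophagy
# act on time scales orders of magnitude slower (protein turnover with
# half-lives of days).  Selectivity Hill midpoints sit at mid-ladder.
n_states: 50
dt: 0.1
t_end: 20000.0
output_every: 50.0
equilibrium_tolerance: 1.0e-9
damage_mode: none
seed: 0
processes:
  fusion_fission:
    schedule: {type: hill, v_init: 0.05, v_final: 0.05, hill_exponent: 0, half_time: 1.0}
    selectivity: {s_low: 0.0, s_high: 1.0, hill_coefficient: 24.5, hill_exponent: 2, zero_at_floor: true}
  decay:
    schedule: {type: hill, v_init: 1.0e-4, v_final: 1.0e-4, hill_exponent: 0, half_time: 1.0}
    selectivity: {s_low: 1.0, s_high: 0.2, hill_coefficient: 24.5, hill_exponent: 2, zero_at_floor: false}
  mitophagy:
    schedule: {type: hill, v_init: 1.0e-4, v_final: 1.0e-4, hill_exponent: 0, half_time: 1.0}
    selectivity: {s_low: 1.0, s_high: 0.2, hill_coefficient: 24.5, hill_exponent: 2, zero_at_floor: false}
  renewal:
    selectivity: {s_low: 0.0, s_high: 1.0, hill_coefficient: 24.5, hill_exponent: 2, zero_at_floor: true}
  random_damage:
    # ramps in from zero, reaching its plateau on the multi-thousand-minute
    # "aging" time scale; each event moves up to r_max of one state's mass
    schedule: {type: hill, v_init: 0.0, v_final: 0.05, hill_exponent: 2, half_time: 2000.0}
    extras: {r_max: 0.5}
  infectious_damage:
    # occurrence rate of damaging fusion-fission events; capped by the
    # fusion-fission rate at run time.  Each damaged event loses at most
    # eps_max quality units per output.  The plateau is calibrated so the
    # quality-destruction flux matches the random-damage default above.
    # rd_limit / id_max drive the coupled mode in which random damage
    # triggers infectious damage.
    schedule: {type: hill, v_init: 0.0, v_final: 0.005, hill_exponent: 2, half_time: 2000.0}
    extras: {rd_limit: 0.025, id_max: 0.005, eps_max: 1}
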