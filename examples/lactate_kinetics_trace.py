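"""Quantify lactate-transport kinetics from a simulated BCECF pH trace.

Simulates a lactate perfusion experiment (resting pH 7.4, 60 nM proton
influx amplitude, tau 20 s), then recovers the kinetic metrics from the
noisy trace and compares them with the generator's analytic truth.
"""

from cenckit import TraceConfig, lactate_kinetics, simulate_ph_trace

config = TraceConfig(seed=2)
trace = simulate_ph_trace(config)
metrics = lactate_kinetics(trace.time_s, trace.ph,
                           t_on=config.t_on, t_off=config.t_off)

truth = trace.ground_truth
print(f"resting [H] pre-lactate : {metrics.resting_h_pre:7.2f} nM "
      f"(true {truth['resting_h_pre']:.2f})")
print(f"max d[H]/dt             : {metrics.max_dh_dt:7.2f} nM/s "
      f"(true {truth['max_dh_dt']:.2f})")
print(f"influx excursion d[H]   : {metrics.delta_h_influx:7.2f} nM "
      f"(true {truth['delta_h_influx']:.2f})")
print(f"resting shift post-pre  : {metrics.delta_h_resting:7.2f} nM "
      f"(true {truth['delta_h_resting']:.2f})")
print(f"extremum direction      : {metrics.extremum_direction} "
      "(protons flow in with lactate, so [H] rises)")
# The derivative is a central difference on the sampled [H]; its ~3-5%
# downward bias at 1 Hz sampling is the price of not fitting a model.
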