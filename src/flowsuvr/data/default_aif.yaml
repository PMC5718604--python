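# Shipped input-function surrogate: tri-exponential bolus with linear rise,
# Hill-type parent-fraction decline, constant whole-blood/plasma ratio.
# Calibrated once against the built-in average-HC baseline kinetics so that
# the simulated late-window SUVRs and flow-effect directions are plausible
# for an amyloid-negative cohort; fixed thereafter. This is a declared
# synthetic stand-in for unavailable measured arterial data.
A1: 600.0    # kBq/mL/min, linear-rise amplitude
A2: 2.0      # kBq/mL, fast washout amplitude
A3: 150.0    # kBq/mL, slow washout amplitude
lam1: 4.0    # 1/min
lam2: 1.5    # 1/min
lam3: 0.003  # 1/min
delay: 0.5   # min, injection-to-arrival delay
t50: 3.0     # min, parent-fraction half-time
hill: 2.65   # Hill slope of the parent-fraction decline
r_bp: 0.85   # whole-blood to total-plasma ratio
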