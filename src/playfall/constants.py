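"""Physical constants shared across the package."""

#: Gravitational acceleration, m/s^2.  9.81 keeps the printed height/velocity
#: pair 1.59 m <-> 5.59 m/s consistent to three significant figures and is
#: used both for free-fall kinematics and for the g unit conversion.
GRAVITY = 9.81

#: ASTM-style low-pass cutoff applied to the resultant linear acceleration
#: before HIC computation, Hz.
HIC_FILTER_HZ = 2077.5

#: Cutoff applied to head centre-of-gravity kinematics (linear/angular
#: acceleration, angular velocity) before peak extraction, Hz.
KINEMATICS_FILTER_HZ = 180.0

#: HIC window caps, seconds.
HIC15_WINDOW = 0.015
HIC36_WINDOW = 0.036

#: Performance criterion of the impact-attenuation standard.
HIC_LIMIT = 1000.0

#: First-principal Green-Lagrange strain associated with 50% risk of mild
#: traumatic brain injury.
MTBI_STRAIN_THRESHOLD = 0.3
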