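# Schema of the tfdmi YAML run configuration.
# Every key is optional; defaults shown.  Flags given on the command line
# override file values.  Give either (Ne, kappa_F) or scaled_size, not both.

ell: 10                 # int >= 1: binding-site length (positions)
delta_eps: 3.0          # float > 0: energy per mismatch, kBT
delta_eps_ns: 1.5       # float >= 0: nonspecific energy per site, kBT
r_star_override: null   # int in [0, ell] or null: force the viability threshold
Ne: null                # float >= 1: effective population size (with kappa_F)
kappa_F: null           # float >= 0: fitness curvature (with Ne)
scaled_size: 0.04       # float >= 0: 4*Ne*kappa_F; Ne defaults to 1000
mu0: 1.0                # float > 0: per-position mutation rate (time unit mu0*t)
M: 1.0e5                # float >= 1: interacting gene pairs per genome
ancestor_mode: equilibrium   # equilibrium | fixed-r | user
dmi_mode: first_passage      # first_passage | instantaneous
rate_form: full              # full | scaled  (Kimura fixation-rate form)
n_replicates: 1000      # int >= 1: replicate pairs per experiment
t_max: 500.0            # float > 0: horizon in mu0*t
grid_min: 1.0e-4        # float > 0: first point of the log time grid
points_per_decade: 50   # int: log-grid density
seed: 0                 # int: master seed; fixes every output bit
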