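# Example vaspol run configuration.
#
# NOTE on provenance: the Carreau-Yasuda parameters below are generic
# literature values for whole blood (zero-shear and infinite-shear
# viscosities in Pa*s, relaxation time in s).  They are editable inputs,
# not constants measured on any particular retina data set.  Likewise
# the boundary pressures are placeholders on the scale of central-retina
# arteriovenous differences; supply values appropriate to your sample.

pixel_size_um = 1.0
min_spur_factor = 2.0

[rheology]
kind = "carreau_yasuda"   # or "newtonian" (then only mu is used)
mu0 = 1.6e-2
mu_inf = 3.5e-3
lam = 8.2
a = 0.64
n = 0.2128
mu = 3.5e-3

[solver]
tol = 1e-6
max_iter = 100
relaxation = 0.5

[analysis]
tolerance_deg = 45.0      # against-flow window half-width
threshold_frac = 0.60     # sensor-curve crossing level
n_bins = 8                # WSS quantile bins for the sensor analysis
polar_bins = 24
max_distance_um = 25.0    # cell-to-centerline matching radius
sample_spacing_um = 2.0
seed = 0

# one [[boundary_conditions]] block per inlet/outlet, referencing node
# ids of the built network (degree-1 terminals)
[[boundary_conditions]]
node = 1
pressure = 100.0
role = "inlet"

[[boundary_conditions]]
node = 0
pressure = 0.0
role = "outlet"
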