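# Ridge-invasion demo: an E-W mountain ridge (1200 m) along lat = 0.5 with a
# single N-S valley gap at lon = 0.25.  Terrain above 1000 m is hostile
# (carrying capacity < 0), so the only route from the NE colony to the south
# is west along the ridge and through the gap.

[domain]
roi = [0.0, 0.0, 1.0, 1.0]
buffer_deg = 0.2

[terrain]
source = "synthetic"
resolution_arcsec = 60
seed = 7

[terrain.ridge]
amplitude = 1200.0   # metres
lat = 0.5
sigma = 0.08         # ridge half-width, degrees
gap_lon = 0.25
gap_width = 0.12

[mesh]
background_size = 0.05      # degrees
roi_size = 0.025
gradient_threshold = 4000.0 # m/deg
gradient_passes = 1

[coefficients]
nu = 5e-4    # deg^2 / yr
alpha = 1.0

[initial]
center = [0.75, 0.85]
radius = 0.12
amplitude = 10.0

[time]
dt_months = 0.1
horizon_years = 10.0
snapshot_stride = 24
arrival_threshold = 1.0

[probes]
north = [0.6, 0.75]
gap = [0.25, 0.5]
south = [0.6, 0.2]

[uq]
level = 1
n_samples = 2000
n_mc = 100000
seed = 0

[[uq.inputs]]
name = "nu"
family = "normal"
mean = 5e-4
std = 1.2e-4

[[uq.inputs]]
name = "alpha"
family = "uniform"
low = 0.0
high = 2.0
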