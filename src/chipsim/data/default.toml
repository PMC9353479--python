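# chipsim default configuration (version 0.1.0)
#
# These values are the shipped calibration of the transport model; every
# scenario in the package runs at these defaults unless overridden.

[conditions]
temperature_k = 310.15      # incubator temperature, K
viscosity_pa_s = 8.9e-4     # dynamic viscosity of water near 37 C, Pa*s

[geometry]
medium_channel_width_um = 1000.0
gel_channel_width_um = 1000.0
height_um = 200.0           # photoresist mold thickness
length_mm = 6.0             # culture length of a channel
reservoir_volume_ul = 120.0 # daily refresh volume held in each medium channel's ports
dx_um = 5.0                 # finite-volume resolution across the channels
gel_cell_density_per_ml = 1.0e6  # final density after 10x dilution into collagen
bec_suspension_per_ml = 8.0e5    # endothelial seeding suspension
bec_seed_volume_ul = 60.0        # suspension volume per outer channel

[gel]
volume_fraction = 0.125     # collagen fiber volume fraction (phi)
fiber_radius_nm = 200.0     # type 1 collagen fiber radius
permeability_m2 = 1e-13     # Darcy permeability, typical for 2 mg/mL collagen
collagen_density_mg_ml = 2.0

[flow]
tau_s = 200.0               # lumped drainage time constant (5% equilibrium at 600 s)
initial_head_ul = 60.0      # reservoir liquid-volume difference driving the flow
reservoir_area_m2 = 1.65e-6 # punched port area; sets the initial head pressure

[collagenase]
load_mg_ml = 1.0            # enzyme concentration loaded into the communication channels
molecular_weight_da = 100000.0  # midpoint of the 63-130 kDa collagenase range
duration_s = 1800.0
d_medium_m2_s = 8.4e-11     # collagenase diffusivity in medium channels
d_gel_m2_s = 8.35e-11       # collagenase diffusivity in collagen channels
reach_threshold_fraction = 0.01  # "reached channel #2" = 1% of the initial load
activation_min_mg_ml = 0.5  # lower edge of the enzymatically activating window
activation_max_mg_ml = 2.5  # upper edge of the activating window
pbs_reservoir_ul = 120.0    # cold PBS loaded into the outer reservoirs
collagenase_reservoir_ul = 60.0  # enzyme volume loaded into the communication reservoirs
sample_interval_s = 10.0

[cytokine]
duration_h = 24.0
solutes = ["serpin E1", "IL-8"]
sample_interval_s = 300.0
arrival_threshold_fraction = 0.01  # "reached the tumor channel" = 1% of the source side
separation_mm = 0.9         # insert floor to well floor in the Transwell comparator
well_area_cm2 = 1.9         # 24-well footprint used for the 1-D column
tumor_zone_um = 200.0       # bottom slab of the Transwell column read out as "tumor"
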