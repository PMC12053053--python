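[chamber]
lateral_size_x = 10 mm
lateral_size_y = 10 mm
fluid_height = 1.1 mm
fluid_density = 1000 kg/m^3
fluid_sound_speed = 1480 m/s
top_impedance = 13 MPa*s/m
side_impedance = 17 MPa*s/m

[transducer]
rows = 3
cols = 3
unit_size = 2 mm
pitch = 2.4 mm
center_displacement = 1.7 nm/V
edge_displacement = 1.2 nm/V
corner_displacement = 1.0 nm/V
epoxy_displacement = 0.6 nm/V

[drive]
voltage = 60 V
frequency = 660 kHz

[particle]
diameter = 150 um
density = 1099 kg/m^3
compressibility = 4.0e-10 1/Pa
viscosity = 1 mPa*s
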