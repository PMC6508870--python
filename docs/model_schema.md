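# Model description file

`neckdyn.io.save_model` / `load_model` serialise a `SpecimenModel` as JSON.
All quantities are SI; the `units` block in every file restates this.

```
{
  "units": { ... },                  # fixed SI declaration
  "segments": [                      # ordered cranial -> caudal
    {
      "name": "C2",                  # unique segment name
      "mass": 0.078,                 # kg
      "inertia": [[...3x3...]],      # kg m^2, about the COM, segment frame
      "com_offset": [0,0,0],         # m, COM in the segment frame
      "marker_points": {             # m, marker attachments, segment frame
        "POT_1": [x, y, z], ...
      },
      "rest_position": [x, y, z],    # m, global pose at the undeflected
      "rest_orientation": [[3x3]]    #    reference configuration
    }, ...
  ],
  "joints": [                        # ordered C2-C3 .. C5-C6
    {
      "caudal_segment": "C3",
      "cranial_segment": "C2",
      "origin_in_caudal": [x,y,z],   # m, joint origin in the caudal frame
      "orientation_in_caudal": [[3x3]],  # caudal frame -> joint frame
      "rest_offset": [x,y,z]         # m, joint origin in the cranial frame
    }, ...                           #    at zero deflection
  ],
  "bushings": [                      # parallel to joints
    {
      "k_trans": [kx, ky, kz],       # N/m   (x shear, y axial, z lateral)
      "b_trans": [bx, by, bz],       # Ns/m
      "k_rot":  [..],                # Nm/rad
      "b_rot":  [..]                 # Nms/rad
    }, ...
  ],
  "constraints": {                   # per-segment mobility
    "C2": "axial_translation_only",  # one of: fixed,
    "C6": "fixed", ...               # axial_translation_only, free
  },
  "gravity": [0, -9.81, 0],          # m/s^2
  "include_gravity": true,
  "preload": {
    "spring_force_N": 102.0,         # constant-force springs
    "plate_weight_N": 50.0,          # impact-plate weight
    "plate_mass_kg": 5.10            # rides with the drive segment
  }
}
```

Coordinate convention: global right-handed frame, x anterior, y superior,
z = x cross y.  Joint frames: y normal to the caudal superior surface,
x anterior projected onto it.

Marker files are TRC (positions in mm per the format convention); force
files are CSV with header `time_s,force_N`, uniformly sampled, compressive
force positive.
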