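pathway,scenario,median,ci_low_mag,ci_high_mag
extended_rotation,ambitious,-5.63,-5.40,-5.84
extended_rotation,moderate,-3.46,-3.32,-3.60
extended_rotation,limited,-4.02,-3.88,-4.16
agriculture,ambitious,-1.40,-1.28,-1.52
agriculture,moderate,-0.83,-0.75,-0.90
agriculture,limited,-0.10,-0.0863,-0.1074
avoided_forest_conversion,ambitious,-1.16,-1.05,-1.27
avoided_forest_conversion,moderate,-0.58,-0.52,-0.64
avoided_forest_conversion,limited,-0.12,-0.11,-0.13
riparian_restoration,ambitious,-0.29,-0.29,-0.30
riparian_restoration,moderate,-0.07,-0.07,-0.08
riparian_restoration,limited,-0.01,-0.01,-0.01
avoided_sagebrush_conversion,ambitious,-0.13,-0.11,-0.14
avoided_sagebrush_conversion,moderate,-0.03,-0.02,-0.02
avoided_sagebrush_conversion,limited,-0.01,-0.01,-0.01
tidal_wetland_restoration,ambitious,-0.11,-0.10,-0.12
tidal_wetland_restoration,moderate,-0.06,-0.05,-0.06
tidal_wetland_restoration,limited,-0.03,-0.03,-0.03
replanting_after_wildfire,ambitious,-0.11,-0.09,-0.13
replanting_after_wildfire,moderate,-0.06,-0.05,-0.06
replanting_after_wildfire,limited,-0.03,-0.03,-0.04
total,ambitious,-8.84,-8.56,-9.10
total,moderate,-5.10,-4.92,-5.25
total,limited,-4.32,-4.17,-4.46
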