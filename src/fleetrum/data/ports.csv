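port_name,lon,lat,country
Mazatlan,-106.4,23.2,MEX
Manta,-80.7,-0.95,ECU
Panama_City,-79.5,8.9,PAN
Chimbote,-78.6,-9.1,PER
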