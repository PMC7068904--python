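run_id,combination,varus_deg,slope_deg,rotation_deg,peak_pressure_mpa
1,A1B1C1,0.0,1.0,3.0,18.99
2,A1B2C2,0.0,2.0,4.0,17.10
3,A1B3C3,0.0,3.0,5.0,20.46
4,A2B1C2,3.0,1.0,4.0,22.18
5,A2B2C3,3.0,2.0,5.0,24.10
6,A2B3C1,3.0,3.0,3.0,21.26
7,A3B1C3,-3.0,1.0,5.0,22.68
8,A3B2C1,-3.0,2.0,3.0,29.73
9,A3B3C2,-3.0,3.0,4.0,24.25
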