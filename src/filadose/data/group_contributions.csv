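# Hoftyzer-van Krevelen molar attraction constants with Fedors molar-volume
# increments (standard polymer-handbook values).  Units: F_d, F_p in
# MPa^1/2 cm^3/mol; E_h in J/mol; V in cm^3/mol.  Groups whose Fedors volume
# increment is non-positive (>CH-, >C<) are intentionally not listed; supply
# molar_volume_override for molecules that need them.
group,F_d,F_p,E_h,V
CH3,420,0,0,33.5
CH2,270,0,0,16.1
CH2=,400,0,0,28.5
CH=,200,0,0,13.5
phenyl,1430,110,0,71.4
phenylene,1270,110,0,52.4
OH,210,500,20000,10.0
O,100,400,3000,3.8
CO,290,770,2000,10.8
COO,390,490,7000,18.0
COOH,530,420,10000,28.5
CN,430,1100,2500,24.0
NH2,280,0,8400,19.2
NH,160,210,3100,4.5
NO2,500,1070,1500,24.0
Cl,450,550,400,24.0
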