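# 4-acetaminophen (paracetamol) Raman shift standard band positions, cm^-1.
# Reference data transcribed from the ASTM E1840 Raman shift standard;
# editable — replace with your own calibrant positions if needed.
# column: reference_wavenumber_cm-1
390.9
465.1
504.0
651.6
710.8
797.2
834.5
857.9
968.7
1105.5
1168.5
1236.8
1278.5
1323.9
1371.5
1561.5
1648.4
2931.1
3064.6
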