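name,shape,dimension_mm
EBT3 ROI,circular,0.25
W1 PSD,circular,0.5
IBA SFD diode,circular,0.3
IBA Razor diode,circular,0.3
PTW 60008 Diode P,circular,0.6
PTW 60012 Diode E,circular,0.6
PTW 60018 Diode SRS,circular,0.6
SN EDGE Detector,square,0.8
PTW 60019 mD,circular,1.1
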