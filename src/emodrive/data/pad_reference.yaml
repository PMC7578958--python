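# Converted-scale (0-100 per axis) PAD reference coordinates of the eight
# driving emotions; original-cube coordinates are score/50 - 1.
anger: [24.5, 79.5, 62.5]
surprise: [57.5, 64.0, 50.75]
fear: [18.0, 80.0, 28.5]
anxiety: [38.0, 54.0, 42.0]
helplessness: [35.0, 55.0, 30.0]
contempt: [30.0, 54.0, 63.0]
relief: [60.0, 35.0, 70.0]
pleasure: [70.0, 60.0, 55.0]
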