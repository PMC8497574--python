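000000000000000000000000000000000000000000000000000000000000
000000000000000000000000000000000000000000000000000000000000
000000000000000000000000000000000000000000000000000000000000
000000000000111111110000000000000011111111110000000000000000
111111111111111111111111000000111111111111111111000000000000
111111111111111111111111111111111111111111111111000001111000
111111111111111111111111111111111111111111111111000001111000
111111111111111111111111111111111111111111111111000001111000
111111111111111111111111111111111111111111111111000001111000
111111111111111111111111111111111111111111111111110011111000
111111111111111111111111111111111111111111111111111111111000
111111111111111111111111111111111111111111111111111111111000
111111111111111111111111111111111111111111111111111111111100
111111111111111111111111111111111111111111111111111111111100
110000001111111111111111111111111111111111111111111111111100
110000001111111111111111111111111111111111111111111111111100
110000001111111111111111111111000000001111111111111111111100
110000001111111111111111111000000000000001111111111111111100
110000001111111111111111111000000000000001111111111111111100
110000001111111111111111111000000000000000001111111111111100
110000001111111111111111111000000000000000001111111111111100
110000001111111111111111111000000000000000001111111111111100
110000001111111111111111111000000000000000001111111111111110
110000001111111111111111111111111111111110001111111111111110
111000111111111111111111111111111111111111111111000011111110
111000111111111111111111111111111111111111111111000011111110
111000111111111111111111111111111111111111111111000011111110
111000111111111111111111111111111111111111111111000011111110
111111111111111111111111111111111111111111110000000000000010
111111111111111111111111111111111111111111110000000000000010
111111111111111111111111111111111100000000000000000000000000
111111111111111111111111111111111100000000000000000000000000
111111111111111111111111000000011100000000000000000000000000
111111111111111111111111000000011100000000000000000000000000
111111111111111111111111000000011100000000000000000000000000
111111111111111111111111000000011100000000000000000000000000
111111111111111111111111000000011100000000001111111111111100
111111111111111111111111000000011111111111111111111111111100
111111111111111111111111111000111111111111111111111111111100
111111111111111111111111111000111111111111111111111111111100
111111111111111111111111111000111111111111111111111111111100
111111111111111111111111111111111111111111111111111111111100
111111111111111111111111111111111111111111111111111111111100
111111111111111111111111111111111111111111111111111111111100
111111111111111111111111111111111111111111111111111111000000
111111111111111111111111111111111111111111111111111111000000
000000000000000000001111111111111111111111111111111111000000
000000000000000000000000000000000000000011111111111111000000
000000000000000000000000000000000000000011111111111111000000
000000000000000000000000000000000000000011111111111111000000
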