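# Four-component multi-valued example network.
# a and c are Boolean; b and d have three levels (0, 1, 2).
automaton a 2
automaton b 3
automaton c 2
automaton d 3
trans a 0 -> 1 when c:1
trans a 1 -> 0 when b:2
trans b 0 -> 1 when d:0
trans b 0 -> 2 when a:1, c:1
trans b 1 -> 2 when d:1
trans b 2 -> 0 when c:0
trans c 0 -> 1 when a:1, b:0
trans c 1 -> 0 when d:2
trans d 0 -> 1 when b:2
trans d 0 -> 2 when a:0, b:1
trans d 1 -> 0 when a:1
trans d 2 -> 0 when c:0
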