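isolate_id,lipase,protease,chitinase
AAUB03,+,+++,++
AAUB28,+,+++,+
AAUB29,+,++,+
AAUB19,+,++,+
AAUB90,+,++,+
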