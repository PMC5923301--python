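sample_id	toxins_present
CLP1930	42
CLP1936	45
CLP1959	56
CLP1961	53
CLP1972	45
CLP1831	64
CLP1835	66
CLP2136	64
CLP2142	69
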