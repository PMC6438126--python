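# Functional sites of the T. thermophilus 70S ribosome (author numbering).
# Selector prefix is a chain ID or an annotation molecule name.
sites:
  - name: DC
    members: ["16S:530", "16S:1492", "16S:1493"]
  - name: PTC
    members: ["23S:2451", "23S:2452", "23S:2506", "23S:2585", "23S:2602"]
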