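# Intersubunit bridges of the T. thermophilus 70S ribosome (author numbering).
# 30S-side selectors address the 16S rRNA or small-subunit proteins; 50S-side
# selectors the 23S rRNA or large-subunit proteins.  Editable config, not code.
sites:
  - name: B1b
    members: ["S13:68", "L5:146"]
  - name: B2a/d
    members: ["16S:1495", "23S:1919", "23S:1920"]
  - name: B2b
    members: ["16S:783", "23S:1836"]
  - name: B2c
    members: ["16S:770", "16S:771", "16S:899", "23S:1832", "23S:1833"]
  - name: B3
    members: ["16S:1483", "16S:1418", "23S:1947", "23S:1959", "23S:1948", "23S:1958"]
  - name: B5
    members: ["16S:1475", "23S:1689", "23S:1700"]
  - name: B7a
    members: ["16S:702", "23S:1848"]
  - name: B7b
    members: ["16S:773", "L2:202"]
  - name: B8
    members: ["16S:340", "L14:96"]
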