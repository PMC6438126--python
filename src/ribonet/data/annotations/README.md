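# Chain annotation templates

`2j00-2j01.yaml` is a worked template for one 70S complex split across two
deposited entries. For the other study pairs (4juw-4jux, 2wdk-2wdl,
3f1e-3f1f) copy the template and adjust:

- address each chain as `"<entry>:<chain>"`; the merge step resolves these
  through the recorded chain_map even when the two entries reuse chain IDs;
- categories: `RRNA_16S`, `RRNA_23S`, `RRNA_5S`, `R_PROTEIN`, `TRNA`,
  `MRNA`, `FACTOR` (use `FACTOR` for EF-G in 4jux and RF2 in 3f1f), or the
  string `exclude`;
- `molecule` names are what site/bridge selectors match (`16S:530`,
  `L14:96`, ...), so keep the rRNA names `16S`/`23S`/`5S` and protein names
  `S2`...`L36` as in the bridge definitions.

Always check assignments against the coordinate files you actually
downloaded: depositions are occasionally re-versioned with different chain
naming.
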