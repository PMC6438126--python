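# Chain annotation template for the pretranslocation 70S complex deposited as
# 2j00 (30S half) + 2j01 (50S half).  Keys of the form "<entry>:<chain>" are
# resolved through the merged structure's chain_map, so collision remapping
# between the two entries is handled automatically.  Chain assignments follow
# the depositions' conventional naming; verify against the files you
# downloaded before use (entries are occasionally re-versioned).
chains:
  # 2j00 (30S subunit + ligands)
  "2j00:A": {category: RRNA_16S, molecule: 16S}
  "2j00:B": {category: R_PROTEIN, molecule: S2}
  "2j00:C": {category: R_PROTEIN, molecule: S3}
  "2j00:D": {category: R_PROTEIN, molecule: S4}
  "2j00:E": {category: R_PROTEIN, molecule: S5}
  "2j00:F": {category: R_PROTEIN, molecule: S6}
  "2j00:G": {category: R_PROTEIN, molecule: S7}
  "2j00:H": {category: R_PROTEIN, molecule: S8}
  "2j00:I": {category: R_PROTEIN, molecule: S9}
  "2j00:J": {category: R_PROTEIN, molecule: S10}
  "2j00:K": {category: R_PROTEIN, molecule: S11}
  "2j00:L": {category: R_PROTEIN, molecule: S12}
  "2j00:M": {category: R_PROTEIN, molecule: S13}
  "2j00:N": {category: R_PROTEIN, molecule: S14}
  "2j00:O": {category: R_PROTEIN, molecule: S15}
  "2j00:P": {category: R_PROTEIN, molecule: S16}
  "2j00:Q": {category: R_PROTEIN, molecule: S17}
  "2j00:R": {category: R_PROTEIN, molecule: S18}
  "2j00:S": {category: R_PROTEIN, molecule: S19}
  "2j00:T": {category: R_PROTEIN, molecule: S20}
  "2j00:U": {category: R_PROTEIN, molecule: THX}
  "2j00:V": {category: MRNA, molecule: mRNA}
  "2j00:W": {category: TRNA, molecule: A-tRNA}
  "2j00:X": {category: TRNA, molecule: P-tRNA}
  "2j00:Y": {category: TRNA, molecule: E-tRNA}
  # 2j01 (50S subunit)
  "2j01:A": {category: RRNA_23S, molecule: 23S}
  "2j01:B": {category: RRNA_5S, molecule: 5S}
  "2j01:D": {category: R_PROTEIN, molecule: L2}
  "2j01:E": {category: R_PROTEIN, molecule: L3}
  "2j01:F": {category: R_PROTEIN, molecule: L4}
  "2j01:G": {category: R_PROTEIN, molecule: L5}
  "2j01:H": {category: R_PROTEIN, molecule: L6}
  "2j01:J": {category: R_PROTEIN, molecule: L9}
  "2j01:K": {category: R_PROTEIN, molecule: L11}
  "2j01:L": {category: R_PROTEIN, molecule: L13}
  "2j01:M": {category: R_PROTEIN, molecule: L14}
  "2j01:N": {category: R_PROTEIN, molecule: L15}
  "2j01:O": {category: R_PROTEIN, molecule: L16}
  "2j01:P": {category: R_PROTEIN, molecule: L17}
  "2j01:Q": {category: R_PROTEIN, molecule: L18}
  "2j01:R": {category: R_PROTEIN, molecule: L19}
  "2j01:S": {category: R_PROTEIN, molecule: L20}
  "2j01:T": {category: R_PROTEIN, molecule: L21}
  "2j01:U": {category: R_PROTEIN, molecule: L22}
  "2j01:V": {category: R_PROTEIN, molecule: L23}
  "2j01:W": {category: R_PROTEIN, molecule: L24}
  "2j01:X": {category: R_PROTEIN, molecule: L25}
  "2j01:Y": {category: R_PROTEIN, molecule: L27}
  "2j01:Z": {category: R_PROTEIN, molecule: L28}
  "2j01:0": {category: R_PROTEIN, molecule: L29}
  "2j01:1": {category: R_PROTEIN, molecule: L30}
  "2j01:2": {category: R_PROTEIN, molecule: L31}
  "2j01:3": {category: R_PROTEIN, molecule: L32}
  "2j01:4": {category: R_PROTEIN, molecule: L33}
  "2j01:5": {category: R_PROTEIN, molecule: L34}
  "2j01:6": {category: R_PROTEIN, molecule: L35}
  "2j01:7": {category: R_PROTEIN, molecule: L36}
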