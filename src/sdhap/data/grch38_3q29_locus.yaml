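# 3q29 locus configuration (GRCh38).  Coordinates are 1-based inclusive,
# as printed in genome browsers; converted to 0-based half-open on load.
# Note: the published analysis region ends before the SDC critical region;
# the loader keeps the union envelope and flags the discrepancy.
chrom: chr3
region: [195428934, 197230596]
critical_regions:
  SDA: [195578485, 195817578]
  SDB: [195804017, 196073500]
  SDC: [197557633, 197743251]
segment_lengths:
  magenta: 26000
  blue: 5000
  yellow: 11000
  red: 4000
  maroon: 33000
  orange: 15000
  green: 124000
parent_segments:
  orange: magenta
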