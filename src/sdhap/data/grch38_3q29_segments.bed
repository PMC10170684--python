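# Synthetic reconstruction of the 3q29 segment-copy layout on GRCh38
# coordinates.  Copy counts, segment lengths, SD-block membership and the
# positions of the recurrent-CNV breakpoint cassettes follow the published
# locus description; exact copy coordinates are approximate placements
# inside the published SD-block spans, not measured annotations.
chr3	195600000	195626000	magenta	0	+
chr3	195626500	195631500	blue	0	+
chr3	195632000	195643000	yellow	0	+
chr3	195644000	195648000	red	0	+
chr3	195650000	195683000	maroon	0	+
chr3	195720000	195844000	green	0	+
chr3	195900000	195926000	magenta	0	+
chr3	195936000	195941000	blue	0	+
chr3	195942000	195957000	orange	0	+
chr3	195960000	195971000	yellow	0	+
chr3	195975000	195979000	red	0	+
chr3	195989000	195994000	blue	0	+
chr3	197600000	197626000	magenta	0	+
chr3	197636500	197641500	blue	0	+
chr3	197642000	197653000	yellow	0	+
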