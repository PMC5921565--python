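# Default track palettes. Colorblind-safe (Okabe-Ito) hues for categorical
# roles; gene models gold, transposable elements purple; small-RNA length
# classes 18-30 nt take 13 perceptually-distinct viridis samples.

[annotation]
gene = "#E69F00"                 # gold
transposable_element = "#CC79A7" # purple
other = "#999999"

[methylation]
CG = "#D55E00"      # vermillion
CHG = "#0072B2"     # blue
CHH = "#009E73"     # bluish green
CH = "#0072B2"      # animal non-CG class
unknown = "#999999"
"4mC" = "#F0E442"   # extra modification types, distinct from contexts
"5hmC" = "#56B4E9"
"6mA" = "#000000"

[coverage]
plus = "#D55E00"
minus = "#0072B2"

[density]
low = "#F7FBFF"   # near-white, density 0
high = "#08306B"  # dark blue, density 1

[smrna]
lengths = [
  "#440154", "#481F70", "#443983", "#3B528B", "#31688E", "#287C8E",
  "#21918C", "#20A486", "#35B779", "#5EC962", "#90D743", "#C8E020",
  "#FDE725",
]
min_length = 18
max_length = 30
other_length = "#999999"
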