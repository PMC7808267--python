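"""Sequence-level exploration of SMART data.

Each patient follows exactly one treatment sequence (A1, O2, A2); the
sequence summary is the natural first look at the data.  The synthetic
depression-management trial shipped with the package has 108 patients
over 8 sequences (stage-1 medication vs problem-solving therapy, binary
early response, re-randomization between the same options, outcome =
depression-score reduction at six months).
"""

from smartats import (
    codiacs_like_sim,
    make_codiacs_like,
    parse_design,
    render_plots,
    seqmeans,
)

data = make_codiacs_like()
design = parse_design(codiacs_like_sim())

table = seqmeans(data, design=design, digits=2)
print(table.to_string(index=False))
# N partitions the 108 patients; MEAN/VAR/SD are per-sequence moments of
# the outcome (variance with the n-1 denominator).

render_plots("diagram", "design_diagram.png", design=design)
render_plots("summary", "sequence_boxplots.png", data=data)
print("wrote design_diagram.png and sequence_boxplots.png")
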