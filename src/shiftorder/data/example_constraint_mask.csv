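# Example zero-mask for the CONSTRAINED pollination-syndrome scheme:
# direct transitions between the two vertebrate syndromes and the
# generalist syndrome are forbidden (shifts radiate from the ancestral
# bee state). States: 0=bee, 1=generalist, 2=nectar_vertebrate,
# 3=foodbody_vertebrate.
from_state,to_state
1,2
2,1
1,3
3,1
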