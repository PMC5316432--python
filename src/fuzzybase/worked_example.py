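"""Bundled six-base worked example (sequence ATCTCG).

The input features of six consecutive called bases, together with the
feature scores and confidence values produced by the originally trained
reference system.  The reference outputs come from systems trained on
unpublished data, so they serve as qualitative anchors (orderings,
magnitudes) rather than exact targets; the ``demo`` CLI command prints
them next to the scores of a freshly trained model.
"""

from .pipeline import BaseCallRecord

#: base, NP_called, NP_2nd, NH_called, NH_2nd, dNS_next, dNS_prev
WORKED_EXAMPLE_RECORDS = [
    BaseCallRecord("A", 0.998, 0.361, 0.889, 0.560, 0.305, 0.298),
    BaseCallRecord("T", 0.999, 0.478, 0.991, 0.421, 0.305, 0.305),
    BaseCallRecord("C", 0.794, 0.838, 0.644, 0.604, 0.281, 0.305),
    BaseCallRecord("T", 0.999, 0.721, 0.954, 0.606, 0.286, 0.281),
    BaseCallRecord("C", 0.930, 0.665, 0.696, 0.531, 0.302, 0.286),
    BaseCallRecord("G", 0.999, 0.618, 0.952, 0.485, 0.274, 0.302),
]

#: reference feature scores of the original trained system, per record
REFERENCE_NC_P = (0.824, 0.825, 0.499, 0.499, 0.612, 0.766)
REFERENCE_NC_H = (0.683, 0.767, 0.230, 0.692, 0.390, 0.741)
REFERENCE_NC_DS = (0.813, 0.813, 0.813, 0.812, 0.813, 0.813)

#: reference confidence values; the third base (C) is the row minimum
REFERENCE_NC_O = (0.653, 0.747, 0.205, 0.661, 0.364, 0.716)
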