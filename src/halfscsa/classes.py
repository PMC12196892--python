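"""Class codes shared across the package.

The segmentation works with three organ classes plus an explicit
"unclassified" state. Ties in the max-intersection classifier are broken
in favour of the rarest class first (knot, then stem, then leaf).
"""

UNCLASSIFIED = 0
LEAF = 1
STEM = 2
KNOT = 3

ORGAN_CLASSES = (LEAF, STEM, KNOT)

#: tie-break order for classification: earlier wins on exact ties
TIE_ORDER = (KNOT, STEM, LEAF)

CLASS_NAMES = {
    UNCLASSIFIED: "unclassified",
    LEAF: "leaf",
    STEM: "stem",
    KNOT: "knot",
}

NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}
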