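"""Named marker lists from the HCC seromics literature.

These are documentation constants: the pipeline never assumes their
presence in a dataset, and synthetic cohorts use neutral protein IDs.
"""

#: 19 autoantigens added to the HCC-focused array from the cancer
#: literature (alongside the proteins screened on the proteome-wide array).
LITERATURE_AUTOANTIGENS: tuple[str, ...] = (
    "CTRL", "DCAF4L2", "BIRC5", "CCNB1IP1", "GPR78", "HM13", "HSPA2",
    "IMP3", "KDM1A", "MAPK1", "RALA", "RPLP0", "SARNP", "SF3A3",
    "TSPAN13", "TUBB6", "XRCC5", "CENPF", "CDKN2A",
)

#: The published 7-autoantibody consensus panel for HCC detection.
PUBLISHED_CONSENSUS_PANEL: tuple[str, ...] = (
    "CIAPIN1", "EGFR", "MAS1", "SLC44A3", "ASAH1", "UBL7", "ZNF428",
)
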