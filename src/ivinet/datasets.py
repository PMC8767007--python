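"""Reference gene lists from the published CVD/CKD case study.

These are the printed outputs of the study's overlap and module stages,
bundled as worked-example inputs: the cross-condition up/down overlap
lists and the per-module node/edge/seed-gene bookkeeping of its dense
modules. They let the bookkeeping operations be exercised against known
totals without access to the study's (unpublished) interaction network.
"""

from __future__ import annotations

__all__ = ["CVD_CKD_UP_OVERLAP", "CVD_CKD_DOWN_OVERLAP", "CVD_CKD_MODULES"]

#: upregulated in both conditions
CVD_CKD_UP_OVERLAP: tuple[str, ...] = (
    "NPR3", "NFE2L1", "TNFSF10", "HMGB2", "GABPB2", "KDM5D", "RSRP1",
    "GPCPD1", "ZNF83", "THY1", "COX7B", "NPPB", "PDZK1IP1", "BCL6",
    "IRAK3", "GRN", "SOCS3", "CASP5", "RPS24",
)

#: downregulated in both conditions
CVD_CKD_DOWN_OVERLAP: tuple[str, ...] = (
    "BCL3", "ZRANB2", "NR1D2", "C7", "LYN", "ANXA3", "PER3", "PTP4A3",
    "RPLP0", "HSPB1", "ACTG1", "RPL13", "HCAR3", "FCGR3A", "MAP2K3",
    "MYC", "CIRBP", "AHSA2", "ATP1A1", "NPIPB3", "PNISR", "RPS2",
    "ENO1", "CNN1",
)

#: seed-containing dense modules: (module id, nodes, edges, seed genes)
CVD_CKD_MODULES: tuple[tuple[str, int, int, tuple[str, ...]], ...] = (
    ("Module 1", 133, 8061, ("RPL13", "RPLP0", "RPS2", "RPS24")),
    ("Module 5", 44, 231, ("MYC", "COX7B", "SOCS3")),
    ("Module 6", 36, 126, ("MAP2K3", "TNFSF10")),
    ("Module 7", 6, 14, ("PER3",)),
    ("Module 8", 25, 67, ("IRAK3",)),
    ("Module 9", 30, 80, ("BCL6", "HSPB1")),
    ("Module 10", 16, 38, ("ENO1",)),
    ("Module 11", 5, 10, ("ATP1A1",)),
    ("Module 13", 5, 6, ("LYN", "FCGR3A")),
    ("Module 15", 3, 3, ("NPR3", "NPPB")),
)
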