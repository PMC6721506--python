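"""Gene panels and the published 13-gene prognostic signature.

The candidate universe is a panel of 86 human tyrosine-kinase (TK) gene
symbols covering the receptor and non-receptor TK families (EPH, ERBB, FGFR,
JAK, SRC, TEC, ... families).  The published prognostic signature is a
13-gene subset of the panel; its coefficients were fit on patient data that
is not redistributable, so the fixture carries only the gene identities and
the direction of each gene's univariate disease-free-survival association
(+1: higher expression, shorter DFS; -1: higher expression, longer DFS).

The three hormone/growth-factor receptor genes used for transcriptional
receptor-status calling (ESR1, PGR, ERBB2) are kept out of the candidate
panel: they define the analysis subgroup, not the signature search space.
"""

from __future__ import annotations

#: 86 tyrosine-kinase gene symbols — the candidate universe for signature search.
TK_PANEL: tuple[str, ...] = (
    "ABL1", "ABL2", "ALK", "AXL", "BLK", "BMX", "BTK", "CSF1R", "CSK",
    "DDR1", "DDR2", "EGFR",
    "EPHA1", "EPHA2", "EPHA3", "EPHA4", "EPHA5", "EPHA6", "EPHA7", "EPHA8",
    "EPHA10", "EPHB1", "EPHB2", "EPHB3", "EPHB4", "EPHB6",
    "ERBB3", "ERBB4", "FER", "FES",
    "FGFR1", "FGFR2", "FGFR3", "FGFR4", "FGR",
    "FLT1", "FLT3", "FLT4", "FRK", "FYN", "HCK",
    "IGF1R", "INSR", "INSRR", "ITK",
    "JAK1", "JAK2", "JAK3", "KDR", "KIT", "LCK", "LMTK2", "LTK", "LYN",
    "MATK", "MERTK", "MET", "MST1R", "MUSK",
    "NTRK1", "NTRK2", "NTRK3",
    "PDGFRA", "PDGFRB", "PTK2", "PTK2B", "PTK6", "PTK7",
    "RET", "ROR1", "ROR2", "ROS1", "RYK",
    "SRC", "SRMS", "SYK", "TEC", "TEK", "TIE1",
    "TNK1", "TNK2", "TXK", "TYK2", "TYRO3", "YES1", "ZAP70",
)

#: The 13-gene signature with the published univariate DFS effect direction.
#: +1 = expression associated with shorter DFS, -1 = with longer DFS.
PUBLISHED_SIGNATURE: dict[str, int] = {
    "ALK": +1,
    "FLT1": +1,
    "EPHA4": +1,
    "EPHA7": +1,
    "EPHB4": +1,
    "EPHA1": -1,
    "EPHB6": -1,
    "SRC": -1,
    "FYN": -1,
    "ITK": -1,
    "ZAP70": -1,
    "ERBB4": -1,
    "PTK2B": -1,
}

#: Genes used for transcriptional receptor-status calling, in (ER, PR, ERBB2) order.
RECEPTOR_GENES: tuple[str, str, str] = ("ESR1", "PGR", "ERBB2")

assert len(TK_PANEL) == 86, "panel must contain exactly 86 symbols"
assert len(set(TK_PANEL)) == 86
assert set(PUBLISHED_SIGNATURE) <= set(TK_PANEL)
assert not set(RECEPTOR_GENES) & set(TK_PANEL)
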