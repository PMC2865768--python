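"""Reference values from the original colon-cancer microarray study.

The study analyzed 62 colon biopsies (40 tumor, 22 normal) on 2000 genes and
identified 18 well-annotated genes with high tumor/normal discrimination —
10 downregulated in tumor (suppressors) and 8 upregulated (activators).  The
raw expression matrix is not bundled; what is shipped here are the published
connection-degree tables of the two network variants, which serve as inputs
for the degree-asymmetry statistics.  Two of the published labels ("myosin",
"IPL1") are ambiguous gene identifiers and are stored verbatim.

Degree entries are ``(total_degree, indegree)`` per sweep α, exactly as
printed (the Type 2 KCNMB1 average indegree is printed as 9 although the
per-α values average to 10.8; the printed value is kept).
"""

from __future__ import annotations

from .analysis import DegreeRecord

__all__ = [
    "IDENTIFIED_GENES",
    "GENE_ANNOTATIONS",
    "TYPE1_ALPHAS",
    "TYPE2_ALPHAS",
    "TYPE1_DEGREES",
    "TYPE2_DEGREES",
    "degree_records",
]

DOWN_GENES = (
    "DES", "MYL9", "CSRP1", "ACTA2", "SPARCL1",
    "KCNMB1", "Mgp", "SLC2A4", "myosin", "TPM3",
)
UP_GENES = (
    "IL8", "S100A11", "HSPD1", "HNRNPA1", "DARS", "SRPK1", "IPL1", "PCBD1",
)
IDENTIFIED_GENES = DOWN_GENES + UP_GENES
GENE_ANNOTATIONS = {g: "down" for g in DOWN_GENES} | {g: "up" for g in UP_GENES}

TYPE1_ALPHAS = (1.0, 0.95, 0.9, 0.85, 0.8, 0.75, 0.7)

# Network among the 18 identified genes: (total, indegree) per alpha.
TYPE1_DEGREES = {
    "DES":     [(0, 0), (1, 1), (2, 2), (10, 5), (14, 6), (17, 8), (22, 13)],
    "MYL9":    [(0, 0), (0, 0), (2, 1), (9, 3), (12, 4), (24, 13), (27, 15)],
    "CSRP1":   [(0, 0), (1, 0), (2, 0), (10, 4), (20, 12), (23, 13), (27, 16)],
    "ACTA2":   [(0, 0), (0, 0), (4, 3), (9, 3), (12, 3), (18, 5), (27, 13)],
    "SPARCL1": [(0, 0), (1, 1), (4, 3), (10, 3), (15, 7), (20, 8), (27, 15)],
    "KCNMB1":  [(0, 0), (0, 0), (6, 3), (13, 4), (14, 4), (29, 15), (29, 15)],
    "Mgp":     [(0, 0), (0, 0), (4, 0), (11, 2), (16, 4), (26, 13), (27, 13)],
    "SLC2A4":  [(0, 0), (0, 0), (1, 0), (5, 1), (12, 2), (24, 11), (25, 11)],
    "myosin":  [(0, 0), (0, 0), (0, 0), (3, 0), (7, 3), (15, 10), (19, 14)],
    "TPM3":    [(0, 0), (1, 0), (4, 2), (13, 6), (18, 9), (22, 9), (22, 9)],
    "IL8":     [(0, 0), (0, 0), (1, 1), (3, 1), (6, 2), (21, 9), (22, 9)],
    "S100A11": [(0, 0), (1, 0), (2, 0), (14, 12), (16, 13), (21, 13), (26, 15)],
    "HSPD1":   [(0, 0), (0, 0), (0, 0), (3, 2), (7, 5), (14, 6), (15, 6)],
    "HNRNPA1": [(0, 0), (0, 0), (2, 2), (5, 3), (17, 12), (22, 13), (27, 13)],
    "DARS":    [(0, 0), (0, 0), (0, 0), (3, 1), (7, 3), (13, 5), (18, 5)],
    "SRPK1":   [(0, 0), (0, 0), (0, 0), (1, 1), (5, 3), (10, 4), (15, 5)],
    "IPL1":    [(0, 0), (0, 0), (0, 0), (13, 11), (14, 11), (20, 12), (25, 13)],
    "PCBD1":   [(0, 0), (1, 1), (2, 1), (14, 13), (17, 12), (21, 12), (26, 13)],
}

TYPE2_ALPHAS = (1.0, 0.95, 0.9, 0.85, 0.8)

# Genome-wide regulation of the identified genes: (total, indegree) per alpha.
TYPE2_DEGREES = {
    "DES":     [(0, 0), (2, 2), (4, 3), (15, 10), (33, 25)],
    "MYL9":    [(0, 0), (0, 0), (7, 6), (22, 17), (40, 33)],
    "CSRP1":   [(1, 1), (3, 2), (3, 2), (9, 5), (18, 13)],
    "ACTA2":   [(0, 0), (0, 0), (11, 10), (28, 22), (30, 22)],
    "SPARCL1": [(1, 1), (2, 2), (6, 5), (20, 13), (36, 28)],
    "KCNMB1":  [(0, 0), (0, 0), (13, 10), (24, 15), (40, 29)],
    "Mgp":     [(0, 0), (0, 0), (12, 8), (30, 21), (47, 36)],
    "SLC2A4":  [(0, 0), (0, 0), (10, 9), (27, 23), (63, 54)],
    "myosin":  [(0, 0), (0, 0), (0, 0), (3, 1), (10, 6)],
    "TPM3":    [(0, 0), (0, 0), (6, 4), (24, 18), (53, 45)],
    "IL8":     [(0, 0), (0, 0), (1, 1), (2, 1), (8, 4)],
    "S100A11": [(0, 0), (4, 3), (67, 64), (1369, 1367), (1401, 1399)],
    "HSPD1":   [(0, 0), (0, 0), (0, 0), (8, 7), (28, 27)],
    "HNRNPA1": [(0, 0), (0, 0), (6, 6), (57, 55), (1752, 1747)],
    "DARS":    [(0, 0), (0, 0), (0, 0), (7, 5), (37, 33)],
    "SRPK1":   [(0, 0), (0, 0), (2, 2), (9, 9), (22, 21)],
    "IPL1":    [(0, 0), (6, 6), (57, 57), (1772, 1770), (1787, 1785)],
    "PCBD1":   [(0, 0), (13, 13), (84, 83), (1569, 1568), (1595, 1591)],
}


def degree_records(network_type: int = 1) -> list[DegreeRecord]:
    """The published degree tables as DegreeRecord objects."""
    if network_type == 1:
        alphas, table = TYPE1_ALPHAS, TYPE1_DEGREES
    elif network_type == 2:
        alphas, table = TYPE2_ALPHAS, TYPE2_DEGREES
    else:
        raise ValueError("network_type must be 1 or 2")
    return [
        DegreeRecord(
            gene=g,
            total={a: t for a, (t, _) in zip(alphas, vals)},
            indegree={a: i for a, (_, i) in zip(alphas, vals)},
        )
        for g, vals in table.items()
    ]
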