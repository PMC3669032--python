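"""Curated reference tables from the bilateral TBI microarray study of rat
cortex 24 h after unilateral controlled cortical impact (GEO accession
GSE45997).

Three published summary tables are transcribed here because they are inputs
to — and fixed points for — the pipeline:

* ``FUNCTION_OVERLAP`` — the 14 top biological functions besides
  inflammatory response (IR), each with its unique gene count, the number
  of genes shared with the IR set, and the printed integer overlap
  percentage.
* ``DIVERGENT_COMMON_GENES`` — the 37 IR genes changed at least 2-fold on
  both sides of the brain whose hemispheric fold-ratio exceeded 1.75
  ("changed differently"), with both signed fold changes and the printed
  ratio.
* ``GOI_HIERARCHY`` — the full 114-gene interaction hierarchy: tier
  (primary/secondary/peripheral/orphan), fold-change cells as printed
  ("~" = no qualifying change on that side), cellular compartment and
  molecule type.

Note: CLEC12A's ipsilateral fold change appears as 10.92 in the divergent
table and 10.29 in the hierarchy table in the published source; each table
is transcribed as printed, and the divergent table is treated as
authoritative for ratio computations.
"""

from __future__ import annotations

from .datatypes import GeneAnnotation
from .io import parse_fold

# (function name, unique genes for function, genes overlapping IR, printed %)
FUNCTION_OVERLAP: list[tuple[str, int, int, int]] = [
    ("Cellular movement", 381, 209, 55),
    ("Cellular growth and proliferation", 583, 227, 39),
    ("Cancer", 663, 225, 34),
    ("Cellular development", 499, 208, 42),
    ("Cell death", 472, 202, 43),
    ("Neurological disease", 663, 185, 28),
    ("Genetic disorder", 1023, 267, 26),
    ("Gene expression", 441, 151, 34),
    ("Skeletal and muscular disorders", 538, 191, 36),
    ("Tissue development", 479, 203, 42),
    ("Cell cycle", 296, 111, 38),
    ("Cell morphology", 267, 133, 50),
    ("Immune cell trafficking", 231, 216, 94),
    ("Dermatological diseases & conditions", 268, 147, 55),
]

#: Pooled overlap across the 14 functions, one decimal, as published.
CUMULATIVE_OVERLAP_PERCENT = 39.3

# (symbol, fc TBI-I, fc TBI-C, printed ratio, compartment, molecule type)
DIVERGENT_COMMON_GENES: list[tuple[str, float, float, float, str, str]] = [
    ("CSF1", 3.70, 2.09, 1.77, "extracellular space", "cytokine"),
    ("SPP1", 37.91, 2.37, 15.99, "extracellular space", "cytokine"),
    ("ERAP1", 5.84, 3.05, 1.92, "extracellular space", "peptidase"),
    ("LCN2", 71.82, 3.90, 18.44, "extracellular space", "transporter"),
    ("TGFB2", -4.00, -7.97, 1.99, "extracellular space", "growth factor"),
    ("SERPINA3", 58.49, 2.51, 23.31, "extracellular space", "other"),
    ("SERPING1", 5.81, 2.03, 2.86, "extracellular space", "other"),
    ("TIMP1", 38.49, 2.10, 18.32, "extracellular space", "other"),
    ("HLA-C", 9.30, 3.66, 2.54, "plasma membrane", "transmembrane receptor"),
    ("IGSF6", 22.46, 3.27, 6.87, "plasma membrane", "transmembrane receptor"),
    ("IL13RA1", 4.53, 2.27, 1.99, "plasma membrane", "transmembrane receptor"),
    ("IL6ST", 2.31, -3.28, 7.57, "plasma membrane", "transmembrane receptor"),
    ("THBD", 3.85, 2.09, 1.84, "plasma membrane", "transmembrane receptor"),
    ("KCNN4", 3.09, -9.43, 29.12, "plasma membrane", "ion channel"),
    ("EGFR", 6.77, 2.37, 2.85, "plasma membrane", "kinase"),
    ("MGLL", -7.85, -18.15, 2.31, "plasma membrane", "enzyme"),
    ("CD44", 15.56, 2.40, 6.49, "plasma membrane", "other"),
    ("CLEC12A", 10.92, 2.15, 5.08, "plasma membrane", "other"),
    ("ITGA5", 4.83, 2.68, 1.80, "plasma membrane", "other"),
    ("SDC1", 13.68, 2.57, 5.33, "plasma membrane", "other"),
    ("LYN", 6.94, 3.78, 1.84, "cytoplasm", "kinase"),
    ("PDE4B", 5.60, 2.36, 2.37, "cytoplasm", "enzyme"),
    ("PTPN4", 4.49, 2.21, 2.03, "cytoplasm", "phosphatase"),
    ("RASA1", 2.39, -2.11, 5.04, "cytoplasm", "transporter"),
    ("HSPB1", 46.92, 2.64, 17.78, "cytoplasm", "other"),
    ("LCP1", 6.08, 2.80, 2.17, "cytoplasm", "other"),
    ("LSP1", 11.72, 2.14, 5.47, "cytoplasm", "other"),
    ("MYO1F", 4.27, 2.26, 1.89, "cytoplasm", "other"),
    ("CBL", -3.40, -6.13, 1.80, "nucleus", "transcription regulator"),
    ("CEBPD", 11.27, 2.04, 5.53, "nucleus", "transcription regulator"),
    ("DEK", -3.01, -7.35, 2.45, "nucleus", "transcription regulator"),
    ("STAT3", 4.22, -3.77, 15.91, "nucleus", "transcription regulator"),
    ("MX1", 28.18, 7.33, 3.85, "nucleus", "enzyme"),
    ("TOP2A", 2.26, -2.41, 5.44, "nucleus", "enzyme"),
    ("THRA", -2.80, -11.52, 4.12, "nucleus", "ligand-dependent nuclear receptor"),
    ("CCND1", 2.15, -2.03, 4.36, "nucleus", "other"),
    ("Slpi (includes others)", 82.91, 3.12, 26.58, "unknown", "other"),
]

#: Published breakdown of the 372 changed IR genes.
IR_CLASS_COUNTS = {
    "common-similar-up": 79,
    "common-similar-down": 30,
    "common-different": 37,
    "ipsi-unique-up": 179,
    "ipsi-unique-down": 9,
    "contra-unique-up": 10,
    "contra-unique-down": 28,
}

# (symbol, tier, fc TBI-I as printed, fc TBI-C as printed, compartment, type)
GOI_HIERARCHY: list[tuple[str, str, str, str, str, str]] = [
    ("CEBPB", "primary", "3.37", "~", "nucleus", "transcription regulator"),
    ("FOS", "primary", "2.83", "~", "nucleus", "transcription regulator"),
    ("IRF1", "primary", "2.22", "~", "nucleus", "transcription regulator"),
    ("IRF7", "primary", "2.78", "~", "nucleus", "transcription regulator"),
    ("MYC", "primary", "3.96", "~", "nucleus", "transcription regulator"),
    ("NFKB2", "primary", "2.77", "~", "nucleus", "transcription regulator"),
    ("STAT3", "primary", "4.22", "-3.77", "nucleus", "transcription regulator"),
    ("EGFR", "primary", "6.77", "2.37", "plasma membrane", "kinase"),
    ("IKBKB", "primary", "2.13", "~", "cytoplasm", "kinase"),
    ("JAK2", "primary", "2.53", "~", "cytoplasm", "kinase"),
    ("LYN", "primary", "6.94", "3.78", "cytoplasm", "kinase"),
    ("FN1", "primary", "3.97", "~", "extracellular space", "enzyme"),
    ("HSP90AA1", "primary", "~", "-4.84", "cytoplasm", "enzyme"),
    ("IL1B", "primary", "5.17", "~", "extracellular space", "cytokine"),
    ("CASP3", "primary", "2.54", "~", "cytoplasm", "peptidase"),
    ("TLR4", "primary", "2.70", "~", "plasma membrane", "transmembrane receptor"),
    ("CCND1", "primary", "2.15", "-2.03", "nucleus", "other"),
    ("CD44", "primary", "15.56", "2.40", "plasma membrane", "other"),
    ("CDKN1A", "primary", "2.68", "~", "nucleus", "other"),
    ("MYD88", "primary", "2.70", "~", "plasma membrane", "other"),
    ("ERAP1", "secondary", "5.84", "3.05", "extracellular space", "peptidase"),
    ("MMP13", "secondary", "2.26", "~", "extracellular space", "peptidase"),
    ("MMP14", "secondary", "~", "-3.03", "extracellular space", "peptidase"),
    ("MMP3", "secondary", "4.05", "~", "extracellular space", "peptidase"),
    ("MMP9", "secondary", "7.18", "~", "extracellular space", "peptidase"),
    ("PSMB8", "secondary", "3.30", "~", "cytoplasm", "peptidase"),
    ("PSMB9", "secondary", "2.32", "~", "cytoplasm", "peptidase"),
    ("ICAM1", "secondary", "2.60", "~", "plasma membrane", "transmembrane receptor"),
    ("IL6R", "secondary", "2.32", "~", "plasma membrane", "transmembrane receptor"),
    ("IL6ST", "secondary", "2.31", "-3.28", "plasma membrane", "transmembrane receptor"),
    ("TLR2", "secondary", "2.33", "~", "plasma membrane", "transmembrane receptor"),
    ("TNFRSF1A", "secondary", "3.56", "~", "plasma membrane", "transmembrane receptor"),
    ("CBL", "secondary", "-3.40", "-6.13", "nucleus", "transcription regulator"),
    ("CEBPD", "secondary", "11.27", "2.04", "nucleus", "transcription regulator"),
    ("IRF2", "secondary", "~", "2.17", "nucleus", "transcription regulator"),
    ("IRF9", "secondary", "3.26", "~", "nucleus", "transcription regulator"),
    ("CCL7", "secondary", "124.78", "~", "extracellular space", "cytokine"),
    ("CXCL10", "secondary", "~", "-3.29", "extracellular space", "cytokine"),
    ("SPP1", "secondary", "37.91", "2.37", "extracellular space", "cytokine"),
    ("AKT1", "secondary", "2.04", "~", "cytoplasm", "kinase"),
    ("BTK", "secondary", "2.29", "~", "cytoplasm", "kinase"),
    ("EIF2AK2", "secondary", "2.18", "~", "cytoplasm", "kinase"),
    ("CCR5", "secondary", "2.09", "~", "plasma membrane", "G-protein coupled receptor"),
    ("CXCR4", "secondary", "2.31", "~", "plasma membrane", "G-protein coupled receptor"),
    ("HBEGF", "secondary", "7.07", "~", "extracellular space", "growth factor"),
    ("FGF2", "secondary", "2.39", "~", "extracellular space", "growth factor"),
    ("RORA", "secondary", "2.50", "~", "nucleus", "ligand-dependent nuclear receptor"),
    ("THRA", "secondary", "-2.80", "-11.52", "nucleus", "ligand-dependent nuclear receptor"),
    ("RAC1", "secondary", "2.32", "~", "plasma membrane", "enzyme"),
    ("PTPN6", "secondary", "3.64", "~", "cytoplasm", "phosphatase"),
    ("HSPA1A/HSPA1B", "secondary", "3.14", "~", "cytoplasm", "other"),
    ("ITGA5", "secondary", "4.83", "2.68", "plasma membrane", "other"),
    ("SDC1", "secondary", "13.68", "2.57", "plasma membrane", "other"),
    ("TIMP1", "secondary", "38.49", "2.10", "extracellular space", "other"),
    ("CCL13/CCL2", "peripheral", "195.46", "~", "extracellular space", "cytokine"),
    ("CCL3L1/CCL3L3", "peripheral", "5.27", "~", "extracellular space", "cytokine"),
    ("CCL4", "peripheral", "2.16", "~", "extracellular space", "cytokine"),
    ("Ccl6", "peripheral", "10.29", "~", "extracellular space", "cytokine"),
    ("CSF1", "peripheral", "3.70", "2.09", "extracellular space", "cytokine"),
    ("CXCL13", "peripheral", "3.78", "~", "extracellular space", "cytokine"),
    ("CXCL14", "peripheral", "~", "2.13", "extracellular space", "cytokine"),
    ("CXCL9", "peripheral", "2.85", "~", "extracellular space", "cytokine"),
    ("CD14", "peripheral", "10.66", "~", "plasma membrane", "transmembrane receptor"),
    ("FCGR2B", "peripheral", "5.12", "~", "plasma membrane", "transmembrane receptor"),
    ("HLA-C", "peripheral", "9.30", "3.66", "plasma membrane", "transmembrane receptor"),
    ("HLA-DRA", "peripheral", "2.70", "~", "plasma membrane", "transmembrane receptor"),
    ("IL13RA1", "peripheral", "4.53", "2.27", "plasma membrane", "transmembrane receptor"),
    ("IL1R2", "peripheral", "37.03", "~", "plasma membrane", "transmembrane receptor"),
    ("GBP2 (includes EG:14469)", "peripheral", "9.13", "~", "cytoplasm", "enzyme"),
    ("MX1", "peripheral", "28.18", "7.33", "nucleus", "enzyme"),
    ("RALBP1", "peripheral", "2.23", "~", "cytoplasm", "enzyme"),
    ("TOP2A", "peripheral", "2.26", "-2.41", "nucleus", "enzyme"),
    ("EGR2", "peripheral", "2.27", "~", "nucleus", "transcription regulator"),
    ("NFE2L2", "peripheral", "2.45", "~", "nucleus", "transcription regulator"),
    ("ZFP36", "peripheral", "7.28", "~", "nucleus", "transcription regulator"),
    ("ABCC1", "peripheral", "~", "-3.11", "plasma membrane", "transporter"),
    ("LCN2", "peripheral", "71.82", "3.90", "extracellular space", "transporter"),
    ("RASA1", "peripheral", "2.39", "-2.11", "cytoplasm", "transporter"),
    ("NR1H2", "peripheral", "2.15", "~", "nucleus", "ligand-dependent nuclear receptor"),
    ("NR1H3", "peripheral", "2.16", "~", "nucleus", "ligand-dependent nuclear receptor"),
    ("HSPB8", "peripheral", "4.11", "~", "cytoplasm", "kinase"),
    ("RIPK3", "peripheral", "7.55", "~", "plasma membrane", "kinase"),
    ("CASP4", "peripheral", "3.05", "~", "cytoplasm", "peptidase"),
    ("DPP8", "peripheral", "~", "2.06", "cytoplasm", "peptidase"),
    ("ANGPT2", "peripheral", "2.98", "~", "extracellular space", "growth factor"),
    ("CD63", "peripheral", "2.07", "~", "plasma membrane", "other"),
    ("HSPB1", "peripheral", "46.92", "2.64", "cytoplasm", "other"),
    ("IER3", "peripheral", "2.35", "~", "cytoplasm", "other"),
    ("IFI44", "peripheral", "3.12", "~", "cytoplasm", "other"),
    ("IFITM3", "peripheral", "3.48", "~", "plasma membrane", "other"),
    ("ISG15", "peripheral", "3.53", "~", "extracellular space", "other"),
    ("NEDD9", "peripheral", "2.59", "~", "nucleus", "other"),
    ("S100A4", "peripheral", "4.73", "~", "cytoplasm", "other"),
    ("SERPINA3", "peripheral", "58.49", "2.51", "extracellular space", "other"),
    ("TNFAIP6", "peripheral", "3.02", "~", "extracellular space", "other"),
    ("MGLL", "orphan", "-7.85", "-18.15", "plasma membrane", "enzyme"),
    ("MYO9B", "orphan", "2.18", "~", "cytoplasm", "enzyme"),
    ("PAFAH1B1", "orphan", "~", "-2.86", "cytoplasm", "enzyme"),
    ("PDE4B", "orphan", "5.60", "2.36", "cytoplasm", "enzyme"),
    ("DEK", "orphan", "-3.01", "-7.35", "nucleus", "transcription regulator"),
    ("TCF12", "orphan", "2.16", "~", "nucleus", "transcription regulator"),
    ("IGSF6", "orphan", "22.46", "3.27", "plasma membrane", "transmembrane receptor"),
    ("THBD", "orphan", "3.85", "2.09", "plasma membrane", "transmembrane receptor"),
    ("TGFB2", "orphan", "-4.00", "-7.97", "extracellular space", "growth factor"),
    ("KCNN4", "orphan", "3.09", "-9.43", "plasma membrane", "ion channel"),
    ("PRSS23", "orphan", "4.05", "~", "extracellular space", "peptidase"),
    ("PTPN4", "orphan", "4.49", "2.21", "cytoplasm", "phosphatase"),
    ("CALB1", "orphan", "-2.09", "~", "cytoplasm", "other"),
    ("CLEC12A", "orphan", "10.29", "2.15", "plasma membrane", "other"),
    ("LCP1", "orphan", "6.08", "2.80", "cytoplasm", "other"),
    ("LSP1", "orphan", "11.72", "2.14", "cytoplasm", "other"),
    ("MYO1F", "orphan", "4.27", "2.26", "cytoplasm", "other"),
    ("SERPING1", "orphan", "5.81", "2.03", "extracellular space", "other"),
    ("Slpi (includes others)", "orphan", "82.91", "3.12", "unknown", "other"),
]

#: Published tier sizes (primary, secondary, peripheral, orphan).
GOI_TIER_SIZES = {"primary": 20, "secondary": 34, "peripheral": 41, "orphan": 19}


def goi_symbols() -> list[str]:
    """The 114 genes of interest, in hierarchy order."""
    return [row[0] for row in GOI_HIERARCHY]


def goi_annotations() -> dict[str, GeneAnnotation]:
    """Annotations (compartment, molecule type) for the 114 GOI."""
    return {
        sym: GeneAnnotation(
            gene_id=sym, symbol=sym, compartment=comp, molecule_type=mtype
        )
        for sym, _tier, _fi, _fc, comp, mtype in GOI_HIERARCHY
    }


def goi_fold_changes() -> dict[str, tuple[float | None, float | None]]:
    """Published (TBI-I, TBI-C) fold-change cells for the 114 GOI;
    ``None`` where the printed cell is "~"."""
    return {
        sym: (parse_fold(fi), parse_fold(fc))
        for sym, _tier, fi, fc, _comp, _mtype in GOI_HIERARCHY
    }
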